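"""Backbone-amide chemical-shift perturbation (CSP) mapping.

Compares two 1H-15N HSQC peak lists (reference vs variant) residue by
residue using the conventional weighted combined shift

    CSP_i = sqrt( (d_dH_i)^2 + (wN * d_dN_i)^2 ),   wN = 0.2 by default,

where wN rescales the 15N dimension by roughly |gammaN/gammaH|.  Residues
present in only one list are reported separately and excluded from the
statistics.  Significance is classified against a relative threshold
(mean + 1 SD by default), with the mutated-site residue excluded from the
threshold computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PeakList", "CSPResult", "compute_csp", "classify_significant",
           "read_peak_list"]

DEFAULT_WN = 0.2


@dataclass
class PeakList:
    """Amide resonance positions keyed by residue identifier."""

    peaks: dict  # residue id -> (dH ppm, dN ppm)
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for res, (dh, dn) in self.peaks.items():
            if not (np.isfinite(dh) and np.isfinite(dn)):
                raise ValueError(f"non-finite shifts for residue {res!r}")

    @property
    def residues(self) -> set:
        return set(self.peaks)


@dataclass
class CSPResult:
    """Per-residue CSPs between two peak lists."""

    csp: dict  # residue id -> CSP (ppm), shared residues only
    only_reference: set
    only_variant: set
    wN: float
    threshold: float | None = None
    significant: set | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(sorted(self.csp.items()), columns=["residue", "csp_ppm"])
        if self.significant is not None:
            df["significant"] = df["residue"].isin(self.significant)
        return df


def read_peak_list(path) -> PeakList:
    """Read a whitespace/TSV peak list with columns (residue, dH_ppm, dN_ppm).

    An optional trailing assignment-name column is kept as a label.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError("peak list needs at least residue, dH_ppm, dN_ppm columns")
    peaks, labels = {}, {}
    for _, row in df.iterrows():
        res = row[cols[0]]
        res = int(res) if str(res).lstrip("-").isdigit() else res
        if res in peaks:
            raise ValueError(f"duplicate residue identifier {res!r}")
        peaks[res] = (float(row[cols[1]]), float(row[cols[2]]))
        if len(cols) > 3 and not pd.isna(row[cols[3]]):
            labels[res] = str(row[cols[3]])
    return PeakList(peaks, labels)


def compute_csp(reference: PeakList, variant: PeakList,
                wN: float = DEFAULT_WN) -> CSPResult:
    """Weighted combined 1H/15N shift differences over shared residues."""
    shared = reference.residues & variant.residues
    if not shared:
        raise ValueError("peak lists share no residues")
    csp = {}
    for res in shared:
        dh = variant.peaks[res][0] - reference.peaks[res][0]
        dn = variant.peaks[res][1] - reference.peaks[res][1]
        csp[res] = float(np.hypot(dh, wN * dn))
    return CSPResult(
        csp=csp,
        only_reference=reference.residues - variant.residues,
        only_variant=variant.residues - reference.residues,
        wN=wN,
    )


def classify_significant(result: CSPResult, n_sd: float = 1.0,
                         exclude=()) -> CSPResult:
    """Flag residues with CSP strictly above mean + n_sd * SD.

    ``exclude`` lists residues (typically the mutated site) left out of the
    mean/SD computation; they are still eligible for flagging.  With all
    CSPs equal the SD is zero and the strict inequality flags nothing.
    """
    if len(result.csp) < 5:
        raise ValueError("significance classification needs >= 5 residues")
    exclude = set(exclude)
    stat_vals = np.array([v for r, v in result.csp.items() if r not in exclude])
    if stat_vals.size == 0:
        raise ValueError("no residues left after exclusion")
    threshold = float(stat_vals.mean() + n_sd * stat_vals.std(ddof=0))
    significant = {r for r, v in result.csp.items() if v > threshold}
    return CSPResult(csp=result.csp, only_reference=result.only_reference,
                     only_variant=result.only_variant, wN=result.wN,
                     threshold=threshold, significant=significant)
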
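"""Glycoside census: count SGs per steroidal-aglycone species per sample.

A scan contributes one count when it contains an SA-species fragment carrying
a glycosylation signature — a chain of at least one glycosyl-residue neutral
loss (hexose, deoxyhexose or pentose; malonylhexoside allowed as the terminal
step onto the aglycone) connecting a heavier peak down to the SA fragment.
When several SA species qualify in one scan, the whole scan is attributed to
the heaviest one, so a saturated aglycone pre-empts the in-source dehydration
artifact of its unsaturated analogue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SA_SPECIES_MZ, Spectrum

GLYCOSYL_CHAIN = {"hexose": 162.052824, "deoxyhexose": 146.057909,
                  "pentose": 132.042259}
TERMINAL_ONLY = {"malonylhexoside": 248.053218}
DEFAULT_CENSUS_TOL = 0.02


@dataclass(frozen=True)
class SignatureMatch:
    found: bool
    ladder_mzs: tuple[float, ...] = ()   # descending, ends at the SA peak
    losses: tuple[str, ...] = ()


def detect_glycosylation_signature(
    scan: Spectrum, sa_mz: float, tol: float = DEFAULT_CENSUS_TOL
) -> SignatureMatch:
    """Longest glycosyl-loss ladder ending on the SA fragment, if any.

    Reachability is computed bottom-up over the sorted peak list; the reported
    ladder is the deepest chain, starting from the heaviest peak among ties.
    Raises when the scan has no peak near ``sa_mz`` (callers gate on the EIC).
    """
    sa_idx = scan.peaks_near(sa_mz, tol)
    if len(sa_idx) == 0:
        raise ValueError(f"no peak within {tol} of SA m/z {sa_mz}")
    mz = scan.mz
    n = len(mz)
    depth = np.full(n, -1)
    parent = np.full(n, -1)
    step = [""] * n
    is_sa = np.zeros(n, bool)
    for i in sa_idx:
        depth[i] = 0
        is_sa[i] = True
    for q in range(n):
        if depth[q] >= 0 and not is_sa[q]:
            continue
        best = depth[q]
        for r in range(q):
            if depth[r] < 0:
                continue
            delta = mz[q] - mz[r]
            for name, m in GLYCOSYL_CHAIN.items():
                if abs(delta - m) <= tol and depth[r] + 1 > best:
                    best, parent[q], step[q] = depth[r] + 1, r, name
            if is_sa[r]:
                for name, m in TERMINAL_ONLY.items():
                    if abs(delta - m) <= tol and depth[r] + 1 > best:
                        best, parent[q], step[q] = depth[r] + 1, r, name
        if best > depth[q]:
            depth[q] = best
    candidates = [i for i in range(n) if depth[i] >= 1]
    if not candidates:
        return SignatureMatch(False)
    top = max(candidates, key=lambda i: (depth[i], mz[i]))
    ladder, losses = [], []
    i = top
    while parent[i] >= 0:
        ladder.append(float(mz[i]))
        losses.append(step[i])
        i = parent[i]
    ladder.append(float(mz[i]))
    return SignatureMatch(True, tuple(ladder), tuple(losses))


def census_scan(scan: Spectrum, sa_mzs: Sequence[float] = SA_SPECIES_MZ,
                tol: float = DEFAULT_CENSUS_TOL) -> float | None:
    """SA species this scan counts toward (heaviest qualifying), or None."""
    qualifying = []
    for sa in sa_mzs:
        if len(scan.peaks_near(sa, tol)) == 0:
            continue
        if detect_glycosylation_signature(scan, sa, tol).found:
            qualifying.append(sa)
    return max(qualifying) if qualifying else None


def census_spectra(
    spectra_by_sample: dict[str, list[Spectrum]],
    sa_mzs: Sequence[float] = SA_SPECIES_MZ,
    tol: float = DEFAULT_CENSUS_TOL,
) -> pd.DataFrame:
    """SG count matrix (samples x SA species); each scan adds at most 1."""
    samples = list(spectra_by_sample)
    counts = pd.DataFrame(0, index=pd.Index(samples, name="sample"),
                          columns=list(sa_mzs))
    for sample, scans in spectra_by_sample.items():
        for scan in scans:
            sa = census_scan(scan, sa_mzs, tol)
            if sa is not None:
                counts.loc[sample, sa] += 1
    return counts
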
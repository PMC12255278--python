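"""Extracted ion chromatograms and the S/U leaf-chemotype decision rule.

A plant is assigned the saturated (S) chemotype when the m/z 416.3 fragment is
present in its chromatograms, and the unsaturated (U) chemotype when m/z 414.3
is present in the absence of 416.3; 416.3 presence dominates.  Chemotyping
uses a coarser one-decimal m/z window (default tolerance 0.05 Da) than the
census.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Spectrum

CHEMOTYPE_MZ_S = 416.3
CHEMOTYPE_MZ_U = 414.3
DEFAULT_EIC_TOL = 0.05


@dataclass(frozen=True)
class EIC:
    """Extracted ion chromatogram: (rt, summed intensity) trace for one m/z."""

    target_mz: float
    tol: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.rt) < 0):
            raise ValueError("retention times must be non-decreasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def max_intensity(self) -> float:
        return float(self.intensity.max()) if len(self.intensity) else 0.0


def extract_eic(spectra: Sequence[Spectrum], target_mz: float,
                tol: float = DEFAULT_EIC_TOL) -> EIC:
    """Per-scan summed intensity of peaks within ``tol`` of ``target_mz``."""
    if not spectra:
        raise ValueError("spectra must be non-empty")
    scans = sorted(spectra, key=lambda s: s.rt)
    rts = np.array([s.rt for s in scans])
    vals = np.array([
        float(s.intensity[s.peaks_near(target_mz, tol)].sum()) for s in scans
    ])
    return EIC(target_mz, tol, rts, vals)


def auto_threshold(eic: EIC, factor: float = 5.0) -> float:
    """Presence threshold: ``factor`` x the median of the full trace.

    The median over all scans (zeros included) estimates the baseline; for a
    sparse trace it is zero, so any strictly positive maximum counts as
    present.  An explicit numeric threshold can be passed instead wherever a
    threshold argument is accepted.
    """
    return factor * float(np.median(eic.intensity)) if len(eic.intensity) else 0.0


def assign_chemotype(
    eic414: EIC,
    eic416: EIC,
    presence_threshold: float | None = None,
) -> str:
    """S iff 416.3 present; else U iff 414.3 present; else undetermined."""
    thr416 = presence_threshold if presence_threshold is not None else auto_threshold(eic416)
    thr414 = presence_threshold if presence_threshold is not None else auto_threshold(eic414)
    if eic416.max_intensity > max(thr416, 0.0):
        return "S"
    if eic414.max_intensity > max(thr414, 0.0):
        return "U"
    return "undetermined"


def chemotype_samples(
    spectra_by_sample: dict[str, list[Spectrum]],
    tol: float = DEFAULT_EIC_TOL,
    presence_threshold: float | None = None,
) -> pd.DataFrame:
    """Chemotype call per sample, with the two EIC maxima for inspection."""
    rows = []
    for sample, spectra in spectra_by_sample.items():
        e414 = extract_eic(spectra, CHEMOTYPE_MZ_U, tol)
        e416 = extract_eic(spectra, CHEMOTYPE_MZ_S, tol)
        rows.append({
            "sample": sample,
            "label": assign_chemotype(e414, e416, presence_threshold),
            "max414": e414.max_intensity,
            "max416": e416.max_intensity,
        })
    return pd.DataFrame(rows).set_index("sample")
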
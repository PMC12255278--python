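"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 12 steroidal-aglycone (SA) fragment m/z values used as census
#: categories.  Even nominal mass => nitrogen-containing glycoalkaloid (SGA),
#: odd => saponin (SSG), by the nitrogen rule for [M+H]+ ions.
SA_SPECIES_MZ = (
    412.32, 414.35, 416.35, 428.32, 430.33, 432.35,
    415.32, 417.33, 433.33, 434.36, 446.33, 448.34,
)


def sa_species_table() -> pd.DataFrame:
    """SA species with SGA/SSG class assignment (even/odd nominal mass)."""
    rows = []
    for mz in SA_SPECIES_MZ:
        cls = "SGA" if round(mz) % 2 == 0 else "SSG"
        rows.append({"sa_mz": mz, "sg_class": cls})
    df = pd.DataFrame(rows)
    assert len(df) == 12 and df["sa_mz"].is_unique
    return df


@dataclass
class Spectrum:
    """One centroided scan: retention time plus (m/z, intensity) pairs."""

    sample: str
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def peaks_near(self, target: float, tol: float) -> np.ndarray:
        """Indices of peaks within ``tol`` of ``target``."""
        lo = np.searchsorted(self.mz, target - tol, side="left")
        hi = np.searchsorted(self.mz, target + tol, side="right")
        return np.arange(lo, hi)


@dataclass
class FeatureTable:
    """Features (m/z, retention time) x samples intensity matrix.

    ``features`` is indexed by feature id with columns ``mz`` and ``rt``;
    ``intensities`` shares the feature index and has one column per sample;
    ``metadata`` is indexed by sample with the factorial descriptors
    (chemotype, organ, ontogeny, genotype).
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        if not self.features.index.equals(self.intensities.index):
            raise ValueError("features and intensities must share an index")
        if self.features.index.duplicated().any():
            dup = self.features.index[self.features.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup}")
        missing = [s for s in self.intensities.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def matrix(self) -> pd.DataFrame:
        """Samples x features intensity matrix."""
        return self.intensities.T


@dataclass
class QPCRDataset:
    """qPCR wells plus per-gene efficiencies and dilution series.

    ``wells`` columns: gene, sample, replicate, cq (NaN = not detected);
    ``dilution_series`` columns: gene, dilution, cq.
    """

    wells: pd.DataFrame
    metadata: pd.DataFrame
    efficiencies: dict[str, float] = field(default_factory=dict)
    reference_genes: tuple[str, ...] = ()
    dilution_series: pd.DataFrame | None = None

    def __post_init__(self):
        required = {"gene", "sample", "replicate", "cq"}
        if not required.issubset(self.wells.columns):
            raise ValueError(f"wells table needs columns {sorted(required)}")
        for e in self.efficiencies.values():
            if not (1.0 < e <= 2.2):
                raise ValueError(f"efficiency {e} outside (1, 2.2]")

    @property
    def genes(self) -> list[str]:
        return sorted(self.wells["gene"].unique())
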
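"""Delimited-text readers and writers for pipeline artifacts.

Formats: feature tables and metadata as TSV, spectra as an MGF-like text
format (one BEGIN IONS/END IONS block per scan with a retention-time header),
Cq tables as TSV with "ND" for not-detected wells, and networks as GraphML.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .core import FeatureTable, QPCRDataset, Spectrum


# -- feature tables ---------------------------------------------------------

def write_feature_table(ft: FeatureTable, features_path, metadata_path) -> None:
    df = pd.concat([ft.features[["mz", "rt"]], ft.intensities], axis=1)
    df.index.name = "feature_id"
    df.to_csv(features_path, sep="\t")
    ft.metadata.rename_axis("sample").to_csv(metadata_path, sep="\t")


def read_feature_table(features_path, metadata_path) -> FeatureTable:
    df = pd.read_csv(features_path, sep="\t", index_col="feature_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{features_path}: duplicate feature id {dup!r}")
    for col in ("mz", "rt"):
        if col not in df.columns:
            raise ValueError(f"{features_path}: missing column {col!r}")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    features = df[["mz", "rt"]]
    intensities = df.drop(columns=["mz", "rt"])
    return FeatureTable(features, intensities, meta)


# -- spectra (MGF-like) -----------------------------------------------------

def write_spectra(spectra: Iterable[Spectrum], path) -> None:
    with open(path, "w") as fh:
        for i, sp in enumerate(spectra):
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE=sample={sp.sample} scan={i}\n")
            fh.write(f"RTINMINUTES={sp.rt:.4f}\n")
            for mz, inten in zip(sp.mz, sp.intensity):
                fh.write(f"{mz:.4f} {inten:.6g}\n")
            fh.write("END IONS\n")


def read_spectra(path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    sample = None
    rt = None
    mzs: list[float] = []
    ints: list[float] = []
    in_block = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                in_block, sample, rt, mzs, ints = True, None, None, [], []
            elif line == "END IONS":
                if rt is None or sample is None:
                    raise ValueError(f"{path}:{lineno}: scan block missing header")
                spectra.append(Spectrum(sample, rt, np.array(mzs), np.array(ints)))
                in_block = False
            elif line.startswith("TITLE="):
                for tok in line[len("TITLE="):].split():
                    if tok.startswith("sample="):
                        sample = tok[len("sample="):]
            elif line.startswith("RTINMINUTES="):
                rt = float(line.split("=", 1)[1])
            elif in_block:
                a, b = line.split()
                mzs.append(float(a))
                ints.append(float(b))
    return spectra


def spectra_by_sample(spectra: Iterable[Spectrum]) -> dict[str, list[Spectrum]]:
    out: dict[str, list[Spectrum]] = {}
    for sp in spectra:
        out.setdefault(sp.sample, []).append(sp)
    return out


# -- qPCR -------------------------------------------------------------------

def write_qpcr_dataset(ds: QPCRDataset, wells_path, metadata_path,
                       dilution_path=None) -> None:
    wells = ds.wells.copy()
    wells["cq"] = wells["cq"].map(lambda v: "ND" if pd.isna(v) else f"{v:.4f}")
    wells.to_csv(wells_path, sep="\t", index=False)
    ds.metadata.rename_axis("sample").to_csv(metadata_path, sep="\t")
    if dilution_path is not None and ds.dilution_series is not None:
        ds.dilution_series.to_csv(dilution_path, sep="\t", index=False)


def read_qpcr_dataset(wells_path, metadata_path, dilution_path=None,
                      efficiencies: dict[str, float] | None = None,
                      reference_genes: Iterable[str] = ()) -> QPCRDataset:
    wells = pd.read_csv(wells_path, sep="\t")
    wells["cq"] = pd.to_numeric(wells["cq"].replace("ND", np.nan), errors="coerce")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    dil = pd.read_csv(dilution_path, sep="\t") if dilution_path else None
    return QPCRDataset(wells, meta, efficiencies or {}, tuple(reference_genes), dil)
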
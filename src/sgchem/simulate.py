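"""Synthetic LC-MS and qPCR data with known ground truth.

The generator emulates the factorial study design of a two-chemotype
*Solanum dulcamara* experiment: S- and U-chemo-genotypes (3 + 4 by default),
organs (roots and leaves of vegetative plants; roots, leaves and stems of
flowering plants) and two ontogenetic stages.  Compounds are steroidal
glycosides built as aglycone + glycosyl chain; the S chemotype carries
saturated leaf aglycones that sit 2.016 Da (one H2) above their unsaturated
U-chemotype analogues, roots of both chemotypes share unsaturated compounds,
and one malonylated glycoalkaloid occurs exclusively in roots.

Every emitted artifact (spectra, feature table, Cq table) derives from a
single seeded random stream per artifact, so a fixed seed fixes the output
bit-for-bit, and the generator records ground truth for each downstream
stage: true per-sample glycoside counts per aglycone species, compound-family
membership of every feature, and the generating qPCR model coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SA_SPECIES_MZ, FeatureTable, QPCRDataset, Spectrum
from .masschem import ResidueTable, default_residue_table, predict_fragment_ladder

H2 = 2.015650  # saturation mass difference, Da


@dataclass(frozen=True)
class SimulationDesign:
    """Factorial design and noise model for the synthetic study."""

    n_genotypes_s: int = 3
    n_genotypes_u: int = 4
    replicates: int = 1
    intensity_sigma: float = 0.4     # log-normal sd of compound abundance
    scan_sigma: float = 0.1          # log-normal sd of per-scan ion intensity
    decoy_peaks: int = 5             # decoy peaks per scan
    decoy_intensity: float = 0.02    # decoy scale relative to baseline
    n_noise_features: int = 20       # unrelated features in the feature table
    baseline_intensity: float = 1e5
    scan_rate_k: float = 3.0         # scans per compound = k * log10(abundance)
    rt_range: tuple[float, float] = (0.75, 11.00)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genotypes_s, self.n_genotypes_u, self.replicates) < 1:
            raise ValueError("design counts must be >= 1")


ORGANS_BY_STAGE = {"vegetative": ("root", "leaf"),
                   "flowering": ("root", "leaf", "stem")}


@dataclass(frozen=True)
class CompoundSpec:
    """One steroidal glycoside: aglycone ion + ordered glycosyl losses."""

    name: str
    aglycone_mz: float
    losses: tuple[str, ...]          # ordered, molecular ion downward
    rt: float
    family: str                      # MDN family (co-eluting analogue group)
    multipliers: dict                # (chemotype, organ, ontogeny) -> float

    def ladder_mzs(self, table: ResidueTable | None = None) -> tuple[float, ...]:
        table = table or default_residue_table()
        total = sum(table.mass(l) for l in self.losses)
        ladder = predict_fragment_ladder(self.aglycone_mz + total, self.losses, table)
        return ladder.ions

    @property
    def molecular_ion_mz(self) -> float:
        return self.ladder_mzs()[0]

    @property
    def sa_species_mz(self) -> float:
        """Census category: nearest of the 12 SA species m/z values."""
        return min(SA_SPECIES_MZ, key=lambda s: abs(s - self.aglycone_mz))

    def multiplier(self, chemotype: str, organ: str, ontogeny: str) -> float:
        return self.multipliers.get((chemotype, organ, ontogeny), 0.0)


@dataclass
class GroundTruth:
    """What the generator planted, for oracle comparisons downstream."""

    library: list[CompoundSpec] = field(default_factory=list)
    sg_counts: pd.DataFrame | None = None          # samples x SA species
    scan_counts: pd.DataFrame | None = None        # sample, compound, n_scans
    feature_families: dict | None = None           # family -> [feature ids]
    feature_compounds: pd.Series | None = None     # feature id -> compound/"decoy"
    abundances: pd.DataFrame | None = None         # compounds x samples
    qpcr_coefficients: pd.DataFrame | None = None
    qpcr_efficiencies: dict | None = None
    qpcr_sample_effects: pd.Series | None = None


def sample_frame(design: SimulationDesign) -> pd.DataFrame:
    """Sample metadata table implied by the design."""
    rows = []
    genotypes = [("S", f"S{i+1}") for i in range(design.n_genotypes_s)] + \
                [("U", f"U{i+1}") for i in range(design.n_genotypes_u)]
    for ontogeny, organs in ORGANS_BY_STAGE.items():
        for chemotype, genotype in genotypes:
            for rep in range(1, design.replicates + 1):
                for organ in organs:
                    sid = f"{ontogeny[:4]}_{organ}_{genotype}_r{rep}"
                    rows.append({"sample": sid, "chemotype": chemotype,
                                 "organ": organ, "ontogeny": ontogeny,
                                 "genotype": genotype})
    return pd.DataFrame(rows).set_index("sample")


def _mult(leaf_s=0.0, leaf_u=0.0, root_s=0.0, root_u=0.0, stem_s=0.0,
          stem_u=0.0, veg=1.0, flo=1.0) -> dict:
    """Multiplier table from organ/chemotype levels and ontogeny scalers."""
    out = {}
    for (organ, chem), v in {("leaf", "S"): leaf_s, ("leaf", "U"): leaf_u,
                             ("root", "S"): root_s, ("root", "U"): root_u,
                             ("stem", "S"): stem_s, ("stem", "U"): stem_u}.items():
        out[(chem, organ, "vegetative")] = v * veg
        out[(chem, organ, "flowering")] = v * flo
    return out


def build_compound_library(design: SimulationDesign) -> tuple[list[CompoundSpec], GroundTruth]:
    """Compound library with the six worked SG structures plus hydroxylated
    variants covering all 12 SA species.

    Saturated/unsaturated analogue pairs share a retention time so that the
    saturation (H2) mass difference links them in the mass-difference network,
    defining the planted compound families.
    """
    lib: list[CompoundSpec] = []

    def add(name, aglycone, losses, rt, family, mult):
        lib.append(CompoundSpec(name, aglycone, tuple(losses), rt, family, mult))

    sat, unsat = 416.35, 416.35 - H2       # soladulcidine / solasodine class
    # I: SGA tetraoside, S leaves (plus unsaturated analogue in U leaves/roots)
    add("I_sat", sat, ["hexose", "pentose", "hexose", "hexose"], 6.2, "F1",
        _mult(leaf_s=1.0, veg=2.0))
    add("I_unsat", unsat, ["hexose", "pentose", "hexose", "hexose"], 6.2, "F1",
        _mult(leaf_u=1.0, root_s=0.6, root_u=0.6, veg=2.0))
    # II: SGA trioside (soladulcine A class)
    add("II_sat", sat, ["hexose", "deoxyhexose", "hexose"], 5.0, "F2",
        _mult(leaf_s=1.2, veg=2.0))
    add("II_unsat", unsat, ["hexose", "deoxyhexose", "hexose"], 5.0, "F2",
        _mult(leaf_u=1.2, root_s=0.8, root_u=0.8, veg=2.0))
    # III: trioside with hexose -> deoxyhexose substitution
    add("III_sat", sat, ["deoxyhexose", "deoxyhexose", "hexose"], 5.6, "F3",
        _mult(leaf_s=0.8))
    add("III_unsat", unsat, ["deoxyhexose", "deoxyhexose", "hexose"], 5.6, "F3",
        _mult(leaf_u=0.8, root_s=0.5, root_u=0.5))
    # IV: malonylated SGA, exclusively in roots, unsaturated
    add("IV_malonyl", 414.34, ["deoxyhexose", "deoxyhexose", "malonylhexoside"],
        4.2, "F4", _mult(root_s=1.0, root_u=1.0, flo=0.5))
    # V: unsaturated SSG pentoside; VI: its saturated analogue, flowering only
    add("V_ssg", 415.3126, ["hexose", "pentose", "hexose", "hexose", "hexose"],
        3.1, "F5", _mult(leaf_u=1.0, root_s=1.0, root_u=1.0, stem_u=0.6))
    add("VI_ssg_sat", 415.3126 + H2,
        ["hexose", "pentose", "hexose", "hexose", "hexose"], 3.1, "F5",
        _mult(leaf_s=0.8, stem_s=0.6, veg=0.0))
    # hydroxylated SGA pair (430.33 / 432.35)
    add("OH_sat", 432.35, ["hexose", "hexose"], 7.0, "F6",
        _mult(leaf_s=0.7, stem_s=0.5, flo=1.5))
    add("OH_unsat", 432.35 - H2, ["hexose", "hexose"], 7.0, "F6",
        _mult(leaf_u=0.7, root_s=0.5, root_u=0.5, stem_u=0.5, flo=1.5))
    # di-hydroxylated SGA pair (446.33 / 448.34), vegetative-enriched
    add("diOH_sat", 448.34, ["hexose"], 7.6, "F7",
        _mult(leaf_s=0.6, stem_s=0.4, veg=1.5))
    add("diOH_unsat", 448.34 - H2, ["hexose"], 7.6, "F7",
        _mult(leaf_u=0.6, root_s=0.4, root_u=0.4, stem_u=0.4, veg=1.5))
    # unsaturated SGA + its hydroxylated partner (412.32 / 428.32), O edge
    add("u8", 412.32, ["hexose", "hexose"], 8.2, "F8",
        _mult(leaf_u=0.5, root_s=0.6, root_u=0.6, flo=1.5))
    add("u8_OH", 428.32, ["hexose", "hexose"], 8.2, "F8",
        _mult(root_s=0.6, root_u=0.6, flo=1.5))
    # SSG hydroxylation pair (417.33 / 433.33)
    add("ssg_sapo", 417.33, ["hexose", "hexose"], 8.8, "F9",
        _mult(leaf_s=0.5, leaf_u=0.5, root_s=0.5, root_u=0.5, stem_s=0.7,
              stem_u=0.7, veg=1.5))
    add("ssg_sapo_OH", 433.33, ["hexose", "hexose"], 8.8, "F9",
        _mult(root_s=0.7, root_u=0.7, leaf_s=0.3, leaf_u=0.3, flo=1.8))
    # SGA with RDBE 5 aglycone (434.36), stem-enriched when flowering
    add("sga_434", 434.36, ["hexose"], 9.4, "F10",
        _mult(stem_s=0.8, stem_u=0.8, root_s=0.3, root_u=0.3))

    lo, hi = design.rt_range
    assert all(lo <= c.rt <= hi for c in lib)
    truth = GroundTruth(library=lib)
    return lib, truth


def _abundances(library: list[CompoundSpec], design: SimulationDesign) -> pd.DataFrame:
    """Compound x sample abundance draws (shared by spectra and features).

    abundance = baseline * group multiplier * LogNormal(0, sigma); zero where
    the multiplier is zero.  Seeded independently of the other noise streams
    so spectra and the feature table stay mutually consistent.
    """
    meta = sample_frame(design)
    rng = np.random.default_rng(design.seed)
    vals = np.zeros((len(library), len(meta)))
    for i, comp in enumerate(library):
        for j, (sid, row) in enumerate(meta.iterrows()):
            m = comp.multiplier(row["chemotype"], row["organ"], row["ontogeny"])
            if m > 0:
                noise = rng.lognormal(0.0, design.intensity_sigma) \
                    if design.intensity_sigma > 0 else 1.0
                vals[i, j] = design.baseline_intensity * m * noise
            else:
                rng.lognormal(0.0, 1.0)  # keep the stream aligned
    return pd.DataFrame(vals, index=[c.name for c in library], columns=meta.index)


def _n_scans(abundance: float, k: float) -> int:
    if abundance <= 0:
        return 0
    return max(1, round(k * math.log10(max(abundance, 10.0))))


def _relative_intensities(n_ions: int) -> np.ndarray:
    """Ladder ion intensity profile: base peak mid-ladder, molecular ion and
    aglycone weaker (the real relative intensities are not constrained)."""
    centre = (n_ions - 1) / 2
    rel = 1.0 - 0.6 * np.abs(np.arange(n_ions) - centre) / max(centre, 1)
    return np.clip(rel, 0.3, 1.0)


def _forbidden_mzs(library: list[CompoundSpec]) -> np.ndarray:
    true_ions = {mz for c in library for mz in c.ladder_mzs()}
    true_ions.update(SA_SPECIES_MZ)
    return np.array(sorted(true_ions))


def simulate_spectra(
    library: list[CompoundSpec],
    design: SimulationDesign,
    truth: GroundTruth | None = None,
) -> tuple[list[Spectrum], GroundTruth]:
    """In-source fragmentation scans for every sample.

    Each compound emits, in samples where its multiplier is positive, a number
    of scans increasing with abundance (``max(1, round(k log10 a))``); every
    scan contains the compound's full fragment ladder plus decoy peaks drawn
    uniformly over m/z 100-1300 away (+-0.05 Da) from all true ions.
    """
    meta = sample_frame(design)
    ab = _abundances(library, design)
    rng = np.random.default_rng(design.seed + 1)
    forbidden = _forbidden_mzs(library)
    spectra: list[Spectrum] = []
    scan_rows = []
    counts = pd.DataFrame(0, index=meta.index, columns=list(SA_SPECIES_MZ))
    for sid in meta.index:
        for comp in library:
            a = ab.loc[comp.name, sid]
            n = _n_scans(a, design.scan_rate_k)
            if n == 0:
                continue
            ladder = np.array(comp.ladder_mzs())
            rel = _relative_intensities(len(ladder))
            for _ in range(n):
                inten = a * rel
                if design.scan_sigma > 0:
                    inten = inten * rng.lognormal(0, design.scan_sigma, len(ladder))
                mzs, ints = list(ladder), list(inten)
                for _ in range(design.decoy_peaks):
                    for _try in range(20):
                        m = rng.uniform(100.0, 1300.0)
                        if np.min(np.abs(forbidden - m)) > 0.05:
                            break
                    mzs.append(m)
                    ints.append(design.decoy_intensity
                                * design.baseline_intensity * rng.uniform(0.2, 1.0))
                rt = comp.rt + rng.normal(0, 0.01)
                spectra.append(Spectrum(sid, rt, np.array(mzs), np.array(ints)))
            scan_rows.append({"sample": sid, "compound": comp.name, "n_scans": n})
            counts.loc[sid, comp.sa_species_mz] += n
    truth = truth or GroundTruth(library=library)
    truth.scan_counts = pd.DataFrame(scan_rows)
    truth.sg_counts = counts
    truth.abundances = ab
    return spectra, truth


def simulate_feature_table(
    library: list[CompoundSpec],
    design: SimulationDesign,
    truth: GroundTruth | None = None,
) -> tuple[FeatureTable, GroundTruth]:
    """Feature table with one row per distinct (ladder ion m/z, rt).

    Intensities are the per-sample compound abundances scaled by the ladder
    ion profile; a decoy feature at m/z 329.32 and unrelated noise features
    are appended (the latter become singletons in the network).
    """
    meta = sample_frame(design)
    ab = _abundances(library, design)
    rng = np.random.default_rng(design.seed + 2)
    feats: dict[tuple[float, float], dict] = {}
    for comp in library:
        ladder = comp.ladder_mzs()
        rel = _relative_intensities(len(ladder))
        for mz, r in zip(ladder, rel):
            key = (round(mz, 4), comp.rt)
            rec = feats.setdefault(key, {"mz": round(mz, 4), "rt": comp.rt,
                                         "compounds": [], "family": comp.family,
                                         "intens": np.zeros(len(meta))})
            rec["compounds"].append(comp.name)
            rec["intens"] = rec["intens"] + ab.loc[comp.name].to_numpy() * r
    rows, intens, fam_map, comp_map = [], [], {}, {}
    for i, rec in enumerate(feats.values()):
        fid = f"f{i+1:04d}"
        rows.append({"feature_id": fid, "mz": rec["mz"], "rt": rec["rt"]})
        intens.append(rec["intens"])
        fam_map.setdefault(rec["family"], []).append(fid)
        comp_map[fid] = "+".join(rec["compounds"])
    # decoy at m/z 329.32 (excluded from TIC_SG downstream)
    fid = f"f{len(rows)+1:04d}"
    rows.append({"feature_id": fid, "mz": 329.32, "rt": 2.0})
    intens.append(design.baseline_intensity * 0.5
                  * rng.lognormal(0, design.intensity_sigma, len(meta)))
    comp_map[fid] = "decoy_329"
    forbidden = _forbidden_mzs(library)
    for k in range(design.n_noise_features):
        for _try in range(50):
            m = rng.uniform(100.0, 1300.0)
            if np.min(np.abs(forbidden - m)) > 0.05:
                break
        fid = f"f{len(rows)+1:04d}"
        rows.append({"feature_id": fid, "mz": round(m, 4),
                     "rt": round(rng.uniform(*design.rt_range), 3)})
        intens.append(design.baseline_intensity * design.decoy_intensity
                      * rng.lognormal(0, design.intensity_sigma, len(meta)))
        comp_map[fid] = "noise"
    features = pd.DataFrame(rows).set_index("feature_id")
    intensities = pd.DataFrame(np.vstack(intens), index=features.index,
                               columns=meta.index)
    ft = FeatureTable(features[["mz", "rt"]], intensities, meta)
    truth = truth or GroundTruth(library=library)
    truth.feature_families = fam_map
    truth.feature_compounds = pd.Series(comp_map)
    if truth.abundances is None:
        truth.abundances = ab
    return ft, truth


# -- qPCR -------------------------------------------------------------------

DEFAULT_GENES = ("GAME9", "GAME4", "GAME25", "S5aR2", "DPS")
DEFAULT_REFERENCES = ("EXP", "SAND")
DEFAULT_EFFICIENCIES = {"GAME9": 1.93, "GAME4": 1.90, "GAME25": 1.95,
                        "S5aR2": 1.88, "DPS": 1.92, "EXP": 2.0, "SAND": 2.0}


def default_qpcr_coefficients() -> pd.DataFrame:
    """Generating log-scale mean counts per gene x chemotype x organ.

    The planted pattern mirrors the study system: GAME25 near the detection
    limit in U-chemotype leaves while readily expressed elsewhere; DPS high in
    roots; reference genes flat across all conditions.
    """
    base = math.log(5000.0)
    rows = []
    for gene in DEFAULT_GENES + DEFAULT_REFERENCES:
        for chem in ("S", "U"):
            for organ in ("root", "leaf", "stem"):
                b = base
                if gene == "GAME25" and chem == "U" and organ == "leaf":
                    b = math.log(2.0)          # near detection limit
                elif gene == "GAME4":
                    b = base + (math.log(2.9) if chem == "S" and organ == "root" else 0.0)
                elif gene == "DPS":
                    b = base + (math.log(8.0) if organ == "root" else 0.0)
                rows.append({"gene": gene, "chemotype": chem, "organ": organ,
                             "log_mean": b})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QPCRSimSettings:
    cq1: float = 37.0                 # single-molecule baseline cycle
    technical_replicates: int = 3
    cq_noise: float = 0.15            # sd of technical Cq noise, cycles
    sample_effect_sd: float = 0.3     # natural-log scale
    genotype_effect_sd: float = 0.2
    dilution_factors: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    dilution_base_count: float = 1e5


def simulate_qpcr_dataset(
    design: SimulationDesign,
    coefficients: pd.DataFrame | None = None,
    efficiencies: dict | None = None,
    settings: QPCRSimSettings | None = None,
) -> tuple[QPCRDataset, GroundTruth]:
    """Cq tables from a Poisson count model.

    True counts are Poisson with log-mean = gene x chemotype x organ fixed
    effect + sample and genotype random effects; Cq = Cq1 - log(count)/log(E)
    plus technical noise, three technical replicates per well group.  A 1-1000x
    dilution series per gene supports efficiency estimation; zero counts are
    emitted as not-detected.
    """
    settings = settings or QPCRSimSettings()
    coefficients = coefficients if coefficients is not None else default_qpcr_coefficients()
    efficiencies = dict(efficiencies or DEFAULT_EFFICIENCIES)
    if any(not (1.0 < e <= 2.0) for e in efficiencies.values()):
        raise ValueError("efficiencies must lie in (1, 2]")
    meta = sample_frame(design)
    rng = np.random.default_rng(design.seed + 3)
    coef = coefficients.set_index(["gene", "chemotype", "organ"])["log_mean"]
    genes = list(dict.fromkeys(coefficients["gene"]))
    u_sample = pd.Series(
        rng.normal(0, settings.sample_effect_sd, len(meta)), index=meta.index)
    genos = sorted(meta["genotype"].unique())
    u_geno = pd.Series(rng.normal(0, settings.genotype_effect_sd, len(genos)),
                       index=genos)
    rows = []
    for sid, srow in meta.iterrows():
        for gene in genes:
            eta = (coef[(gene, srow["chemotype"], srow["organ"])]
                   + u_sample[sid] + u_geno[srow["genotype"]])
            E = efficiencies[gene]
            for rep in range(1, settings.technical_replicates + 1):
                count = rng.poisson(math.exp(eta))
                if count == 0:
                    cq = np.nan
                else:
                    cq = settings.cq1 - math.log(count) / math.log(E)
                    if settings.cq_noise > 0:
                        cq += rng.normal(0, settings.cq_noise)
                rows.append({"gene": gene, "sample": sid, "replicate": rep,
                             "cq": cq})
    wells = pd.DataFrame(rows)
    dil_rows = []
    for gene in genes:
        E = efficiencies[gene]
        for d in settings.dilution_factors:
            cq = settings.cq1 - math.log(settings.dilution_base_count / d) / math.log(E)
            if settings.cq_noise > 0:
                cq += rng.normal(0, settings.cq_noise)
            dil_rows.append({"gene": gene, "dilution": d, "cq": cq})
    ds = QPCRDataset(wells, meta, efficiencies,
                     tuple(g for g in DEFAULT_REFERENCES if g in genes),
                     pd.DataFrame(dil_rows))
    truth = GroundTruth(qpcr_coefficients=coefficients,
                        qpcr_efficiencies=efficiencies,
                        qpcr_sample_effects=u_sample)
    return ds, truth


def simulate_study(design: SimulationDesign):
    """Convenience bundle: library, spectra, feature table, qPCR, truth."""
    lib, truth = build_compound_library(design)
    spectra, truth = simulate_spectra(lib, design, truth)
    ft, truth = simulate_feature_table(lib, design, truth)
    qpcr, qtruth = simulate_qpcr_dataset(design)
    truth.qpcr_coefficients = qtruth.qpcr_coefficients
    truth.qpcr_efficiencies = qtruth.qpcr_efficiencies
    truth.qpcr_sample_effects = qtruth.qpcr_sample_effects
    return lib, spectra, ft, qpcr, truth
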
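"""Synthetic-data generator: design structure, chemistry, determinism."""

import numpy as np
import pandas as pd
import pytest

from sgchem.io import write_spectra
from sgchem.simulate import (QPCRSimSettings, SimulationDesign,
                             build_compound_library, sample_frame,
                             simulate_feature_table, simulate_qpcr_dataset,
                             simulate_spectra)


@pytest.fixture(scope="module")
def design():
    return SimulationDesign(seed=3, decoy_peaks=0, n_noise_features=0)


class TestSampleFrame:
    def test_factorial_structure(self, design):
        meta = sample_frame(design)
        assert set(meta["chemotype"]) == {"S", "U"}
        # stems are harvested only from flowering plants
        veg = meta.query("ontogeny == 'vegetative'")
        assert set(veg["organ"]) == {"root", "leaf"}
        flo = meta.query("ontogeny == 'flowering'")
        assert set(flo["organ"]) == {"root", "leaf", "stem"}
        assert meta.query("chemotype == 'S'")["genotype"].nunique() == 3
        assert meta.query("chemotype == 'U'")["genotype"].nunique() == 4


class TestCompoundLibrary:
    def test_contains_tetraoside_at_1034(self, design):
        lib, _ = build_compound_library(design)
        mols = [c.molecular_ion_mz for c in lib]
        assert any(abs(m - 1034.55) <= 0.02 for m in mols)

    def test_root_only_malonylated_sga(self, design):
        lib, _ = build_compound_library(design)
        iv = [c for c in lib if abs(c.molecular_ion_mz - 954.51) <= 0.02]
        assert len(iv) == 1
        mult = iv[0].multipliers
        assert all(v == 0 for (c, o, s), v in mult.items() if o != "root")
        assert any(v > 0 for (c, o, s), v in mult.items() if o == "root")

    def test_chemotype_saturation_rule(self, design):
        """U-chemotype leaf compounds sit one H2 (2.016 Da) below their
        S-chemotype analogues; molecular ion = aglycone + glycan mass."""
        lib, _ = build_compound_library(design)
        by_family = {}
        for c in lib:
            by_family.setdefault(c.family, []).append(c)
        paired = 0
        for fam, comps in by_family.items():
            if len(comps) != 2:
                continue
            hi, lo = sorted(comps, key=lambda c: -c.aglycone_mz)
            if abs((hi.aglycone_mz - lo.aglycone_mz) - 2.0157) < 0.01:
                paired += 1
                # the saturated one occurs in S leaves, not U leaves
                s_leaf = [hi.multiplier("S", "leaf", o)
                          for o in ("vegetative", "flowering")]
                u_leaf = [hi.multiplier("U", "leaf", o)
                          for o in ("vegetative", "flowering")]
                assert max(s_leaf) > 0 and max(u_leaf) == 0
        assert paired >= 4

    def test_ssg_pentoside_ladder_present(self, design):
        lib, _ = build_compound_library(design)
        v = [c for c in lib if abs(c.molecular_ion_mz - 1195.5662) <= 0.01]
        assert v
        ions = v[0].ladder_mzs()
        assert any(abs(i - 739.42) <= 0.02 for i in ions)
        assert abs(ions[-1] - 415.31) <= 0.02


class TestSpectra:
    def test_absent_group_emits_no_scans(self, design):
        lib, truth = build_compound_library(design)
        spectra, truth = simulate_spectra(lib, design, truth)
        sc = truth.scan_counts
        iv = [c.name for c in lib if "IV" in c.name][0]
        meta = sample_frame(design)
        leafstem = meta.query("organ != 'root'").index
        assert not sc[(sc["compound"] == iv)
                      & (sc["sample"].isin(leafstem))].shape[0]

    def test_seed_determinism_byte_identical(self, design, tmp_path):
        outs = []
        for i in range(2):
            lib, truth = build_compound_library(design)
            spectra, _ = simulate_spectra(lib, design, truth)
            path = tmp_path / f"run{i}.mgf"
            write_spectra(spectra, path)
            outs.append(path.read_text())
        assert outs[0] == outs[1]

    def test_scan_count_scales_with_abundance(self, design):
        lib, truth = build_compound_library(design)
        _, truth = simulate_spectra(lib, design, truth)
        merged = truth.scan_counts.merge(
            truth.abundances.stack().rename("abundance"),
            left_on=["compound", "sample"], right_index=True)
        grp = merged.groupby("compound")
        for _, g in grp:
            if g["abundance"].nunique() > 1:
                hi = g.loc[g["abundance"].idxmax(), "n_scans"]
                lo = g.loc[g["abundance"].idxmin(), "n_scans"]
                assert hi >= lo


class TestFeatureTable:
    def test_zero_sigma_intensities_equal_group_means(self):
        d0 = SimulationDesign(seed=5, intensity_sigma=0.0, decoy_peaks=0,
                              n_noise_features=0)
        lib, _ = build_compound_library(d0)
        ft, truth = simulate_feature_table(lib, d0)
        meta = ft.metadata
        planted = truth.feature_compounds[
            ~truth.feature_compounds.isin(["decoy_329", "noise"])].index
        groups = meta.groupby(["chemotype", "organ", "ontogeny"]).groups
        for fid in planted[:10]:
            for _, idx in groups.items():
                vals = ft.intensities.loc[fid, idx]
                assert vals.nunique() <= 1

    def test_chemotype_difference_restricted_to_saturation_features(self):
        d0 = SimulationDesign(seed=5, intensity_sigma=0.0, decoy_peaks=0,
                              n_noise_features=0)
        lib, _ = build_compound_library(d0)
        ft, truth = simulate_feature_table(lib, d0)
        meta = ft.metadata
        s_leaf = meta.query("chemotype=='S' and organ=='leaf' and "
                            "ontogeny=='vegetative'").index
        u_leaf = meta.query("chemotype=='U' and organ=='leaf' and "
                            "ontogeny=='vegetative'").index
        diff = (ft.intensities[s_leaf].mean(axis=1)
                - ft.intensities[u_leaf].mean(axis=1)).abs()
        differing = set(truth.feature_compounds[diff[diff > 0].index])
        # every differing feature belongs to a chemotype-dependent compound
        for comp in differing:
            assert comp not in ("decoy_329", "noise")

    def test_contains_decoy_at_329(self, design):
        lib, _ = build_compound_library(design)
        ft, _ = simulate_feature_table(lib, design)
        assert (ft.features["mz"] == 329.32).any()


class TestQPCRSimulation:
    def test_cq_count_identity_without_noise(self):
        settings = QPCRSimSettings(cq_noise=0.0)
        # Cq = Cq1 - log_E(count): doubling E, count 1024 -> Cq 27
        assert settings.cq1 - np.log(1024) / np.log(2.0) == pytest.approx(27.0)

    def test_zero_counts_are_not_detected(self):
        d = SimulationDesign(seed=11)
        coef = pd.DataFrame(
            [{"gene": "g", "chemotype": c, "organ": o,
              "log_mean": -10.0}   # mean counts ~ 0
             for c in ("S", "U") for o in ("root", "leaf", "stem")])
        ds, _ = simulate_qpcr_dataset(d, coefficients=coef,
                                      efficiencies={"g": 2.0})
        assert ds.wells["cq"].isna().mean() > 0.9

    def test_game25_near_detection_limit_in_u_leaves_only(self):
        d = SimulationDesign(seed=13)
        ds, truth = simulate_qpcr_dataset(
            d, settings=QPCRSimSettings(cq_noise=0.0))
        wells = ds.wells.merge(ds.metadata, left_on="sample",
                               right_index=True)
        g25 = wells[wells["gene"] == "GAME25"]
        u_leaf = g25.query("chemotype=='U' and organ=='leaf'")["cq"]
        other = g25.query("~(chemotype=='U' and organ=='leaf')")["cq"]
        # U leaves: high Cq or not detected; elsewhere: strong signal
        assert u_leaf.fillna(40).min() > other.max()

    def test_determinism(self):
        d = SimulationDesign(seed=17)
        a, _ = simulate_qpcr_dataset(d)
        b, _ = simulate_qpcr_dataset(d)
        pd.testing.assert_frame_equal(a.wells, b.wells)
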
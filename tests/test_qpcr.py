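"""qPCR: efficiencies, Cq-count transform, expression model, contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

from sgchem.qpcr import (QPCRModel, cq_to_counts, dataset_counts,
                         efficiency_from_dilution)
from sgchem.simulate import (QPCRSimSettings, SimulationDesign,
                             simulate_qpcr_dataset)


def _series(E, cq1=37.0, base=1e5, dils=(1, 10, 100, 1000)):
    return [(d, cq1 - math.log(base / d) / math.log(E)) for d in dils]


class TestEfficiency:
    def test_perfect_doubling(self):
        assert efficiency_from_dilution(_series(2.0)) == pytest.approx(2.0, abs=1e-9)

    def test_slope_minus_3_5(self):
        # slope -3.5 on the standard-curve scale corresponds to E ~ 1.931
        pairs = [(d, 10.0 + 3.5 * math.log10(d)) for d in (1, 10, 100, 1000)]
        assert efficiency_from_dilution(pairs) == pytest.approx(1.931, abs=1e-3)

    def test_two_dilutions_rejected(self):
        with pytest.raises(ValueError):
            efficiency_from_dilution([(1, 20.0), (10, 23.3)])

    def test_nonmonotone_series_warns_but_returns(self):
        pairs = [(1, 20.0), (10, 19.0), (100, 26.6), (1000, 30.0)]
        with pytest.warns(UserWarning):
            E = efficiency_from_dilution(pairs)
        assert E > 1

    def test_noiseless_recovery_within_tolerance(self):
        design = SimulationDesign(seed=21)
        ds, truth = simulate_qpcr_dataset(
            design, settings=QPCRSimSettings(cq_noise=0.0))
        for gene, grp in ds.dilution_series.groupby("gene"):
            E = efficiency_from_dilution(grp)
            assert abs(E - truth.qpcr_efficiencies[gene]) <= 0.02


class TestCqToCounts:
    @pytest.mark.parametrize("cq,E,expected", [
        (27.0, 2.0, 1024), (37.0, 2.0, 1), (30.0, 1.93, 100)])
    def test_known_values(self, cq, E, expected):
        assert cq_to_counts(cq, E, cq1=37.0) == expected

    def test_not_detected_gives_zero(self):
        assert cq_to_counts(float("nan"), 2.0) == 0

    def test_round_trip_identity(self):
        # count -> Cq (generator convention) -> count is the identity
        for E in (1.85, 1.93, 2.0):
            for count in (1, 17, 1024, 100_000):
                cq = 37.0 - math.log(count) / math.log(E)
                assert cq_to_counts(cq, E, 37.0) == count

    def test_invalid_efficiency(self):
        with pytest.raises(ValueError):
            cq_to_counts(20.0, 1.0)


def _tiny_dataset(seed=0, u_sd=0.0, groups=("A", "B"), lam=None, reps=3):
    rng = np.random.default_rng(seed)
    lam = lam or {("g1", "A"): 400, ("g1", "B"): 900,
                  ("g2", "A"): 150, ("g2", "B"): 150}
    samples = [f"s{i}" for i in range(8)]
    meta = pd.DataFrame({"chemotype": ["A"] * 4 + ["B"] * 4,
                         "organ": ["x"] * 8}, index=samples)
    u = rng.normal(0, u_sd, 8)
    rows = []
    genes = sorted({g for g, _ in lam})
    for g in genes:
        for i, sid in enumerate(samples):
            mean = lam[(g, meta.loc[sid, "chemotype"])] * math.exp(u[i])
            for rep in range(1, reps + 1):
                rows.append({"gene": g, "sample": sid, "replicate": rep,
                             "count": rng.poisson(mean)})
    return pd.DataFrame(rows), meta


class TestExpressionModel:
    def test_naive_balanced_limit_equals_log_mean_counts(self):
        counts, meta = _tiny_dataset(seed=1, u_sd=0.0)
        m = QPCRModel(counts, meta, grouping=("chemotype", "organ"),
                      mode="naive", sample_sigma=1e-3)
        ge = m.fit().group_effects.set_index(["gene", "group"])
        cell_means = counts.merge(meta, left_on="sample", right_index=True) \
            .groupby(["gene", "chemotype"])["count"].mean()
        for (gene, chem), mean in cell_means.items():
            got = ge.loc[(gene, f"{chem}:x"), "log2_abundance"]
            assert got == pytest.approx(math.log2(mean), abs=0.02)

    def test_soft_mode_requires_reference(self):
        counts, meta = _tiny_dataset()
        with pytest.raises(ValueError):
            QPCRModel(counts, meta, mode="soft", reference_genes=())

    def test_soft_mode_absorbs_loading_into_sample_effects(self):
        """With a truly stable reference, soft normalization equalizes the
        reference gene's condition effects and pushes per-sample loading
        differences into the sample effects."""
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(8)]
        meta = pd.DataFrame({"chemotype": ["A"] * 4 + ["B"] * 4,
                             "organ": ["x"] * 8}, index=samples)
        u_true = rng.normal(0, 0.5, 8)
        lam = {("ref", "A"): 500, ("ref", "B"): 500,
               ("t", "A"): 100, ("t", "B"): 800}
        rows = []
        for g in ("ref", "t"):
            for i, sid in enumerate(samples):
                mean = lam[(g, meta.loc[sid, "chemotype"])] \
                    * math.exp(u_true[i])
                for rep in range(1, 4):
                    rows.append({"gene": g, "sample": sid, "replicate": rep,
                                 "count": rng.poisson(mean)})
        m = QPCRModel(pd.DataFrame(rows), meta, mode="soft",
                      reference_genes=("ref",))
        res = m.fit()
        ge = res.group_effects.set_index(["gene", "group"])["log2_abundance"]
        # the reference's two condition effects are pulled together
        assert abs(ge[("ref", "A:x")] - ge[("ref", "B:x")]) < 0.3
        # estimated sample effects track the generating loadings
        est = res.sample_effects.reindex(samples).to_numpy()
        assert np.corrcoef(est, u_true)[0, 1] > 0.9

    def test_doubling_counts_shifts_log2_by_one(self):
        counts, meta = _tiny_dataset(seed=3)
        res1 = QPCRModel(counts, meta, mode="naive").fit()
        doubled = counts.assign(count=counts["count"] * 2)
        res2 = QPCRModel(doubled, meta, mode="naive").fit()
        g1 = res1.group_effects.set_index(["gene", "group"])["log2_abundance"]
        g2 = res2.group_effects.set_index(["gene", "group"])["log2_abundance"]
        assert np.allclose(g2 - g1, 1.0, atol=0.05)
        c1 = res1.contrasts().set_index(["gene", "group_a", "group_b"])
        c2 = res2.contrasts().set_index(["gene", "group_a", "group_b"])
        assert np.allclose(c1["log2_fc"], c2["log2_fc"], atol=0.05)

    def test_all_zero_gene_excluded_with_warning(self):
        counts, meta = _tiny_dataset(seed=4)
        dead = counts[counts["gene"] == "g1"].assign(gene="dead", count=0)
        with pytest.warns(UserWarning, match="dead"):
            m = QPCRModel(pd.concat([counts, dead]), meta, mode="naive")
        assert "dead" not in m.genes
        assert m.fit().excluded_genes == ["dead"]

    def test_near_zero_cell_reported_near_detection_limit(self):
        lam = {("g", "A"): 1, ("g", "B"): 5000,
               ("ref", "A"): 500, ("ref", "B"): 500}
        counts, meta = _tiny_dataset(seed=5, lam=lam)
        res = QPCRModel(counts, meta, mode="naive").fit()
        ge = res.group_effects.set_index(["gene", "group"])["log2_abundance"]
        assert ge[("g", "A:x")] < 3.0 < ge[("g", "B:x")]
        assert np.isfinite(ge[("g", "A:x")])


class TestContrasts:
    def test_identical_groups_not_significant(self):
        lam = {("g", "A"): 300, ("g", "B"): 300}
        counts, meta = _tiny_dataset(seed=6, lam=lam)
        tab = QPCRModel(counts, meta, mode="naive").fit().contrasts()
        assert (tab["p_adj"] > 0.05).all()

    def test_planted_fold_change_detected_with_correct_sign(self):
        lam = {("g", "A"): 2900, ("g", "B"): 1000}
        counts, meta = _tiny_dataset(seed=7, u_sd=0.3, lam=lam)
        tab = QPCRModel(counts, meta, mode="naive",
                        sample_sigma=0.3).fit().contrasts()
        row = tab[(tab["gene"] == "g")].iloc[0]
        assert row["p_adj"] < 0.05
        assert row["log2_fc"] == pytest.approx(math.log2(2.9), abs=0.5)

    def test_adjusted_p_not_below_raw(self):
        counts, meta = _tiny_dataset(seed=8)
        tab = QPCRModel(counts, meta, mode="naive").fit().contrasts()
        assert (tab["p_adj"] >= tab["p"] - 1e-12).all()

    def test_fdr_controlled_under_null(self):
        """Across many null genes the FDR stays near or below nominal."""
        rejections, total = 0, 0
        for s in range(40):
            lam = {(f"g{j}", "A"): 300 for j in range(3)}
            lam.update({(f"g{j}", "B"): 300 for j in range(3)})
            counts, meta = _tiny_dataset(seed=100 + s, lam=lam)
            tab = QPCRModel(counts, meta, mode="naive").fit().contrasts()
            rejections += int((tab["p_adj"] < 0.05).any())
            total += 1
        assert rejections / total <= 0.12


class TestDatasetCounts:
    def test_counts_from_simulated_cq_match_generator(self):
        design = SimulationDesign(seed=23)
        ds, truth = simulate_qpcr_dataset(
            design, settings=QPCRSimSettings(cq_noise=0.0))
        counts = dataset_counts(ds, cq1=37.0)
        assert (counts["count"] >= 0).all()
        nd = ds.wells["cq"].isna()
        assert (counts.loc[nd.to_numpy(), "count"] == 0).all()
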
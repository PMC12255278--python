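"""GLM-ASCA: fits, effect decomposition, permutation, variable screening."""

import numpy as np
import pandas as pd
import pytest

from sgchem.asca import AscaModel, pseudo_r2_screen


def _toy_2x2(seed=0, n_rep=4, effect=1.0):
    rng = np.random.default_rng(seed)
    levels = [(a, b) for a in "xy" for b in "pq"]
    rows, idx = [], []
    for a, b in levels:
        for r in range(n_rep):
            idx.append(f"{a}{b}{r}")
            rows.append((a, b))
    design = pd.DataFrame(rows, columns=["A", "B"], index=idx)
    lam = np.where(design["A"] == "x", 20.0, 20.0 * effect)
    Y = pd.DataFrame({f"v{j}": rng.poisson(lam) for j in range(4)}, index=idx)
    return Y, design


class TestFits:
    def test_constant_counts_give_zero_slopes(self):
        Y, design = _toy_2x2()
        Y.loc[:] = 7
        res = AscaModel(Y, design, ["A", "B"]).fit()
        slopes = res.coefficients.drop(index="intercept")
        assert np.allclose(slopes, 0.0, atol=1e-6)
        assert np.allclose(res.coefficients.loc["intercept"], np.log(7))

    def test_planted_twofold_effect_recovered(self):
        rng = np.random.default_rng(1)
        n = 200
        design = pd.DataFrame({"organ": ["root"] * n + ["leaf"] * n},
                              index=[f"s{i}" for i in range(2 * n)])
        lam = np.where(design["organ"] == "root", 50.0, 100.0)
        Y = pd.DataFrame({"v": rng.poisson(lam)}, index=design.index)
        res = AscaModel(Y, design, ["organ"]).fit()
        # sum coding: organ[leaf] coefficient is half the log fold change
        coef = res.coefficients.loc["organ[leaf]", "v"]
        assert coef == pytest.approx(np.log(2) / 2, abs=0.05)

    def test_all_zero_variable_flagged_not_crashing(self):
        Y, design = _toy_2x2()
        Y["dead"] = 0
        res = AscaModel(Y, design, ["A"]).fit()
        assert res.converged.drop("dead").all()
        # degenerate variable either fails convergence or carries ~no signal
        assert (not res.converged["dead"]) or \
            abs(res.coefficients.loc["A[x]", "dead"]) < 10

    def test_rank_deficient_design_rejected(self):
        Y, design = _toy_2x2()
        design["A2"] = design["A"]
        with pytest.raises(ValueError):
            AscaModel(Y, design, ["A", "A2"])

    def test_from_formula_expands_interaction(self):
        Y, design = _toy_2x2()
        m = AscaModel.from_formula(Y, design, "A * B")
        assert m.terms == ["A", "B", "A:B"]


class TestDecomposition:
    def test_effects_plus_residual_reproduce_linear_predictor(self):
        Y, design = _toy_2x2(seed=2, effect=1.5)
        model = AscaModel(Y, design, ["A", "B", "A:B"])
        res = model.fit()
        total = res.coefficients.loc["intercept"].to_numpy()[None, :] \
            * np.ones((len(Y), 1))
        for term in model.terms:
            block = model.term_blocks[term]
            B = res.coefficients.loc[block.columns].to_numpy()
            total = total + block.to_numpy() @ B
        assert np.allclose(total, res.linear_predictor.to_numpy(), atol=1e-8)

    def test_scores_orthogonal(self):
        Y, design = _toy_2x2(seed=3, effect=2.0)
        res = AscaModel(Y, design, ["A"]).fit()
        S = res.effects["A"].scores.to_numpy()
        if S.shape[1] > 1:
            G = S.T @ S
            off = G - np.diag(np.diag(G))
            assert np.allclose(off, 0.0, atol=1e-8)

    def test_single_affected_variable_concentrates_loading(self):
        rng = np.random.default_rng(4)
        design = pd.DataFrame({"g": ["a"] * 20 + ["b"] * 20},
                              index=[f"s{i}" for i in range(40)])
        Y = pd.DataFrame(rng.poisson(30.0, (40, 3)),
                         index=design.index, columns=["v1", "v2", "v3"])
        Y.loc[design["g"] == "b", "v1"] = rng.poisson(300.0, 20)
        res = AscaModel(Y, design, ["g"]).fit()
        dec = res.effects["g"]
        assert dec.explained[0] == pytest.approx(100.0, abs=1e-6) or \
            dec.explained[0] > 95.0
        lv1 = dec.loadings["LV1"].abs()
        assert lv1.idxmax() == "v1" and lv1["v1"] > 0.9

    def test_explained_variances_sum_to_100(self):
        Y, design = _toy_2x2(seed=5, effect=1.5)
        res = AscaModel(Y, design, ["A", "B"]).fit()
        for dec in res.effects.values():
            if len(dec.explained):
                assert dec.explained.sum() == pytest.approx(100.0)
                assert (np.diff(dec.explained) <= 1e-9).all()

    def test_gaussian_identity_reduces_to_classical_asca(self):
        """On a balanced 2x2 design with Gaussian/identity settings the
        effect matrices equal hand-computed group-mean deviation matrices."""
        rng = np.random.default_rng(6)
        design = pd.DataFrame(
            {"A": ["x"] * 4 + ["y"] * 4, "B": ["p", "p", "q", "q"] * 2},
            index=[f"s{i}" for i in range(8)])
        Y = pd.DataFrame(rng.normal(10, 2, (8, 3)), index=design.index,
                         columns=["v1", "v2", "v3"])
        res = AscaModel(Y, design, ["A", "B", "A:B"],
                        family="gaussian").fit()
        grand = Y.mean()
        devA = Y.groupby(design["A"]).transform("mean") - grand
        devB = Y.groupby(design["B"]).transform("mean") - grand
        cell = Y.groupby([design["A"], design["B"]]).transform("mean")
        devAB = cell - grand - devA - devB
        assert np.allclose(res.effects["A"].effect, devA, atol=1e-8)
        assert np.allclose(res.effects["B"].effect, devB, atol=1e-8)
        assert np.allclose(res.effects["A:B"].effect, devAB, atol=1e-8)


class TestPermutation:
    def test_minimum_permutations_enforced(self):
        Y, design = _toy_2x2()
        with pytest.raises(ValueError):
            AscaModel(Y, design, ["A"]).permutation_validation(50)

    def test_strong_effect_reaches_minimal_p(self):
        Y, design = _toy_2x2(seed=7, effect=8.0, n_rep=6)
        p = AscaModel(Y, design, ["A"]).permutation_validation(99, seed=0)
        assert p["A"] == pytest.approx(1 / 100)

    def test_closed_form_matches_general_path(self):
        """The saturated single-factor fast path reproduces the IRLS effect
        matrix."""
        Y, design = _toy_2x2(seed=8, effect=2.0)
        m = AscaModel(Y, design, ["A"])
        res = m.fit()
        eta = m._group_link_means(design["A"].to_numpy(), Y.to_numpy(float))
        eta = eta - eta.mean(axis=0, keepdims=True)
        assert np.allclose(eta, res.effects["A"].effect, atol=1e-6)

    def test_null_p_values_not_degenerate(self):
        Y, design = _toy_2x2(seed=9, effect=1.0)
        p = AscaModel(Y, design, ["A"]).permutation_validation(199, seed=1)
        assert 0.0 < p["A"] <= 1.0

    def test_interaction_term_p_value(self):
        Y, design = _toy_2x2(seed=10, effect=1.0)
        m = AscaModel(Y, design, ["A", "B", "A:B"])
        p = m.permutation_validation(99, seed=2)
        assert set(p.index) == {"A", "B", "A:B"}
        assert ((p > 0) & (p <= 1)).all()


class TestScreen:
    def test_structured_variable_retained_flat_dropped(self):
        rng = np.random.default_rng(11)
        design = pd.DataFrame({"g": ["a"] * 12 + ["b"] * 12},
                              index=[f"s{i}" for i in range(24)])
        Y = pd.DataFrame({
            "signal": rng.poisson(np.where(design["g"] == "a", 10, 80)),
            "flat": rng.poisson(30.0, 24),
        }, index=design.index)
        table = pseudo_r2_screen(Y, design, ["g"], n_perm=99, seed=0)
        assert bool(table.loc["signal", "retained"])
        assert not bool(table.loc["flat", "retained"])

    def test_all_flat_handled_gracefully(self):
        rng = np.random.default_rng(12)
        design = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10},
                              index=[f"s{i}" for i in range(20)])
        Y = pd.DataFrame(rng.poisson(30.0, (20, 3)), index=design.index,
                         columns=["v1", "v2", "v3"])
        table = pseudo_r2_screen(Y, design, ["g"], n_perm=99, seed=1)
        assert table["retained"].dtype == bool  # may legitimately be empty
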
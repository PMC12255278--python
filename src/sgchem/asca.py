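"""GLM-based ANOVA-simultaneous component analysis of count matrices.

Per response variable (aglycone species) a log-link Poisson GLM is fitted on
a factorial design with sum-to-zero coding.  Each model term's contribution
to the linear predictor forms an effect matrix (samples x variables) on the
log scale — the only scale on which term contributions are additive — which
is column-centered and decomposed by SVD into latent variables (sample
scores, species loadings, explained-variance fractions).  Term significance
comes from a permutation test on the squared Frobenius norm of the effect
matrix, and variables can be screened by comparing each model's pseudo-R²
(1 - deviance/null deviance) against a permutation null.

A Gaussian/identity family option reduces the construction to classical
ASCA (effect matrices equal group-mean deviation matrices on balanced
designs), which serves as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


def _sum_contrast(series: pd.Series) -> pd.DataFrame:
    """Sum-to-zero (effects) coding: L-1 columns, last level = -1 row."""
    levels = sorted(pd.unique(series))
    if len(levels) < 2:
        raise ValueError(f"factor {series.name!r} needs >= 2 levels")
    cols = {}
    for lev in levels[:-1]:
        col = (series == lev).astype(float) - (series == levels[-1]).astype(float)
        cols[f"{series.name}[{lev}]"] = col
    return pd.DataFrame(cols, index=series.index)


def _term_matrix(design: pd.DataFrame, term: str) -> pd.DataFrame:
    factors = term.split(":")
    for f in factors:
        if f not in design.columns:
            raise ValueError(f"unknown design factor {f!r} in term {term!r}")
    block = _sum_contrast(design[factors[0]])
    for f in factors[1:]:
        nxt = _sum_contrast(design[f])
        cols = {}
        for a in block.columns:
            for b in nxt.columns:
                cols[f"{a}:{b}"] = block[a] * nxt[b]
        block = pd.DataFrame(cols, index=design.index)
    return block


@dataclass
class TermDecomposition:
    """SVD of one term's centered effect matrix."""

    effect: pd.DataFrame            # samples x variables, column-centered
    scores: pd.DataFrame            # samples x LV
    loadings: pd.DataFrame          # variables x LV
    explained: np.ndarray           # % of the term's variance per LV
    p_value: float | None = None


class AscaResults:
    """Fit results: coefficients, diagnostics, per-term decompositions."""

    def __init__(self, model, coefficients, deviance, null_deviance,
                 converged, linear_predictor):
        self.model = model
        self.coefficients = coefficients          # params x variables
        self.deviance = deviance
        self.null_deviance = null_deviance
        self.converged = converged
        self.linear_predictor = linear_predictor  # samples x variables
        self.effects: dict[str, TermDecomposition] = {}
        self.permutation_p: pd.Series | None = None

    @property
    def pseudo_r2(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - self.deviance / self.null_deviance
        return r2.rename("pseudo_r2")

    def summary(self) -> str:
        lines = [f"GLM-ASCA ({self.model.family} family)",
                 f"  variables: {self.coefficients.shape[1]} "
                 f"({int(self.converged.sum())} converged)",
                 f"  samples:   {len(self.model.design)}",
                 f"  terms:     {', '.join(self.model.terms)}"]
        for term, dec in self.effects.items():
            ev = ", ".join(f"LV{i+1} {v:.1f}%" for i, v in
                           enumerate(dec.explained[:3]))
            p = "" if dec.p_value is None else f"  p={dec.p_value:.4g}"
            lines.append(f"  {term}: {ev}{p}")
        return "\n".join(lines)


class AscaModel:
    """GLM-ASCA model for a samples x variables count matrix.

    Parameters
    ----------
    counts : DataFrame, samples x variables (non-negative integers).
    design : DataFrame of categorical factors, indexed like ``counts``.
    terms : model terms, e.g. ``["organ", "chemotype", "organ:chemotype"]``.
    family : "poisson" (log link) or "gaussian" (identity; classical ASCA).
    """

    def __init__(self, counts: pd.DataFrame, design: pd.DataFrame,
                 terms: list[str], family: str = "poisson"):
        if not counts.index.equals(design.index):
            design = design.loc[counts.index]
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if family not in ("poisson", "gaussian"):
            raise ValueError("family must be 'poisson' or 'gaussian'")
        self.counts = counts
        self.design = design
        self.terms = list(terms)
        self.family = family
        self.term_blocks = {t: _term_matrix(design, t) for t in self.terms}
        X = pd.concat([pd.Series(1.0, index=design.index, name="intercept")]
                      + [self.term_blocks[t] for t in self.terms], axis=1)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("design matrix is rank-deficient after encoding")
        self.exog = X

    @classmethod
    def from_formula(cls, counts: pd.DataFrame, design: pd.DataFrame,
                     formula: str, family: str = "poisson") -> "AscaModel":
        """Terms from a right-hand-side formula, e.g. ``organ * chemotype``."""
        terms: list[str] = []
        for piece in formula.replace("~", "").split("+"):
            piece = piece.strip()
            if "*" in piece:
                a, b = [p.strip() for p in piece.split("*")]
                terms += [a, b, f"{a}:{b}"]
            elif piece:
                terms.append(piece)
        return cls(counts, design, terms, family)

    def _family(self):
        return sm.families.Poisson() if self.family == "poisson" \
            else sm.families.Gaussian()

    def _fit_glms(self, exog: pd.DataFrame, counts: pd.DataFrame | None = None,
                  compute_null: bool = True):
        counts = counts if counts is not None else self.counts
        params, dev, nulldev, conv = {}, {}, {}, {}
        for var in counts.columns:
            y = counts[var].to_numpy(float)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.GLM(y, exog.to_numpy(), family=self._family()).fit(
                        maxiter=100)
                    nd = np.nan
                    if compute_null:
                        nd = float(sm.GLM(y, np.ones((len(y), 1)),
                                          family=self._family()).fit().deviance)
                ok = bool(res.converged) and np.all(np.isfinite(res.params))
                params[var] = res.params
                dev[var] = float(res.deviance)
                nulldev[var] = nd
                conv[var] = ok
            except Exception:
                params[var] = np.full(exog.shape[1], np.nan)
                dev[var] = np.nan
                nulldev[var] = np.nan
                conv[var] = False
        coef = pd.DataFrame(params, index=exog.columns)
        return (coef, pd.Series(dev), pd.Series(nulldev),
                pd.Series(conv, dtype=bool))

    # -- closed-form path: one saturated categorical term -------------------

    def _is_saturated_single_term(self) -> bool:
        return len(self.terms) == 1 and ":" not in self.terms[0]

    def _group_link_means(self, labels: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Per-sample linked group means (MLE of the saturated one-factor GLM)."""
        levels, inv = np.unique(labels, return_inverse=True)
        G = np.zeros((len(levels), Y.shape[1]))
        n = np.bincount(inv)
        for g in range(len(levels)):
            G[g] = Y[inv == g].sum(axis=0) / n[g]
        if self.family == "poisson":
            eps = 0.5 / n.max()   # continuity correction for empty cells
            G = np.log(np.maximum(G, eps))
        return G[inv]

    # -- public API ----------------------------------------------------------

    def fit(self, variables: list | None = None) -> AscaResults:
        """Fit per-variable GLMs and decompose every term's effect matrix."""
        counts = self.counts if variables is None else self.counts[variables]
        coef, dev, nulldev, conv = self._fit_glms(self.exog, counts)
        keep = [v for v in counts.columns if conv[v]]
        eta = pd.DataFrame(self.exog.to_numpy() @ coef[keep].to_numpy(),
                           index=self.exog.index, columns=keep)
        res = AscaResults(self, coef, dev, nulldev, conv, eta)
        for term in self.terms:
            block = self.term_blocks[term]
            B = coef.loc[block.columns, keep].to_numpy()
            E = block.to_numpy() @ B
            E = E - E.mean(axis=0, keepdims=True)
            res.effects[term] = self._decompose(E, keep)
        return res

    def _decompose(self, E: np.ndarray, variables: list) -> TermDecomposition:
        effect = pd.DataFrame(E, index=self.exog.index, columns=variables)
        total = float((E ** 2).sum())
        if total == 0:
            return TermDecomposition(effect,
                                     pd.DataFrame(index=self.exog.index),
                                     pd.DataFrame(index=variables),
                                     np.zeros(0))
        U, s, Vt = np.linalg.svd(E, full_matrices=False)
        nz = s > s[0] * 1e-10
        U, s, Vt = U[:, nz], s[nz], Vt[nz]
        lv = [f"LV{i+1}" for i in range(len(s))]
        scores = pd.DataFrame(U * s, index=self.exog.index, columns=lv)
        loadings = pd.DataFrame(Vt.T, index=variables, columns=lv)
        explained = 100.0 * s ** 2 / (s ** 2).sum()
        return TermDecomposition(effect, scores, loadings, explained)

    def permutation_validation(
        self,
        n_perm: int = 1000,
        seed: int = 0,
        terms: list[str] | None = None,
        results: AscaResults | None = None,
    ) -> pd.Series:
        """Permutation p-value per term.

        Statistic: squared Frobenius norm of the term's centered effect
        matrix.  Null: the tested term's design rows are permuted (other
        terms fixed) and the model refitted; for a single-factor model this
        is free permutation of the factor labels, computed in closed form
        (the saturated Poisson/Gaussian MLE is the group-mean fit).
        p = (1 + #{null >= observed}) / (n_perm + 1).
        """
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        terms = terms or self.terms
        results = results or self.fit()
        out = {}
        if self._is_saturated_single_term():
            term = self.terms[0]
            labels = self.design[term].to_numpy()
            keep = [v for v in self.counts.columns if results.converged[v]]
            Y = self.counts[keep].to_numpy(float)
            def stat(lab):
                eta = self._group_link_means(lab, Y)
                eta = eta - eta.mean(axis=0, keepdims=True)
                return float((eta ** 2).sum())
            obs = stat(labels)
            null = np.array([stat(rng.permutation(labels))
                             for _ in range(n_perm)])
            out[term] = (1 + int((null >= obs).sum())) / (n_perm + 1)
        else:
            for term in terms:
                obs = float((results.effects[term].effect.to_numpy() ** 2).sum())
                null = np.empty(n_perm)
                for b in range(n_perm):
                    null[b] = self._permuted_stat(term, rng)
                out[term] = (1 + int((null >= obs).sum())) / (n_perm + 1)
        p = pd.Series(out, name="p_value")
        results.permutation_p = p
        for t, dec in results.effects.items():
            if t in p.index:
                dec.p_value = float(p[t])
        return p

    def _permuted_stat(self, term: str, rng: np.random.Generator) -> float:
        perm = rng.permutation(len(self.exog))
        exog = self.exog.copy()
        cols = list(self.term_blocks[term].columns)
        exog[cols] = exog[cols].to_numpy()[perm]
        coef, dev, nulldev, conv = self._fit_glms(exog, compute_null=False)
        keep = [v for v in self.counts.columns if conv[v]]
        B = coef.loc[cols, keep].to_numpy()
        E = exog[cols].to_numpy() @ B
        E = E - E.mean(axis=0, keepdims=True)
        return float((E ** 2).sum())


def pseudo_r2_screen(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    terms: list[str],
    n_perm: int = 199,
    seed: int = 0,
    family: str = "poisson",
) -> pd.DataFrame:
    """Retain variables whose pseudo-R² beats its permutation null.

    The null reference per variable is the median pseudo-R² over refits on
    row-permuted responses; a variable is retained when the observed model
    fits better than that reference.
    """
    model = AscaModel(counts, design, terms, family)
    res = model.fit()
    observed = res.pseudo_r2
    rng = np.random.default_rng(seed)
    null = np.full((n_perm, counts.shape[1]), np.nan)
    for b in range(n_perm):
        perm = rng.permutation(len(counts))
        shuffled = pd.DataFrame(counts.to_numpy()[perm],
                                index=counts.index, columns=counts.columns)
        m = AscaModel(shuffled, design, terms, family)
        null[b] = m.fit().pseudo_r2.to_numpy()
    ref = pd.Series(np.nanmedian(null, axis=0), index=counts.columns,
                    name="null_pseudo_r2")
    table = pd.DataFrame({"pseudo_r2": observed, "null_pseudo_r2": ref})
    table["retained"] = table["pseudo_r2"] > table["null_pseudo_r2"]
    table.loc[~res.converged, "retained"] = False
    return table
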
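"""Count-based RT-qPCR expression modelling.

Raw quantification cycles (Cq) are transformed into estimated template-
molecule counts, ``count = round(E^(Cq1 - Cq))``, given per-gene amplification
efficiencies E (estimated from 1-1000x dilution series, or assumed 2 for
reference genes).  Counts are modelled with a hierarchical log-linear Poisson
model: gene x condition fixed effects plus sample (and optionally genotype)
random effects that absorb loading differences.  In soft-normalization mode
the reference genes' condition effects are penalized toward a common value,
so sample effects are pulled toward values that equalize the references
instead of dividing by them.  Estimation is penalized maximum likelihood with
Laplace (inverse-Hessian) intervals; an optional random-walk MCMC sampler
mirrors the Bayesian treatment.  Pairwise condition contrasts per gene are
reported on the log2 scale with Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import QPCRDataset

LN2 = math.log(2.0)
DEFAULT_CQ1 = 37.0


def efficiency_from_dilution(series: pd.DataFrame | list) -> float:
    """Amplification efficiency from a dilution series.

    ``series``: (dilution factor, Cq) pairs.  Cq is regressed on
    log10(concentration) = -log10(dilution); E = 10^(-1/slope).  E is clipped
    to (1, 2.2] and values outside (1.6, 2.1) raise a warning, as do
    non-monotone series.
    """
    if isinstance(series, pd.DataFrame):
        pairs = list(zip(series["dilution"], series["cq"]))
    else:
        pairs = list(series)
    dils = sorted({d for d, _ in pairs})
    if len(dils) < 3:
        raise ValueError("need >= 3 distinct dilutions")
    x = np.array([-math.log10(d) for d, _ in pairs])
    y = np.array([cq for _, cq in pairs])
    slope, _ = np.polyfit(x, y, 1)
    if slope >= 0:
        warnings.warn("non-negative dilution slope; efficiency unreliable")
        return 2.2
    by_dil = pd.DataFrame(pairs, columns=["d", "cq"]).groupby("d")["cq"].mean()
    if not by_dil.sort_index().is_monotonic_increasing:
        warnings.warn("dilution series is not monotone in Cq")
    E = 10.0 ** (-1.0 / slope)
    if not (1.6 < E < 2.1):
        warnings.warn(f"efficiency {E:.3f} outside the usual (1.6, 2.1) range")
    return float(min(max(E, 1.0 + 1e-6), 2.2))


def cq_to_counts(cq: float, E: float, cq1: float = DEFAULT_CQ1) -> int:
    """Template count implied by a Cq value; not-detected (NaN) gives 0."""
    if not E > 1:
        raise ValueError("efficiency must be > 1")
    if cq is None or (isinstance(cq, float) and math.isnan(cq)):
        return 0
    return max(0, round(E ** (cq1 - cq)))


def dataset_counts(ds: QPCRDataset, cq1: float = DEFAULT_CQ1,
                   efficiencies: dict[str, float] | None = None) -> pd.DataFrame:
    """Tidy count table (gene, sample, replicate, count) from Cq wells."""
    eff = dict(ds.efficiencies)
    if efficiencies:
        eff.update(efficiencies)
    if ds.dilution_series is not None:
        for gene, grp in ds.dilution_series.groupby("gene"):
            eff.setdefault(gene, efficiency_from_dilution(grp))
    out = ds.wells.copy()
    missing = sorted(set(out["gene"]) - set(eff))
    if missing:
        raise ValueError(f"no efficiency for genes: {missing}")
    out["count"] = [cq_to_counts(c, eff[g], cq1)
                    for g, c in zip(out["gene"], out["cq"])]
    return out[["gene", "sample", "replicate", "count"]]


@dataclass
class _ParamIndex:
    beta: dict            # (gene, group) -> column
    sample: dict          # sample -> column
    genotype: dict        # genotype -> column
    n: int


class QPCRResults:
    """Penalized-ML fit: group abundances, intervals and contrasts."""

    def __init__(self, model, theta, cov, index, excluded):
        self.model = model
        self._theta = theta
        self._cov = cov
        self._index = index
        self.excluded_genes = excluded

    def _beta(self, gene, group):
        j = self._index.beta[(gene, group)]
        return self._theta[j], math.sqrt(max(self._cov[j, j], 0.0))

    @property
    def group_effects(self) -> pd.DataFrame:
        """Estimated log2 abundance per gene x condition with 95% intervals."""
        rows = []
        for (gene, group), j in self._index.beta.items():
            b, se = self._theta[j], math.sqrt(max(self._cov[j, j], 0.0))
            rows.append({
                "gene": gene, "group": group,
                "log2_abundance": b / LN2, "log2_se": se / LN2,
                "log2_lo": (b - 1.96 * se) / LN2,
                "log2_hi": (b + 1.96 * se) / LN2,
            })
        return pd.DataFrame(rows)

    @property
    def sample_effects(self) -> pd.Series:
        return pd.Series({s: self._theta[j]
                          for s, j in self._index.sample.items()},
                         name="sample_effect")

    def fitted_counts(self) -> pd.Series:
        eta = self.model._X @ self._theta
        return pd.Series(np.exp(eta), index=self.model._wells.index)

    def contrasts(self, fdr_method: str = "fdr_bh") -> pd.DataFrame:
        """All pairwise condition differences per gene, log2 scale, BH-adjusted."""
        rows = []
        groups = self.model.groups
        for gene in self.model.genes:
            for i, a in enumerate(groups):
                for b in groups[i + 1:]:
                    ja, jb = self._index.beta[(gene, a)], self._index.beta[(gene, b)]
                    d = self._theta[ja] - self._theta[jb]
                    var = (self._cov[ja, ja] + self._cov[jb, jb]
                           - 2 * self._cov[ja, jb])
                    se = math.sqrt(max(var, 1e-12))
                    z = d / se
                    rows.append({"gene": gene, "group_a": a, "group_b": b,
                                 "log2_fc": d / LN2, "log2_se": se / LN2,
                                 "z": z, "p": 2 * stats.norm.sf(abs(z))})
        tab = pd.DataFrame(rows)
        if len(tab):
            tab["p_adj"] = multipletests(tab["p"], method=fdr_method)[1]
        return tab

    def summary(self) -> str:
        ge = self.group_effects
        lines = [f"qPCR expression model (mode={self.model.mode}, "
                 f"{len(self.model.genes)} genes, "
                 f"{len(self.model.samples)} samples)"]
        for gene, grp in ge.groupby("gene"):
            vals = ", ".join(f"{r.group}: {r.log2_abundance:.2f}"
                             for r in grp.itertuples())
            lines.append(f"  {gene}  log2 abundance  {vals}")
        if self.excluded_genes:
            lines.append(f"  excluded (all-zero): {self.excluded_genes}")
        return "\n".join(lines)


class QPCRModel:
    """Hierarchical Poisson expression model over qPCR counts.

    Parameters
    ----------
    counts : tidy table (gene, sample, replicate, count); technical
        replicates enter as repeated observations, never averaged.
    metadata : sample-indexed frame providing the grouping factors.
    grouping : metadata columns whose combinations define the conditions.
    mode : "naive" or "soft" (reference-gene stability penalty).
    reference_genes : required non-empty in soft mode.
    sample_sigma, genotype_sigma : prior sd of the random effects (natural
        log); genotype effects are used when a ``genotype`` column exists.
    ref_sigma : prior sd of reference-gene condition deviations (soft mode).
    beta_sigma : weak prior sd on fixed effects; keeps empty cells finite so
        a condition with no detected template reports a near-detection-limit
        abundance instead of diverging.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame,
                 grouping=("chemotype", "organ"), mode: str = "naive",
                 reference_genes=(), sample_sigma: float = 1.0,
                 genotype_sigma: float = 1.0, ref_sigma: float = 0.1,
                 beta_sigma: float = 5.0):
        if mode not in ("naive", "soft"):
            raise ValueError("mode must be 'naive' or 'soft'")
        if mode == "soft" and not reference_genes:
            raise ValueError("soft mode requires >= 1 reference gene")
        wells = counts.merge(metadata, left_on="sample", right_index=True)
        wells["group"] = wells[list(grouping)].astype(str).agg(":".join, axis=1)
        totals = wells.groupby("gene")["count"].sum()
        self.excluded = sorted(totals.index[totals == 0])
        if self.excluded:
            warnings.warn(f"excluding all-zero genes: {self.excluded}")
            wells = wells[~wells["gene"].isin(self.excluded)]
        self._wells = wells.reset_index(drop=True)
        self.metadata = metadata
        self.grouping = tuple(grouping)
        self.mode = mode
        self.reference_genes = tuple(g for g in reference_genes
                                     if g not in self.excluded)
        self.genes = sorted(self._wells["gene"].unique())
        self.groups = sorted(self._wells["group"].unique())
        self.samples = sorted(self._wells["sample"].unique())
        self._sample_sigma = sample_sigma
        self._genotype_sigma = genotype_sigma
        self._ref_sigma = ref_sigma
        self._beta_sigma = beta_sigma
        self._build_design()

    @classmethod
    def from_dataset(cls, ds: QPCRDataset, cq1: float = DEFAULT_CQ1,
                     **kwargs) -> "QPCRModel":
        counts = dataset_counts(ds, cq1)
        kwargs.setdefault("reference_genes", ds.reference_genes)
        return cls(counts, ds.metadata, **kwargs)

    def _build_design(self):
        w = self._wells
        beta_idx, k = {}, 0
        present = set(zip(w["gene"], w["group"]))
        for gene in self.genes:
            for group in self.groups:
                if (gene, group) in present:
                    beta_idx[(gene, group)] = k
                    k += 1
        sample_idx = {s: k + i for i, s in enumerate(self.samples)}
        k += len(self.samples)
        geno_idx = {}
        self._has_genotype = "genotype" in self.metadata.columns
        if self._has_genotype:
            for g in sorted(self.metadata["genotype"].unique()):
                geno_idx[g] = k
                k += 1
        self._index = _ParamIndex(beta_idx, sample_idx, geno_idx, k)
        X = np.zeros((len(w), k))
        for row_i, row in enumerate(w.itertuples()):
            X[row_i, beta_idx[(row.gene, row.group)]] = 1.0
            X[row_i, sample_idx[row.sample]] = 1.0
            if self._has_genotype:
                X[row_i, geno_idx[row.genotype]] = 1.0
        self._X = X
        self._y = w["count"].to_numpy(float)
        # quadratic penalty matrix (Gaussian priors)
        P = np.zeros((k, k))
        for j in beta_idx.values():
            P[j, j] += 1.0 / self._beta_sigma ** 2
        for j in sample_idx.values():
            P[j, j] += 1.0 / self._sample_sigma ** 2
        for j in geno_idx.values():
            P[j, j] += 1.0 / self._genotype_sigma ** 2
        if self.mode == "soft":
            lam = 1.0 / self._ref_sigma ** 2
            for gene in self.reference_genes:
                cols = [j for (g, grp), j in beta_idx.items() if g == gene]
                m = len(cols)
                if m < 2:
                    continue
                # penalize deviations of the gene's condition effects from
                # their mean: lam * || (I - 11^T/m) beta_ref ||^2
                C = np.full((m, m), -1.0 / m)
                np.fill_diagonal(C, 1.0 - 1.0 / m)
                for a in range(m):
                    for b in range(m):
                        P[cols[a], cols[b]] += lam * C[a, b]
        self._P = P

    # -- penalized likelihood -------------------------------------------------

    def _nll(self, theta):
        eta = self._X @ theta
        return float(np.sum(np.exp(eta) - self._y * eta)
                     + 0.5 * theta @ self._P @ theta)

    def _newton(self, max_iter=50, tol=1e-8):
        X, y, P = self._X, self._y, self._P
        theta = np.zeros(self._index.n)
        # initialize fixed effects at log cell means
        w = self._wells
        means = w.groupby(["gene", "group"])["count"].mean()
        for (gene, group), j in self._index.beta.items():
            theta[j] = math.log(max(means[(gene, group)], 0.1))
        f = self._nll(theta)
        for _ in range(max_iter):
            mu = np.exp(X @ theta)
            grad = X.T @ (mu - y) + P @ theta
            H = (X.T * mu) @ X + P
            try:
                delta = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(H, grad, rcond=None)[0]
            step = 1.0
            for _ in range(30):
                cand = theta - step * delta
                fc = self._nll(cand)
                if fc <= f:
                    break
                step *= 0.5
            if not np.isfinite(fc):
                raise RuntimeError("qPCR model failed to converge")
            improved = f - fc
            theta, f = cand, fc
            if improved < tol and np.max(np.abs(grad)) < 1e-4:
                break
        mu = np.exp(X @ theta)
        H = (X.T * mu) @ X + P
        cov = np.linalg.inv(H)
        return theta, cov

    def fit(self, method: str = "laplace", iterations: int = 110_000,
            thin: int = 100, burn_in: int = 10_000,
            seed: int = 0) -> QPCRResults:
        """Penalized ML with Laplace intervals (default) or random-walk MCMC.

        The MCMC path draws from the penalized posterior with a Laplace-
        calibrated proposal; the effective-sample-size convergence criterion
        (eff.samp below (iterations - burn_in)/thin) is checked and warned on.
        """
        theta, cov = self._newton()
        if method == "laplace":
            return QPCRResults(self, theta, cov, self._index, self.excluded)
        if method != "mcmc":
            raise ValueError("method must be 'laplace' or 'mcmc'")
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
        scale = 2.38 / math.sqrt(len(theta))
        cur, cur_nll = theta.copy(), self._nll(theta)
        draws = []
        for it in range(iterations):
            prop = cur + scale * (L @ rng.standard_normal(len(cur)))
            prop_nll = self._nll(prop)
            if math.log(rng.uniform()) < cur_nll - prop_nll:
                cur, cur_nll = prop, prop_nll
            if it >= burn_in and (it - burn_in) % thin == 0:
                draws.append(cur.copy())
        D = np.array(draws)
        max_samp = (iterations - burn_in) / thin
        ess = _effective_sample_size(D)
        if np.any(ess < 0.1 * max_samp):
            warnings.warn("low effective sample size in MCMC draws")
        return QPCRResults(self, D.mean(axis=0), np.cov(D.T), self._index,
                           self.excluded)


def _effective_sample_size(draws: np.ndarray) -> np.ndarray:
    """Crude ESS per parameter from lag-1 autocorrelation."""
    n, k = draws.shape
    out = np.empty(k)
    for j in range(k):
        x = draws[:, j] - draws[:, j].mean()
        denom = float(x @ x)
        if denom == 0:
            out[j] = n
            continue
        rho = float(x[:-1] @ x[1:]) / denom
        rho = min(max(rho, -0.99), 0.99)
        out[j] = n * (1 - rho) / (1 + rho)
    return out
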
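"""Count normalization, filtering, and negative-binomial GLM likelihood-ratio tests.

This module is the statistical engine shared by every downstream analysis:
median-of-ratios size factors, low-expression filtering, NB2 log-likelihood,
gene-wise GLM fits with fixed offsets, likelihood-ratio tests against nested
reduced designs, and Benjamini-Hochberg FDR control.

The NB2 parameterization is ``Var(Y) = mu + phi * mu**2``; ``phi = 0``
degenerates to the Poisson limit. Gene-wise dispersion is estimated by
maximising the Cox-Reid adjusted profile likelihood under the full design and
held fixed for both nested fits, so the LRT statistic is always nonnegative.

With per-gene dispersion estimated from a handful of replicates, referring
the LRT statistic directly to its asymptotic chi-squared distribution is
anti-conservative; the default p-value therefore uses a quasi-likelihood
F reference (LRT/df divided by the residual deviance per degree of freedom,
against F(df, n - p)), which absorbs dispersion-estimation noise gene by
gene without borrowing information across genes. The asymptotic chi-squared
p-value remains available via ``p_method='chisq'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger("cistrans")

P_FLOOR = 1e-300          # reported p-values never go below this
MU_FLOOR = 1e-12          # mean floor inside likelihood evaluations
PHI_MIN, PHI_MAX = 1e-6, 10.0   # dispersion search bounds (log-scale search)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Genes x samples nonnegative integer counts with sample metadata.

    ``meta`` is indexed by sample name and must carry at least a ``genotype``
    column (W, C, CxW) and a ``replicate`` column; allele-resolved matrices
    additionally carry ``allele`` (W/C) and ``generation`` (F0/F1).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if "genotype" not in self.meta.columns:
            raise ValueError("sample metadata must include a 'genotype' column")

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(self.counts[samples], self.meta.loc[samples])

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, meta: pd.DataFrame) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(counts, meta)


@dataclass
class DeResult:
    """Per-gene differential-expression test result (log2fc is W over C)."""

    gene_id: str
    base_mean: float
    log2fc: float
    lrt_stat: float
    df: int
    pvalue: float
    qvalue: float = float("nan")
    phi: float = float("nan")
    degenerate: bool = False
    ll_full: float = float("nan")
    ll_reduced: float = float("nan")


def de_results_frame(results: list[DeResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "baseMean": [r.base_mean for r in results],
            "log2fc": [r.log2fc for r in results],
            "lrt_stat": [r.lrt_stat for r in results],
            "df": [r.df for r in results],
            "pvalue": [r.pvalue for r in results],
            "qvalue": [r.qvalue for r in results],
        }
    )
    return df.set_index("gene_id")


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def size_factors_median_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (DESeq-style).

    The per-gene reference is the geometric mean across samples, restricted to
    genes with strictly positive counts in every sample; each sample's factor
    is the median ratio of its counts to that reference.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be 2-dimensional (genes x samples)")
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "relax low-expression filtering before computing size factors"
        )
    logmat = np.log(mat[allpos])
    logref = logmat.mean(axis=1)
    factors = np.exp(np.median(logmat - logref[:, None], axis=0))
    if isinstance(counts, pd.DataFrame):
        return pd.Series(factors, index=counts.columns, name="size_factor")
    return pd.Series(factors, name="size_factor")


def filter_low_expression(
    cm: CountMatrix, threshold: int = 5, rule: str = "any"
) -> CountMatrix:
    """Drop genes with low per-genotype median raw counts.

    ``rule='any'`` (default) retains a gene if its median count is >=
    ``threshold`` in at least one genotype, which preserves genes silenced in
    a single parent; ``rule='all'`` requires every genotype to pass.
    A median exactly equal to the threshold passes ("smaller than" is strict).
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    medians = {}
    for geno, samples in cm.meta.groupby("genotype").groups.items():
        medians[geno] = cm.counts[list(samples)].median(axis=1)
    med = pd.DataFrame(medians)
    passing = (med >= threshold).any(axis=1) if rule == "any" else (med >= threshold).all(axis=1)
    kept = cm.counts.loc[passing]
    logger.info(
        "low-expression filter: %d of %d genes retained (threshold=%d, rule=%s)",
        kept.shape[0], cm.counts.shape[0], threshold, rule,
    )
    return CountMatrix(kept, cm.meta)


# ---------------------------------------------------------------------------
# NB2 likelihood and GLM fitting
# ---------------------------------------------------------------------------

def nb_loglik(y, mu, phi: float) -> float:
    """Exact NB2 log-likelihood; ``phi=0`` evaluates the Poisson limit."""
    if phi < 0:
        raise ValueError("dispersion phi must be nonnegative")
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), MU_FLOOR)
    if phi == 0.0:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)))
    r = 1.0 / phi
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _fit_nb_glm(y, X, offset, phi, beta0=None, maxit=60, tol=1e-10):
    """IRLS fit of an NB2 GLM with log link, fixed offsets and fixed phi.

    Returns (beta, loglik). Step-halving guards against divergence; a Nelder-
    Mead polish is the fallback when IRLS stalls away from the optimum.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if beta0 is None:
        work = np.log(np.maximum(y, 0.5)) - offset
        beta, *_ = np.linalg.lstsq(X, work, rcond=None)
    else:
        beta = np.array(beta0, dtype=float)
    ll = nb_loglik(y, np.exp(np.clip(X @ beta + offset, -30.0, 30.0)), phi)
    for _ in range(maxit):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            sw = np.sqrt(w)
            beta_new, *_ = np.linalg.lstsq(X * sw[:, None], sw * z, rcond=None)
        step = beta_new - beta
        ll_new = nb_loglik(y, np.exp(np.clip(X @ beta_new + offset, -30.0, 30.0)), phi)
        t = 1.0
        while (not np.isfinite(ll_new)) or ll_new < ll - 1e-9:
            t *= 0.5
            if t < 1e-6:
                break
            beta_new = beta + t * step
            ll_new = nb_loglik(y, np.exp(np.clip(X @ beta_new + offset, -30.0, 30.0)), phi)
        if not np.isfinite(ll_new) or ll_new < ll:
            break
        converged = abs(ll_new - ll) < tol * (abs(ll) + 1.0)
        beta, ll = beta_new, ll_new
        if converged:
            return beta, ll
    # polish: direct maximization if IRLS did not converge cleanly
    res = optimize.minimize(
        lambda b: -nb_loglik(y, np.exp(np.clip(X @ b + offset, -30.0, 30.0)), phi),
        beta, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if np.isfinite(res.fun) and -res.fun > ll:
        return res.x, -res.fun
    return beta, ll


def estimate_dispersion(y, X, offset=None, cox_reid: bool = True) -> float:
    """Gene-wise NB2 dispersion by adjusted profile maximum likelihood.

    Profiles the likelihood over phi under the full design; the Cox-Reid term
    ``-0.5 log|X' W X|`` corrects the downward small-sample bias of the plain
    profile MLE. Falls back to a method-of-moments estimate if the numerical
    profile fails.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if offset is None:
        offset = np.zeros(y.shape[0])
    if not y.any():
        return 0.0

    cache = {"beta": None}

    def neg_apl(logphi: float) -> float:
        phi = float(np.exp(logphi))
        beta, ll = _fit_nb_glm(y, X, offset, phi, beta0=cache["beta"])
        cache["beta"] = beta
        if cox_reid:
            mu = np.exp(np.clip(X @ beta + offset, -30.0, 30.0))
            w = mu / (1.0 + phi * mu)
            sign, logdet = np.linalg.slogdet((X.T * w) @ X)
            if sign > 0:
                ll -= 0.5 * logdet
        return -ll

    try:
        res = optimize.minimize_scalar(
            neg_apl,
            bounds=(np.log(PHI_MIN), np.log(PHI_MAX)),
            method="bounded",
            options={"xatol": 5e-3},
        )
        if np.isfinite(res.fun):
            return float(np.exp(res.x))
    except (np.linalg.LinAlgError, FloatingPointError):  # pragma: no cover
        pass
    # method-of-moments fallback on size-factor-normalized counts
    norm = y / np.exp(offset)
    m, v = norm.mean(), norm.var(ddof=1) if norm.size > 1 else 0.0
    if m <= 0:
        return 0.0
    return float(min(max((v - m) / m**2, PHI_MIN), PHI_MAX))


def _check_nested(X_full: np.ndarray, X_reduced: np.ndarray) -> int:
    """Verify span(X_reduced) is contained in span(X_full); return the df."""
    rank_full = np.linalg.matrix_rank(X_full)
    rank_red = np.linalg.matrix_rank(X_reduced)
    proj, *_ = np.linalg.lstsq(X_full, X_reduced, rcond=None)
    resid = X_reduced - X_full @ proj
    if np.abs(resid).max() > 1e-8:
        raise ValueError("reduced design is not nested in the full design")
    df = rank_full - rank_red
    if df <= 0:
        raise ValueError("full design adds no parameters over the reduced design")
    return df


def nb_glm_lrt(
    y,
    X_full,
    X_reduced,
    size_factors,
    phi: float | None = None,
    gene_id: str = "gene",
    group=None,
    pseudocount: float = 0.5,
    p_method: str = "ql_f",
) -> DeResult:
    """Likelihood-ratio test of nested NB2 GLMs for one gene.

    Log size factors enter as fixed offsets. When ``phi`` is None it is
    estimated under the full design (Cox-Reid adjusted profile likelihood) and
    held fixed for both fits. ``group`` (optional, labels 'W'/'C' per sample)
    drives the reported W-over-C log2 fold change, computed from normalized
    mean counts with a pseudocount.

    ``p_method='ql_f'`` (default) refers LRT/df, scaled by the full model's
    residual deviance per degree of freedom, to F(df, n - p) — calibrated at
    replicate numbers where the plain asymptotic reference is liberal;
    ``'chisq'`` uses chi-squared(df) directly. With no residual degrees of
    freedom the chi-squared reference is used regardless.
    """
    y = np.asarray(y, dtype=float)
    X_full = np.atleast_2d(np.asarray(X_full, dtype=float))
    X_reduced = np.atleast_2d(np.asarray(X_reduced, dtype=float))
    sf = np.asarray(size_factors, dtype=float)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    df = _check_nested(X_full, X_reduced)
    offset = np.log(sf)
    norm = y / sf
    base_mean = float(norm.mean())

    log2fc = float("nan")
    if group is not None:
        group = np.asarray(group)
        mw = norm[group == "W"].mean() if (group == "W").any() else np.nan
        mc = norm[group == "C"].mean() if (group == "C").any() else np.nan
        log2fc = float(np.log2((mw + pseudocount) / (mc + pseudocount)))

    if not y.any():
        return DeResult(gene_id, 0.0, 0.0 if group is not None else log2fc,
                        0.0, df, 1.0, phi=0.0, degenerate=True)

    if phi is None:
        phi = estimate_dispersion(y, X_full, offset)
    elif phi < 0:
        raise ValueError("dispersion phi must be nonnegative")
    if p_method not in ("ql_f", "chisq"):
        raise ValueError("p_method must be 'ql_f' or 'chisq'")

    beta_full, ll_full = _fit_nb_glm(y, X_full, offset, phi)
    _, ll_red = _fit_nb_glm(y, X_reduced, offset, phi)
    lrt = max(0.0, 2.0 * (ll_full - ll_red))
    df_resid = y.size - int(np.linalg.matrix_rank(X_full))
    if p_method == "ql_f" and df_resid > 0:
        ll_sat = nb_loglik(y, np.maximum(y, MU_FLOOR), phi)
        s2 = max(2.0 * (ll_sat - ll_full) / df_resid, 1e-8)
        p = float(stats.f.sf((lrt / df) / s2, df, df_resid))
    else:
        p = float(stats.chi2.sf(lrt, df))
    p = max(p, P_FLOOR)
    return DeResult(gene_id, base_mean, log2fc, lrt, df, p, phi=phi,
                    ll_full=ll_full, ll_reduced=ll_red)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone and capped at 1.

    NaN entries are propagated as NaN and excluded from the ranking.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="mergesort")
    scaled = pv[order] * m / np.arange(1, m + 1)
    stepped = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(stepped, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# parental differential expression
# ---------------------------------------------------------------------------

def parental_de(
    cm: CountMatrix,
    alpha_fdr: float = 0.05,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Wild-vs-cultivated differential expression via NB-GLM LRT with BH FDR.

    Tests the genotype factor (full ``~ genotype`` vs reduced ``~ 1``) on the
    W and C parental samples; returns the per-gene results table with q-values
    adjusted within this test family.
    """
    parents = cm.meta.index[cm.meta["genotype"].isin(["W", "C"])]
    if len(parents) < 4:
        raise ValueError("need W and C samples with at least 2 replicates each")
    sub = cm.subset_samples(parents)
    for geno in ("W", "C"):
        if (sub.meta["genotype"] == geno).sum() < 2:
            raise ValueError(f"need at least 2 replicates of genotype {geno}")
    if size_factors is None:
        size_factors = size_factors_median_ratios(sub.counts)
    sf = size_factors.loc[sub.counts.columns].to_numpy()
    group = np.where(sub.meta.loc[sub.counts.columns, "genotype"] == "W", "W", "C")
    is_w = (group == "W").astype(float)
    X_full = np.column_stack([np.ones(is_w.size), is_w])
    X_red = np.ones((is_w.size, 1))

    results = []
    mat = sub.counts.to_numpy(dtype=float)
    for i, gene in enumerate(sub.counts.index):
        results.append(
            nb_glm_lrt(mat[i], X_full, X_red, sf, gene_id=str(gene), group=group)
        )
    table = de_results_frame(results)
    table["qvalue"] = bh_adjust(table["pvalue"].to_numpy())
    table["significant"] = table["qvalue"] < alpha_fdr
    logger.info(
        "parental DE: %d of %d genes significant at FDR %.2f",
        int(table["significant"].sum()), len(table), alpha_fdr,
    )
    return table
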
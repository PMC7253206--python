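"""Cis/trans regulatory-divergence tests and the seven-category classifier.

Three nested NB-GLM likelihood-ratio tests are run per gene on the
allele-resolved counts:

* parental: wild vs cultivated expression in the F0 libraries
  (full ``~ allele`` vs reduced ``~ 1`` on the parental allele sources);
* cis: allelic imbalance between the two alleles inside the F1 hybrid,
  where both alleles share one cellular (trans) environment
  (full ``~ allele`` vs reduced ``~ 1``);
* trans: the allele x generation interaction
  (full ``~ allele + generation + allele:generation`` vs the additive
  reduced model) — significance means the parental ratio differs from the
  hybrid allelic ratio, i.e. trans divergence.

Effect decomposition: the hybrid allelic log2 ratio is the cis component and
the parental log2 ratio minus the hybrid ratio is the trans component, so
cis + trans equals the parental log2 fold change by construction. Categories
follow the McManus-style decision table with an explicit ambiguous catch-all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ase import AlleleCountProfile
from .de import DeResult, bh_adjust, estimate_dispersion, nb_glm_lrt

logger = logging.getLogger("cistrans")

CATEGORY_LABELS = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_by_trans",
    "compensatory",
    "ambiguous",
)


@dataclass
class RegulatoryCall:
    """Per-gene test results, effect decomposition and category."""

    gene_id: str
    p_parental: float
    q_parental: float
    p_cis: float
    q_cis: float
    p_trans: float
    q_trans: float
    parental_log2fc: float
    hybrid_log2fc: float
    cis_component: float
    trans_component: float
    category: str
    cis_percentage: float


# ---------------------------------------------------------------------------
# per-gene designs
# ---------------------------------------------------------------------------

def _gene_arrays(profile: AlleleCountProfile, gene: str):
    cols = list(profile.counts.columns)
    y = profile.counts.loc[gene].to_numpy(dtype=float)
    gen = np.array([c[0] for c in cols])
    allele = np.array([c[2] for c in cols])
    return y, gen, allele, cols


def _size_factor_array(profile: AlleleCountProfile, size_factors: pd.Series | None):
    if size_factors is None:
        size_factors = profile.size_factors()
    return size_factors.loc[profile.counts.columns].to_numpy(dtype=float)


def cis_test(
    profile: AlleleCountProfile,
    gene: str,
    size_factors: pd.Series | None = None,
    phi: float | None = None,
) -> DeResult:
    """Allelic-imbalance LRT in the F1 hybrid (full ~ allele; reduced ~ 1).

    Both allele channels of a hybrid replicate come from one library and so
    share that replicate's size factor. log2fc is W allele over C allele.
    """
    y, gen, allele, _ = _gene_arrays(profile, gene)
    sf = _size_factor_array(profile, size_factors)
    f1 = gen == "F1"
    if f1.sum() < 4:
        raise ValueError("need F1 allele counts with at least 2 replicates")
    is_w = (allele[f1] == "W").astype(float)
    X_full = np.column_stack([np.ones(is_w.size), is_w])
    return nb_glm_lrt(
        y[f1], X_full, np.ones((is_w.size, 1)), sf[f1],
        phi=phi, gene_id=gene, group=allele[f1],
    )


def parental_test(
    profile: AlleleCountProfile,
    gene: str,
    size_factors: pd.Series | None = None,
    phi: float | None = None,
) -> DeResult:
    """Wild-vs-cultivated LRT on the F0 parental libraries."""
    y, gen, allele, _ = _gene_arrays(profile, gene)
    sf = _size_factor_array(profile, size_factors)
    f0 = gen == "F0"
    if f0.sum() < 4:
        raise ValueError("need F0 counts with at least 2 replicates per parent")
    is_w = (allele[f0] == "W").astype(float)
    X_full = np.column_stack([np.ones(is_w.size), is_w])
    return nb_glm_lrt(
        y[f0], X_full, np.ones((is_w.size, 1)), sf[f0],
        phi=phi, gene_id=gene, group=allele[f0],
    )


def trans_test(
    profile: AlleleCountProfile,
    gene: str,
    size_factors: pd.Series | None = None,
    phi: float | None = None,
) -> DeResult:
    """Allele x generation interaction LRT across F0 and F1.

    full ``~ allele + generation + allele:generation`` against reduced
    ``~ allele + generation``; a significant interaction means the allelic
    ratio changes between generations, the signature of trans divergence.
    """
    y, gen, allele, _ = _gene_arrays(profile, gene)
    if not (gen == "F0").any() or not (gen == "F1").any():
        raise ValueError("trans test needs both F0 and F1 counts")
    sf = _size_factor_array(profile, size_factors)
    is_w = (allele == "W").astype(float)
    is_f1 = (gen == "F1").astype(float)
    ones = np.ones(y.size)
    X_red = np.column_stack([ones, is_w, is_f1])
    X_full = np.column_stack([X_red, is_w * is_f1])
    return nb_glm_lrt(y, X_full, X_red, sf, phi=phi, gene_id=gene)


# ---------------------------------------------------------------------------
# effect decomposition and category assignment
# ---------------------------------------------------------------------------

def effect_components(
    profile: AlleleCountProfile,
    gene: str,
    size_factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> tuple[float, float]:
    """(parental_log2fc, hybrid_log2fc) from normalized mean counts.

    A pseudocount guards against division by zero for silenced alleles.
    """
    y, gen, allele, _ = _gene_arrays(profile, gene)
    sf = _size_factor_array(profile, size_factors)
    norm = y / sf

    def mean_of(g, a):
        sel = (gen == g) & (allele == a)
        return norm[sel].mean()

    parental = float(np.log2(
        (mean_of("F0", "W") + pseudocount) / (mean_of("F0", "C") + pseudocount)
    ))
    hybrid = float(np.log2(
        (mean_of("F1", "W") + pseudocount) / (mean_of("F1", "C") + pseudocount)
    ))
    return parental, hybrid


def classify_regulation(
    q_parental: float,
    q_cis: float,
    q_trans: float,
    cis_component: float,
    trans_component: float,
    alpha: float = 0.05,
) -> str:
    """Assign one of the seven regulatory categories.

    With P/H/T the significance indicators of the parental, cis (hybrid
    allelic imbalance) and trans (interaction) tests: conserved = none
    significant; cis_only = P,H only; trans_only = P,T only;
    cis_plus_trans / cis_by_trans = all three with concordant / opposing
    effect signs; compensatory = H,T without P. Every remaining pattern —
    including a zero effect component where a sign is required — is
    ambiguous.
    """
    P, H, T = q_parental < alpha, q_cis < alpha, q_trans < alpha
    if not P and not H and not T:
        return "conserved"
    if P and H and not T:
        return "cis_only"
    if P and not H and T:
        return "trans_only"
    if P and H and T:
        s_c, s_t = np.sign(cis_component), np.sign(trans_component)
        if s_c == 0 or s_t == 0:
            logger.info("zero effect component with cis and trans significant: ambiguous")
            return "ambiguous"
        return "cis_plus_trans" if s_c == s_t else "cis_by_trans"
    if not P and H and T:
        return "compensatory"
    return "ambiguous"


def classify_all(
    profile: AlleleCountProfile,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Run all three tests on every gene and assign categories.

    q-values are Benjamini-Hochberg adjusted separately within each test
    family (parental, cis, trans). Returns one row per gene; the category
    column is a strict partition of the input genes.
    """
    if size_factors is None:
        size_factors = profile.size_factors()
    rows = []
    for gene in profile.genes:
        r_par = parental_test(profile, gene, size_factors)
        r_cis = cis_test(profile, gene, size_factors)
        r_trans = trans_test(profile, gene, size_factors)
        parental_fc, hybrid_fc = effect_components(
            profile, gene, size_factors, pseudocount
        )
        rows.append(
            {
                "gene_id": gene,
                "p_parental": r_par.pvalue,
                "p_cis": r_cis.pvalue,
                "p_trans": r_trans.pvalue,
                "parental_log2fc": parental_fc,
                "hybrid_log2fc": hybrid_fc,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    for fam in ("parental", "cis", "trans"):
        table[f"q_{fam}"] = bh_adjust(table[f"p_{fam}"].to_numpy())
    table["cis_component"] = table["hybrid_log2fc"]
    table["trans_component"] = table["parental_log2fc"] - table["hybrid_log2fc"]
    table["category"] = [
        classify_regulation(
            row.q_parental, row.q_cis, row.q_trans,
            row.cis_component, row.trans_component, alpha,
        )
        for row in table.itertuples()
    ]
    denom = table["cis_component"].abs() + table["trans_component"].abs()
    table["cis_percentage"] = np.where(
        denom > 0, 100.0 * table["cis_component"].abs() / denom, np.nan
    )
    counts = table["category"].value_counts()
    logger.info("category counts: %s", counts.to_dict())
    return table


def category_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Category tally over all labels (zero-filled), a partition of genes."""
    vc = calls["category"].value_counts()
    return {label: int(vc.get(label, 0)) for label in CATEGORY_LABELS}


def cis_percentage_bins(calls: pd.DataFrame, bin_edges) -> pd.DataFrame:
    """Mean cis percentage per bin of absolute parental log2 fold change.

    Genes with an undefined cis percentage (zero total effect) are excluded;
    empty bins are reported as NaN rather than zero.
    """
    if len(calls) == 0:
        raise ValueError("no regulatory calls to bin")
    edges = np.asarray(bin_edges, dtype=float)
    mag = calls["parental_log2fc"].abs()
    binned = pd.cut(mag, edges, include_lowest=True)
    grouped = calls["cis_percentage"].groupby(binned, observed=False)
    return pd.DataFrame(
        {"mean_cis_percentage": grouped.mean(), "n_genes": grouped.count()}
    )


# ---------------------------------------------------------------------------
# study-level statistics
# ---------------------------------------------------------------------------

def proportion_test(n_success: int, n_total: int, p0: float) -> tuple[float, float]:
    """One-sample proportion z-test with continuity correction (two-sided).

    z = sign(x - n*p0) * (|x - n*p0| - 0.5) / sqrt(n*p0*(1-p0)); used for the
    question whether trans-significant transcripts outnumber cis-significant
    ones beyond an even split. Returns (z, p).
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    if n_total <= 0 or not 0 <= n_success <= n_total:
        raise ValueError("need 0 <= n_success <= n_total with n_total > 0")
    dev = n_success - n_total * p0
    se = np.sqrt(n_total * p0 * (1.0 - p0))
    z = float(np.sign(dev) * (abs(dev) - 0.5) / se)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def binomial_symmetry_test(n_up: int, n_down: int) -> float:
    """Exact two-sided binomial test of up- vs down-regulated counts at p=0.5."""
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be nonnegative")
    n = n_up + n_down
    if n == 0:
        return 1.0
    return float(stats.binomtest(n_up, n, 0.5, alternative="two-sided").pvalue)


def effect_size_comparison(
    trans_effects, ase_effects
) -> tuple[float, float, float]:
    """Compare |log2| effect-size distributions of trans vs cis (ASE) sets.

    Two-sided rank-sum test: exact enumeration when both groups have at most
    10 observations and the pooled values are tie-free, otherwise the normal
    approximation with tie correction. Returns (median_trans, median_ase, p).
    """
    x = np.asarray(trans_effects, dtype=float)
    y = np.asarray(ase_effects, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both effect-size groups must be nonempty")
    pooled = np.concatenate([x, y])
    exact_ok = x.size <= 10 and y.size <= 10 and np.unique(pooled).size == pooled.size
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(np.median(x)), float(np.median(y)), float(min(res.pvalue, 1.0))
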
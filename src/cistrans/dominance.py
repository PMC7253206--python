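"""Additive effect, dominance effect, and degree of dominance.

For a trait (or a gene's normalized expression) with per-genotype medians W
(wild), C (cultivated) and F1 (hybrid):

    a = (W - C) / 2          additive effect
    d = F1 - (W + C) / 2     dominance deviation from midparent
    k = d / a                degree of dominance

On this scale k = 0 is additivity, k = 1 means the cultivated pattern is
completely recessive (hybrid equals wild), k = -1 completely dominant, and
|k| > 1.25 is transgressive (hybrid outside the parental range by margin).
The additivity interval is open (-0.25, 0.25); the partial-dominance bands
are closed at 0.25 and 1.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("cistrans")

A_EPSILON = 1e-9   # |a| below this leaves k undefined rather than infinite

MODES = (
    "additive",
    "C-partially-recessive",
    "C-partially-dominant",
    "transgressive",
    "undefined",
)


@dataclass
class DominanceRecord:
    id: str
    W: float
    C: float
    F1: float
    a: float
    d: float
    k: float          # NaN when |a| < epsilon
    mode: str


def classify_inheritance(k: float) -> str:
    """Inheritance bin for a degree of dominance.

    additive: -0.25 < k < 0.25; C partially recessive: 0.25 <= k <= 1.25;
    C partially dominant: -1.25 <= k <= -0.25; transgressive: |k| > 1.25;
    NaN: undefined.
    """
    if k is None or np.isnan(k):
        return "undefined"
    if -0.25 < k < 0.25:
        return "additive"
    if 0.25 <= k <= 1.25:
        return "C-partially-recessive"
    if -1.25 <= k <= -0.25:
        return "C-partially-dominant"
    return "transgressive"


def degree_of_dominance(
    W: float, C: float, F1: float, id: str = "trait", epsilon: float = A_EPSILON
) -> DominanceRecord:
    """Compute a, d and k from per-genotype medians.

    k is undefined (NaN, mode 'undefined') when the additive effect is below
    ``epsilon`` in magnitude, which avoids infinities for equal parents.
    """
    a = (W - C) / 2.0
    d = F1 - (W + C) / 2.0
    k = d / a if abs(a) >= epsilon else float("nan")
    return DominanceRecord(id, W, C, F1, a, d, k, classify_inheritance(k))


def genotype_medians(
    counts: pd.DataFrame, genotypes: pd.Series, size_factors: pd.Series | None = None
) -> pd.DataFrame:
    """Per-gene median of normalized counts within each genotype group."""
    norm = counts / size_factors if size_factors is not None else counts.astype(float)
    out = {}
    for geno, samples in genotypes.groupby(genotypes).groups.items():
        out[geno] = norm[list(samples)].median(axis=1)
    return pd.DataFrame(out)


def dominance_for_degs(
    de: pd.DataFrame, medians: pd.DataFrame, hybrid_col: str = "CxW"
) -> pd.DataFrame:
    """Dominance records for the differentially expressed genes only.

    ``de`` must carry a boolean ``significant`` column (parental test at the
    chosen FDR); ``medians`` the per-genotype normalized medians with columns
    W, C and the hybrid. Genes with undefined k stay in the table (mode
    'undefined') but are excluded from k-distribution summaries.
    """
    degs = de.index[de["significant"]]
    degs = degs.intersection(medians.index)
    records = [
        degree_of_dominance(
            medians.at[g, "W"], medians.at[g, "C"], medians.at[g, hybrid_col], id=str(g)
        )
        for g in degs
    ]
    table = pd.DataFrame(
        {
            "gene_id": [r.id for r in records],
            "W": [r.W for r in records],
            "C": [r.C for r in records],
            "F1": [r.F1 for r in records],
            "a": [r.a for r in records],
            "d": [r.d for r in records],
            "k": [r.k for r in records],
            "mode": [r.mode for r in records],
        }
    ).set_index("gene_id")
    n_undef = int(table["k"].isna().sum())
    if n_undef:
        logger.info("dominance: %d DEGs with undefined k (|a| ~ 0)", n_undef)
    return table


def k_histogram(records: pd.DataFrame, bin_edges=None) -> pd.DataFrame:
    """Histogram table of the k distribution (finite k only), for export."""
    k = records["k"].dropna()
    if bin_edges is None:
        bin_edges = np.arange(-3.0, 3.25, 0.25)
    counts, edges = np.histogram(k.clip(bin_edges[0], bin_edges[-1]), bins=bin_edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def k_effect_correlation(records: pd.DataFrame, de: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation between |k| and |log2fc| over DEGs.

    A negative sign reproduces the qualitative pattern that near-additive
    genes (k near zero) show the largest parental expression differences.
    """
    joined = records.join(de["log2fc"], how="inner").dropna(subset=["k", "log2fc"])
    if len(joined) < 3:
        raise ValueError("need at least 3 genes with finite k and log2fc")
    rho, p = stats.spearmanr(joined["k"].abs(), joined["log2fc"].abs())
    return float(rho), float(p)


def mode_counts(records: pd.DataFrame) -> dict[str, int]:
    vc = records["mode"].value_counts()
    return {m: int(vc.get(m, 0)) for m in MODES}
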
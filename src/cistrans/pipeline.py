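"""End-to-end orchestration: simulate/extract -> tests -> classify -> report.

The pipeline wires the stages together on either simulated input or
extracted allele counts: low-expression filtering, normalization, parental
differential expression, the cis and trans likelihood-ratio tests, category
assignment, dominance of expression, and the study-level statistics
(binomial up/down symmetry, cis-vs-trans proportion z, rank-sum comparison
of effect sizes). Every filter logs its in/out counts and the run report is
a plain JSON-serializable dictionary, byte-identical for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ase, classify, de, dominance, simulate

logger = logging.getLogger("cistrans")


def setup_logging(logfile=None, level=logging.INFO) -> None:
    logger.setLevel(level)
    logger.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(stream)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
        logger.addHandler(fh)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the study's printed defaults."""

    alpha_fdr: float = 0.05
    low_expression_threshold: int = 5
    low_expression_rule: str = "any"
    qual_min: float = 30.0
    dp_min: int = 20
    depth_reciprocity_mode: str = "exact"
    depth_rel_tol: float = 0.1
    k_bin_edges: tuple[float, float] = (0.25, 1.25)
    effect_bin_edges: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, float("inf"))
    pseudocount: float = 0.5
    seed: int = 0
    # simulation block (used when no extracted profile is supplied)
    n_genes: int = 1000
    n_replicates: int = 3
    baseline_log2_mean: float = 8.0
    dispersion: float = 0.05
    cis_effect_log2: float = 2.0
    trans_effect_log2: float = 2.0
    trans_dominance: float = 0.0
    category_mix: dict = field(default_factory=lambda: dict(simulate.DEFAULT_MIX))

    def __post_init__(self):
        if self.alpha_fdr <= 0 or self.low_expression_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not self.k_bin_edges[0] < self.k_bin_edges[1]:
            raise ValueError("k bin edges must be increasing")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def simulation_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(
            n_genes=self.n_genes,
            baseline_log2_mean=self.baseline_log2_mean,
            dispersion=self.dispersion,
            n_replicates=self.n_replicates,
            category_mix=dict(self.category_mix),
            cis_effect_log2=self.cis_effect_log2,
            trans_effect_log2=self.trans_effect_log2,
            trans_dominance=self.trans_dominance,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def total_count_matrix(profile: ase.AlleleCountProfile) -> de.CountMatrix:
    """Per-library total counts with genotype metadata (W, C, CxW).

    F0 libraries are the parents themselves; the two allele channels of each
    F1 library are summed to its total expression.
    """
    totals = profile.library_totals()
    meta_rows = {}
    for lib in totals.columns:
        parts = lib.split("_")
        if parts[0] == "F0":
            meta_rows[lib] = {"genotype": parts[2], "replicate": parts[1]}
        else:
            meta_rows[lib] = {"genotype": "CxW", "replicate": parts[1]}
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    return de.CountMatrix(totals, meta)


def extract_profile(
    vcf_pairs: dict[str, dict[str, Path]],
    gene_map: ase.GeneIntervalMap,
    cfg: PipelineConfig,
) -> ase.AlleleCountProfile:
    """VCF pairs per replicate -> filtered, gene-aggregated F1 allele counts."""
    records: list[ase.SnpPairRecord] = []
    for rep, paths in sorted(vcf_pairs.items()):
        records.extend(
            ase.pair_vcf_views(paths["cview"], paths["wview"], rep, gene_map)
        )
    kept = ase.reciprocity_filter(
        records,
        shared_positions_only=True,
        qual_min=cfg.qual_min,
        dp_min=cfg.dp_min,
    )
    return ase.aggregate_to_genes(
        kept, depth_mode=cfg.depth_reciprocity_mode, rel_tol=cfg.depth_rel_tol
    )


def _nan_to_none(x):
    if isinstance(x, float) and np.isnan(x):
        return None
    return x


def run_pipeline(
    cfg: PipelineConfig,
    profile: ase.AlleleCountProfile | None = None,
    outdir: Path | None = None,
) -> dict:
    """Execute the full analysis and return the run report dictionary.

    With no ``profile``, allele counts are simulated under ``cfg`` and truth-
    based recovery statistics are appended to the report. Writes the calls,
    dominance and report files when ``outdir`` is given.
    """
    truth = None
    if profile is None:
        logger.info("simulating %d genes (seed=%d)", cfg.n_genes, cfg.seed)
        profile, truth = simulate.simulate_ase_counts(cfg.simulation_config())

    # -- filtering on total expression ---------------------------------
    totals = total_count_matrix(profile)
    filtered = de.filter_low_expression(
        totals, threshold=cfg.low_expression_threshold, rule=cfg.low_expression_rule
    )
    genes = filtered.counts.index
    profile = ase.AlleleCountProfile(profile.counts.loc[genes])

    # -- allele-level tests and classification -------------------------
    size_factors = profile.size_factors()
    calls = classify.classify_all(
        profile, alpha=cfg.alpha_fdr, pseudocount=cfg.pseudocount,
        size_factors=size_factors,
    )
    counts_by_cat = classify.category_counts(calls)

    # -- parental DE on library totals and dominance -------------------
    de_table = de.parental_de(filtered, alpha_fdr=cfg.alpha_fdr)
    lib_sf = de.size_factors_median_ratios(filtered.counts)
    medians = dominance.genotype_medians(
        filtered.counts, filtered.meta["genotype"], lib_sf
    )
    dom = dominance.dominance_for_degs(de_table, medians)
    finite_k = dom["k"].dropna()

    # -- study-level statistics ----------------------------------------
    sig = de_table[de_table["significant"]]
    n_up_c = int((sig["log2fc"] < 0).sum())    # upregulated in C == W/C fold < 0
    n_down_c = int((sig["log2fc"] > 0).sum())
    p_binom = classify.binomial_symmetry_test(n_up_c, n_down_c)

    n_trans_sig = sum(
        counts_by_cat[c]
        for c in ("trans_only", "cis_plus_trans", "cis_by_trans", "compensatory")
    )
    n_cis_sig = sum(
        counts_by_cat[c]
        for c in ("cis_only", "cis_plus_trans", "cis_by_trans", "compensatory")
    )
    if n_trans_sig + n_cis_sig > 0:
        z_prop, p_prop = classify.proportion_test(
            n_trans_sig, n_trans_sig + n_cis_sig, 0.5
        )
    else:
        z_prop, p_prop = float("nan"), float("nan")

    trans_mask = calls["q_trans"] < cfg.alpha_fdr
    cis_mask = calls["q_cis"] < cfg.alpha_fdr
    if trans_mask.any() and cis_mask.any():
        med_trans, med_ase, p_rank = classify.effect_size_comparison(
            calls.loc[trans_mask, "trans_component"].abs(),
            calls.loc[cis_mask, "cis_component"].abs(),
        )
    else:
        med_trans = med_ase = p_rank = float("nan")

    bins = classify.cis_percentage_bins(calls, cfg.effect_bin_edges)

    report = {
        "n_genes_input": int(totals.counts.shape[0]),
        "n_genes_tested": int(len(calls)),
        "category_counts": counts_by_cat,
        "n_parental_degs": int(de_table["significant"].sum()),
        "deg_up_in_C": n_up_c,
        "deg_down_in_C": n_down_c,
        "binomial_symmetry_p": p_binom,
        "n_trans_significant": n_trans_sig,
        "n_cis_significant": n_cis_sig,
        "proportion_z": _nan_to_none(z_prop),
        "proportion_p": _nan_to_none(p_prop),
        "trans_effect_median": _nan_to_none(med_trans),
        "ase_effect_median": _nan_to_none(med_ase),
        "effect_comparison_p": _nan_to_none(p_rank),
        "cis_percentage_bins": {
            str(interval): {
                "mean_cis_percentage": _nan_to_none(float(row["mean_cis_percentage"])),
                "n_genes": int(row["n_genes"]),
            }
            for interval, row in bins.iterrows()
        },
        "k_summary": {
            "n_degs": int(len(dom)),
            "n_finite_k": int(finite_k.size),
            "median_k": _nan_to_none(float(finite_k.median()) if finite_k.size else float("nan")),
            "mode_counts": dominance.mode_counts(dom),
        },
        "seed": cfg.seed,
    }

    if truth is not None:
        joined = calls.join(truth, how="inner")
        recov = {}
        for cat in simulate.CATEGORIES:
            sel = joined["true_category"] == cat
            if sel.any():
                recov[cat] = float((joined.loc[sel, "category"] == cat).mean())
        report["per_category_recall"] = recov
        cons = joined["true_category"] == "conserved"
        if cons.any():
            divergent = ~joined.loc[cons, "category"].isin(["conserved", "ambiguous"])
            report["conserved_false_divergence_rate"] = float(divergent.mean())

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        calls.to_csv(outdir / "regulatory_calls.tsv", sep="\t")
        de_table.to_csv(outdir / "parental_de.tsv", sep="\t")
        dom.to_csv(outdir / "dominance.tsv", sep="\t")
        if truth is not None:
            truth.to_csv(outdir / "simulation_truth.tsv", sep="\t")
        write_report(report, outdir / "report.json")
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
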
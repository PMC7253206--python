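"""Synthetic data with the statistical structure of an F1-hybrid ASE study.

Three generators cover the pipeline's inputs: (1) gene-level allele-specific
NB2 counts for two parents (F0) and their hybrid (F1) with configurable cis
(c) and trans (t) log2 effects and ground-truth category labels; (2) paired
pseudoreference SNP calls with reciprocal heterozygous genotypes and mirrored
allele depths, plus an adjustable contaminated fraction violating the filter
rules; (3) per-fruit morphometric tables with a prescribed degree of
dominance.

Generative model for counts (size factor s_j, baseline log2 mean m0):

    F0  wild parent:        mu = s_j * 2**(m0 + (c+t)/2)
    F0  cultivated parent:  mu = s_j * 2**(m0 - (c+t)/2)
    F1  wild allele:        mu = s_j * 2**(m0 - 1 + c/2 + k_t*t/4)
    F1  cultivated allele:  mu = s_j * 2**(m0 - 1 - c/2 + k_t*t/4)

so the expected parental log2 ratio is c+t and the expected hybrid allelic
log2 ratio is c; ``k_t`` (``trans_dominance``, 0 = additive) shifts the
hybrid's shared trans environment toward one parent. Counts are NB2
(gamma-Poisson) with dispersion phi; phi = 0 is exact Poisson. One master
seed spawns per-gene substreams, so draws do not depend on gene order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .ase import AlleleCountProfile, SnpPairRecord

CATEGORIES = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_by_trans",
    "compensatory",
)

# Default category mix mirrors the study's classified set: of 3,346 genes with
# an interpretable label, ~69.9% conserved, 1.4% cis-only, 27.0% trans-only,
# 0.6% cis+trans, 0.6% cis-by-trans, 0.5% compensatory.
DEFAULT_MIX = {
    "conserved": 0.699,
    "cis_only": 0.014,
    "trans_only": 0.270,
    "cis_plus_trans": 0.006,
    "cis_by_trans": 0.006,
    "compensatory": 0.005,
}

MEAN_FLOOR = 1e-8


@dataclass
class SimulationConfig:
    """Parameters of the allele-specific count generator."""

    n_genes: int = 1000
    baseline_log2_mean: float = 8.0
    dispersion: float = 0.05
    n_replicates: int = 3
    library_size_factors: np.ndarray | None = None  # one per library (3*n_replicates)
    category_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    cis_effect_log2: float = 2.0
    trans_effect_log2: float = 2.0
    trans_dominance: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ValueError("n_genes and n_replicates must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if not -1.25 <= self.trans_dominance <= 1.25:
            raise ValueError("trans_dominance must lie in [-1.25, 1.25]")
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in mix: {sorted(unknown)}")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix must sum to 1 (got {total})")
        n_lib = 3 * self.n_replicates
        if self.library_size_factors is None:
            self.library_size_factors = np.ones(n_lib)
        else:
            self.library_size_factors = np.asarray(self.library_size_factors, float)
            if self.library_size_factors.shape != (n_lib,):
                raise ValueError(f"need {n_lib} library size factors")
            if (self.library_size_factors <= 0).any():
                raise ValueError("library size factors must be positive")


def _category_effects(category: str, cfg: SimulationConfig, sign: int) -> tuple[float, float]:
    """Signed (cis, trans) log2 effects for a truth category.

    Compensatory genes cancel exactly (t = -c). cis-by-trans genes oppose
    without cancelling — an exactly cancelling pair *is* the compensatory
    category — so their trans magnitude is set to twice the configured one,
    keeping the parental divergence (|c + t| = |c|) and the interaction both
    strongly detectable.
    """
    ce, te = cfg.cis_effect_log2, cfg.trans_effect_log2
    if category == "conserved":
        return 0.0, 0.0
    if category == "cis_only":
        return sign * ce, 0.0
    if category == "trans_only":
        return 0.0, sign * te
    if category == "cis_plus_trans":
        return sign * ce, sign * te
    if category == "cis_by_trans":
        return sign * ce, -sign * te * 2.0
    if category == "compensatory":
        return sign * ce, -sign * ce
    raise ValueError(f"unknown category {category!r}")


def _apportion(mix: dict[str, float], n: int) -> list[str]:
    """Largest-remainder apportionment of n genes over the category mix."""
    cats = [c for c in CATEGORIES if mix.get(c, 0.0) > 0]
    raw = np.array([mix[c] * n for c in cats])
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    labels = []
    for c, k in zip(cats, counts):
        labels.extend([c] * int(k))
    return labels


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.maximum(mu, MEAN_FLOOR)
    if phi == 0.0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    return rng.poisson(lam)


def simulate_ase_counts(
    config: SimulationConfig,
) -> tuple[AlleleCountProfile, pd.DataFrame]:
    """Generate the allele-resolved count profile and its ground truth.

    Returns the profile (F0 parental libraries plus F1 allele channels) and a
    truth table with per-gene category, signed c and t, and the expected
    parental (c+t) and hybrid allelic (c) log2 ratios. Deterministic for a
    fixed seed; draws use per-gene substreams of the master seed.
    """
    cfg = config
    n, reps = cfg.n_genes, cfg.n_replicates
    master = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    substreams = np.random.SeedSequence(cfg.seed).spawn(n + 1)
    # substream 0 handles gene-independent choices (category order, signs)
    meta_rng = np.random.default_rng(substreams[0])

    labels = np.array(_apportion(cfg.category_mix, n))
    meta_rng.shuffle(labels)
    signs = meta_rng.choice([-1, 1], size=n)

    sf = cfg.library_size_factors
    sf_f0w, sf_f0c, sf_f1 = sf[:reps], sf[reps : 2 * reps], sf[2 * reps :]
    m0, ktd = cfg.baseline_log2_mean, cfg.trans_dominance

    rows = np.empty((n, 4 * reps), dtype=np.int64)
    truth_rows = []
    for g in range(n):
        c, t = _category_effects(labels[g], cfg, int(signs[g]))
        rng = np.random.default_rng(substreams[g + 1])
        mu_f0w = sf_f0w * 2.0 ** (m0 + (c + t) / 2.0)
        mu_f0c = sf_f0c * 2.0 ** (m0 - (c + t) / 2.0)
        mu_f1w = sf_f1 * 2.0 ** (m0 - 1.0 + c / 2.0 + ktd * t / 4.0)
        mu_f1c = sf_f1 * 2.0 ** (m0 - 1.0 - c / 2.0 + ktd * t / 4.0)
        mus = np.concatenate([mu_f0w, mu_f0c, mu_f1w, mu_f1c])
        rows[g] = _nb_draw(rng, mus, cfg.dispersion)
        truth_rows.append(
            {
                "gene_id": f"gene{g:05d}",
                "true_category": labels[g],
                "c": c,
                "t": t,
                "expected_parental_log2fc": c + t,
                "expected_hybrid_allelic_log2fc": c,
            }
        )

    rep_ids = [f"rep{i + 1}" for i in range(reps)]
    columns = pd.MultiIndex.from_tuples(
        [("F0", r, "W") for r in rep_ids]
        + [("F0", r, "C") for r in rep_ids]
        + [("F1", r, "W") for r in rep_ids]
        + [("F1", r, "C") for r in rep_ids]
    )
    counts = pd.DataFrame(
        rows, index=[f"gene{g:05d}" for g in range(n)], columns=columns
    ).sort_index(axis=1)
    counts.index.name = "gene_id"
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return AlleleCountProfile(counts), truth


# ---------------------------------------------------------------------------
# SNP-pair fixtures
# ---------------------------------------------------------------------------

_NUCS = np.array(["A", "C", "G", "T"])
_VIOLATIONS = ("not_reciprocal", "homozygous", "low_qual", "low_dp")


def _gene_interval(g: int) -> tuple[str, int, int]:
    """Deterministic 0-based half-open interval for simulated gene g."""
    chrom = f"chr{(g % 12) + 1}"
    start0 = (g // 12) * 2000 + 100
    return chrom, start0, start0 + 1000


def simulate_snp_pairs(
    n_genes: int,
    snps_per_gene: int = 3,
    seed: int = 0,
    contamination_rate: float = 0.0,
    n_replicates: int = 3,
) -> list[SnpPairRecord]:
    """Emit paired-view SNP records; a contaminated fraction violates the rules.

    Clean records are biallelic with reciprocal heterozygous genotypes,
    mirrored per-allele depths, QUAL > 30 and DP > 20, and the same positions
    in every replicate. Contaminated records (drawn independently per record
    with probability ``contamination_rate``) break exactly one retention
    rule: a non-reciprocal genotype, a homozygous call, QUAL <= 30, or
    DP <= 20.
    """
    if not 0.0 <= contamination_rate < 1.0:
        raise ValueError("contamination_rate must lie in [0, 1)")
    if n_genes <= 0 or snps_per_gene <= 0:
        raise ValueError("n_genes and snps_per_gene must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    records = []
    for g in range(n_genes):
        chrom, start0, end0 = _gene_interval(g)
        gene_id = f"gene{g:05d}"
        positions = start0 + 1 + rng.choice(end0 - start0, size=snps_per_gene, replace=False)
        for pos in sorted(int(p) for p in positions):
            ref_c, alt_c = rng.choice(_NUCS, size=2, replace=False)
            for rep in range(1, n_replicates + 1):
                dc, dw = rng.integers(11, 31, size=2)
                qual = float(rng.uniform(35.0, 95.0))
                dp = int(dc + dw)
                gt_c = (ref_c, alt_c)
                gt_w = (alt_c, ref_c)
                ad_c = (int(dc), int(dw))
                ad_w = (int(dw), int(dc))
                if rng.random() < contamination_rate:
                    mode = rng.choice(_VIOLATIONS)
                    if mode == "not_reciprocal":
                        gt_w = (ref_c, alt_c)
                    elif mode == "homozygous":
                        gt_c = (ref_c, ref_c)
                        gt_w = (alt_c, alt_c)
                        ad_c, ad_w = (dp, 0), (dp, 0)
                    elif mode == "low_qual":
                        qual = float(rng.uniform(5.0, 30.0))
                    elif mode == "low_dp":
                        ad_c, ad_w = (7, 8), (8, 7)
                        dp = 15
                records.append(
                    SnpPairRecord(
                        chrom=chrom, pos=pos, gene_id=gene_id,
                        ref_cview=str(ref_c), alt_cview=str(alt_c),
                        ref_wview=str(alt_c), alt_wview=str(ref_c),
                        genotype_cview=gt_c, genotype_wview=gt_w,
                        allele_depths_cview=ad_c, allele_depths_wview=ad_w,
                        qual=qual, dp=dp, replicate_id=f"rep{rep}",
                    )
                )
    return records


def write_gene_bed(n_genes: int, path) -> None:
    """BED4 intervals matching :func:`simulate_snp_pairs` gene placement."""
    with open(path, "w") as fh:
        for g in range(n_genes):
            chrom, start0, end0 = _gene_interval(g)
            fh.write(f"{chrom}\t{start0}\t{end0}\tgene{g:05d}\n")


def write_snp_vcfs(records: list[SnpPairRecord], outdir) -> dict[str, dict[str, Path]]:
    """Write per-replicate C-view and W-view VCF 4.2 files (GT, AD, DP).

    Returns ``{replicate: {"cview": path, "wview": path}}``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_rep: dict[str, list[SnpPairRecord]] = {}
    for rec in records:
        by_rep.setdefault(rec.replicate_id, []).append(rec)
    chroms = sorted({r.chrom for r in records}, key=lambda c: (len(c), c))

    paths: dict[str, dict[str, Path]] = {}
    for rep, recs in sorted(by_rep.items()):
        paths[rep] = {}
        for view in ("cview", "wview"):
            header = pysam.VariantHeader()
            header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
            header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
            header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
            for chrom in chroms:
                header.contigs.add(chrom, length=10_000_000)
            header.add_sample("F1")
            path = outdir / f"F1_{rep}_{view}.vcf"
            with pysam.VariantFile(str(path), "w", header=header) as vf:
                for rec in sorted(recs, key=lambda r: (chroms.index(r.chrom), r.pos)):
                    ref = rec.ref_cview if view == "cview" else rec.ref_wview
                    alt = rec.alt_cview if view == "cview" else rec.alt_wview
                    gt = rec.genotype_cview if view == "cview" else rec.genotype_wview
                    ad = rec.allele_depths_cview if view == "cview" else rec.allele_depths_wview
                    out = vf.new_record(
                        contig=rec.chrom, start=rec.pos - 1, stop=rec.pos,
                        alleles=(ref, alt), qual=round(rec.qual, 2),
                    )
                    idx = {ref: 0, alt: 1}
                    out.samples["F1"]["GT"] = (idx[gt[0]], idx[gt[1]])
                    out.samples["F1"]["AD"] = list(ad)
                    out.samples["F1"]["DP"] = rec.dp
                    vf.write(out)
            paths[rep][view] = path
    return paths


# ---------------------------------------------------------------------------
# fruit morphometrics
# ---------------------------------------------------------------------------

# Realistic 40-days-post-anthesis fruit dimensions (mm / mm^2): an elongate
# cultivated "puya"-type pepper against a small, nearly spherical wild chiltepin.
DEFAULT_PARENT_MEANS = {
    "C": {"area": 1100.0, "major_axis": 85.0, "minor_axis": 16.0, "perimeter": 180.0},
    "W": {"area": 78.0, "major_axis": 11.0, "minor_axis": 9.0, "perimeter": 32.0},
}

TRAITS = ("area", "major_axis", "minor_axis", "perimeter")


def simulate_morphometrics(
    n_fruits_per_genotype: int = 20,
    parent_means: dict | None = None,
    trait_k: float = 1.0,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-fruit (area, axes, perimeter) with a prescribed dominance degree.

    Hybrid trait means sit at midparent + k*a with a = (W - C)/2, on the
    convention that k = 1 makes the cultivated parent's trait completely
    recessive (hybrid equals wild) and k in (-0.25, 0.25) is additive.
    Multiplicative lognormal noise has coefficient of variation ``noise_cv``
    and unit mean, so expected values are exact.
    """
    if n_fruits_per_genotype <= 0:
        raise ValueError("n_fruits_per_genotype must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    means = parent_means or DEFAULT_PARENT_MEANS
    for geno in ("W", "C"):
        for trait in TRAITS:
            if means[geno][trait] <= 0:
                raise ValueError(f"nonpositive {trait} for genotype {geno}")
    hybrid = {}
    for trait in TRAITS:
        w, c = means["W"][trait], means["C"][trait]
        a = (w - c) / 2.0
        hybrid[trait] = (w + c) / 2.0 + trait_k * a
        if hybrid[trait] <= 0:
            raise ValueError(f"trait_k={trait_k} drives hybrid {trait} nonpositive")
    genotype_means = {"W": means["W"], "C": means["C"], "CxW": hybrid}

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for geno in ("W", "C", "CxW"):
        for i in range(n_fruits_per_genotype):
            row = {"fruit_id": f"{geno}_{i + 1:03d}", "genotype": geno}
            for trait in TRAITS:
                noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma)) if sigma > 0 else 1.0
                row[trait] = genotype_means[geno][trait] * noise
            # measurement convention: major axis is the longer one
            if row["major_axis"] < row["minor_axis"]:
                row["major_axis"], row["minor_axis"] = row["minor_axis"], row["major_axis"]
            rows.append(row)
    return pd.DataFrame(rows).set_index("fruit_id")
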
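"""Allele-specific count extraction from paired pseudoreference SNP calls.

An F1 hybrid's reads are aligned separately to a cultivated-parent (C) and a
wild-parent (W) pseudoreference. A SNP site usable for allele-specific
expression must be biallelic, heterozygous in both alignment views, and
*reciprocal*: the ordered genotype in one view is the reversal of the other
(e.g. A/G against G/A), because each pseudoreference carries its own parent's
allele as the reference base. Per-allele read depths must likewise mirror
between views. Surviving depths are summed over SNPs of the same gene model
to yield gene-level allele counts.

Allele orientation is fixed here: in the C-pseudoreference view the ALT
allele is the wild allele (the reference base is the cultivated one), and
vice versa in the W view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

logger = logging.getLogger("cistrans")

QUAL_MIN = 30.0   # strict: QUAL > 30
DP_MIN = 20       # strict: DP > 20


# ---------------------------------------------------------------------------
# records and profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpPairRecord:
    """One SNP site observed in both pseudoreference alignments.

    Genotypes are ordered allele pairs as called in each view; allele depths
    are (ref, alt) pairs per view. ``qual`` and ``dp`` are the per-site
    minima over the two views when built from VCF pairs.
    """

    chrom: str
    pos: int                       # 1-based (VCF convention)
    gene_id: str | None
    ref_cview: str
    alt_cview: str
    ref_wview: str
    alt_wview: str
    genotype_cview: tuple[str, str]
    genotype_wview: tuple[str, str]
    allele_depths_cview: tuple[int, int]
    allele_depths_wview: tuple[int, int]
    qual: float
    dp: int
    replicate_id: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based VCF coordinate)")
        for ad in (self.allele_depths_cview, self.allele_depths_wview):
            if min(ad) < 0:
                raise ValueError("allele depths must be nonnegative")
        if sum(self.allele_depths_cview) > self.dp and self.dp > 0:
            # depths never exceed total site depth; tolerate dp==0 sentinels
            raise ValueError("allele depths exceed site depth DP")


class AlleleCountProfile:
    """Gene-level allele-resolved counts across replicates and generations.

    Wraps a genes x samples DataFrame whose columns form a MultiIndex
    ``(generation, replicate, allele)`` with generation in {F0, F1} and
    allele in {W, C}. F0 "allele" columns are the parental libraries (each
    parent contributes only its own allele); F1 columns are the two allele
    channels of one hybrid library and therefore share that library's size
    factor.
    """

    def __init__(self, counts: pd.DataFrame):
        if not isinstance(counts.columns, pd.MultiIndex) or counts.columns.nlevels != 3:
            raise ValueError("columns must be a (generation, replicate, allele) MultiIndex")
        if (counts.to_numpy() < 0).any():
            raise ValueError("allele counts must be nonnegative")
        counts = counts.copy()
        counts.columns = counts.columns.set_names(["generation", "replicate", "allele"])
        self.counts = counts

    # -- structure -----------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def library_of(self, col: tuple[str, str, str]) -> str:
        gen, rep, allele = col
        return f"{gen}_{rep}_{allele}" if gen == "F0" else f"{gen}_{rep}"

    def library_totals(self) -> pd.DataFrame:
        """Per-library total counts (F1 allele channels summed per library)."""
        libs = {}
        for col in self.counts.columns:
            libs.setdefault(self.library_of(col), []).append(col)
        return pd.DataFrame(
            {lib: self.counts[cols].sum(axis=1) for lib, cols in libs.items()}
        )

    def size_factors(self) -> pd.Series:
        """Median-of-ratios factors per library, broadcast to allele columns."""
        from .de import size_factors_median_ratios

        lib_sf = size_factors_median_ratios(self.library_totals())
        return pd.Series(
            {col: lib_sf[self.library_of(col)] for col in self.counts.columns},
            name="size_factor",
        )

    # -- IO ------------------------------------------------------------
    @staticmethod
    def _flatten(col: tuple[str, str, str]) -> str:
        gen, rep, allele = col
        return f"{gen}_{rep}_{allele}allele"

    @staticmethod
    def _unflatten(name: str) -> tuple[str, str, str]:
        gen, rep, allele = name.split("_")
        if not allele.endswith("allele"):
            raise ValueError(f"unrecognized sample column {name!r}")
        return gen, rep, allele[:-6]

    def to_tsv(self, path) -> None:
        flat = self.counts.copy()
        flat.columns = [self._flatten(c) for c in self.counts.columns]
        flat.index.name = "gene_id"
        flat.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "AlleleCountProfile":
        flat = pd.read_csv(path, sep="\t", index_col="gene_id")
        flat.columns = pd.MultiIndex.from_tuples(
            [cls._unflatten(c) for c in flat.columns]
        )
        return cls(flat)


# ---------------------------------------------------------------------------
# gene interval maps
# ---------------------------------------------------------------------------

class GeneIntervalMap:
    """SNP-position -> gene-model lookup from BED or GFF3 intervals.

    Internally 0-based half-open. Multi-gene positions resolve to the gene
    with the longest overlapping interval; ties break lexicographically by
    gene id.
    """

    def __init__(self):
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start0: int, end0: int, gene_id: str) -> None:
        if end0 <= start0:
            raise ValueError("empty interval")
        self._trees.setdefault(chrom, IntervalTree()).addi(start0, end0, gene_id)

    @classmethod
    def from_bed(cls, path) -> "GeneIntervalMap":
        gm = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
                gm.add(chrom, int(start), int(end), name)
        return gm

    @classmethod
    def from_gff3(cls, path, feature: str = "gene") -> "GeneIntervalMap":
        gm = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != feature:
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                name = attrs.get("ID") or attrs.get("Name")
                # GFF3 is 1-based inclusive
                gm.add(parts[0], int(parts[3]) - 1, int(parts[4]), name)
        return gm

    def assign(self, chrom: str, pos1: int) -> str | None:
        """Gene id covering a 1-based position, or None."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree[pos1 - 1]
        if not hits:
            return None
        # longest overlap first, then lexicographic gene id
        best = min(hits, key=lambda iv: (-(iv.end - iv.begin), iv.data))
        return best.data


# ---------------------------------------------------------------------------
# VCF pairing
# ---------------------------------------------------------------------------

def _read_vcf_view(path) -> dict[tuple[str, int], dict]:
    """Read one alignment view's SNP calls keyed by (chrom, 1-based pos)."""
    view = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            sample = rec.samples[0]
            alleles = sample.alleles
            if alleles is None or None in alleles:
                continue
            ad = sample.get("AD")
            view[(rec.chrom, rec.pos)] = {
                "ref": rec.ref,
                "alt": rec.alts[0],
                "gt": tuple(alleles),
                "ad": tuple(int(x) for x in ad[:2]) if ad is not None else (0, 0),
                "qual": float(rec.qual) if rec.qual is not None else 0.0,
                "dp": int(sample.get("DP") or 0),
            }
    return view


def pair_vcf_views(
    cview_path, wview_path, replicate_id: str, gene_map: GeneIntervalMap | None = None
) -> list[SnpPairRecord]:
    """Join the C-view and W-view VCFs of one F1 library on (chrom, pos).

    Sites present in only one view cannot be checked for reciprocity; they
    are excluded and counted in the log, not fatal. QUAL and DP are taken as
    the minimum over the two views (a site must pass in both).
    """
    cview = _read_vcf_view(cview_path)
    wview = _read_vcf_view(wview_path)
    shared = sorted(set(cview) & set(wview))
    n_orphan = len(set(cview) ^ set(wview))
    if n_orphan:
        logger.info(
            "replicate %s: %d sites present in only one alignment view (excluded)",
            replicate_id, n_orphan,
        )
    records = []
    for chrom, pos in shared:
        c, w = cview[(chrom, pos)], wview[(chrom, pos)]
        records.append(
            SnpPairRecord(
                chrom=chrom,
                pos=pos,
                gene_id=gene_map.assign(chrom, pos) if gene_map else None,
                ref_cview=c["ref"], alt_cview=c["alt"],
                ref_wview=w["ref"], alt_wview=w["alt"],
                genotype_cview=c["gt"], genotype_wview=w["gt"],
                allele_depths_cview=c["ad"], allele_depths_wview=w["ad"],
                qual=min(c["qual"], w["qual"]),
                dp=min(c["dp"], w["dp"]),
                replicate_id=replicate_id,
            )
        )
    return records


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _is_biallelic(rec: SnpPairRecord) -> bool:
    nt = {"A", "C", "G", "T"}
    seen = {rec.ref_cview, rec.alt_cview} | set(rec.genotype_cview) | set(rec.genotype_wview)
    return (
        len(rec.ref_cview) == 1 and len(rec.alt_cview) == 1
        and seen <= nt and len({rec.ref_cview, rec.alt_cview}) == 2
        and set(rec.genotype_cview) <= {rec.ref_cview, rec.alt_cview}
        and set(rec.genotype_wview) <= {rec.ref_cview, rec.alt_cview}
    )


def _is_heterozygous(gt: tuple[str, str]) -> bool:
    return gt[0] != gt[1]


def _is_reciprocal(rec: SnpPairRecord) -> bool:
    return rec.genotype_cview == rec.genotype_wview[::-1]


def reciprocity_filter(
    records: list[SnpPairRecord],
    shared_positions_only: bool = False,
    qual_min: float = QUAL_MIN,
    dp_min: int = DP_MIN,
) -> list[SnpPairRecord]:
    """Retain biallelic, doubly-heterozygous, reciprocal, high-quality sites.

    A record passes iff (i) the site is biallelic, (ii) both views call a
    heterozygote, (iii) the ordered genotypes are reciprocal, (iv) QUAL is
    strictly above ``qual_min`` and (v) DP strictly above ``dp_min``. With
    ``shared_positions_only`` a site must additionally appear in every
    replicate's record set. The filter is idempotent.
    """
    passing = [
        r for r in records
        if _is_biallelic(r)
        and _is_heterozygous(r.genotype_cview)
        and _is_heterozygous(r.genotype_wview)
        and _is_reciprocal(r)
        and r.qual > qual_min
        and r.dp > dp_min
    ]
    if shared_positions_only and passing:
        replicates = {r.replicate_id for r in passing}
        by_site: dict[tuple[str, int], set] = {}
        for r in passing:
            by_site.setdefault((r.chrom, r.pos), set()).add(r.replicate_id)
        passing = [
            r for r in passing if by_site[(r.chrom, r.pos)] == replicates
        ]
    logger.info(
        "reciprocity filter: %d of %d records retained", len(passing), len(records)
    )
    return passing


def depth_reciprocity_check(
    rec: SnpPairRecord, mode: str = "exact", rel_tol: float = 0.1
) -> bool:
    """True iff per-allele depths mirror between the two alignment views.

    ``exact`` requires the C-view (ref, alt) pair to equal the reversed
    W-view pair. ``tolerant`` allows a relative deviation up to ``rel_tol``
    per allele (relative to the larger of the two depths), since alignment
    to two different pseudoreferences rarely yields identical depths.
    """
    a = rec.allele_depths_cview
    b = rec.allele_depths_wview[::-1]
    if mode == "exact":
        return a == b
    if mode != "tolerant":
        raise ValueError("mode must be 'exact' or 'tolerant'")
    for x, y in zip(a, b):
        if x == y == 0:
            continue
        if abs(x - y) / max(x, y) > rel_tol:
            return False
    return True


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_to_genes(
    records: list[SnpPairRecord],
    depth_mode: str = "exact",
    rel_tol: float = 0.1,
) -> AlleleCountProfile:
    """Sum per-allele depths over SNPs of the same gene model (F1 profile).

    Depth-reciprocity failures and gene-unassigned SNPs are dropped (counted
    in the log). The C-view orientation is canonical: its REF depth is the
    cultivated-allele count and its ALT depth the wild-allele count. Genes
    with no surviving SNP are absent from the output, not zero-filled.
    """
    sums: dict[tuple[str, str, str], dict[str, int]] = {}
    n_unmapped = n_depth_fail = 0
    for rec in records:
        if rec.gene_id is None:
            n_unmapped += 1
            continue
        if not depth_reciprocity_check(rec, mode=depth_mode, rel_tol=rel_tol):
            n_depth_fail += 1
            continue
        c_depth, w_depth = rec.allele_depths_cview
        cell = sums.setdefault((rec.gene_id, rec.replicate_id, "W"), {})
        cell["n"] = cell.get("n", 0) + w_depth
        cell = sums.setdefault((rec.gene_id, rec.replicate_id, "C"), {})
        cell["n"] = cell.get("n", 0) + c_depth
    if n_unmapped or n_depth_fail:
        logger.info(
            "aggregation: %d SNPs without gene assignment, %d failing depth reciprocity (dropped)",
            n_unmapped, n_depth_fail,
        )
    if not sums:
        raise ValueError("no records survived aggregation")
    series = pd.Series({k: v["n"] for k, v in sums.items()})
    table = series.unstack(level=[1, 2]).fillna(0).astype(int)
    table.columns = pd.MultiIndex.from_tuples(
        [("F1", rep, allele) for rep, allele in table.columns]
    )
    table = table.sort_index(axis=1)
    table.index.name = "gene_id"
    return AlleleCountProfile(table)


def combine_with_parents(
    f1_profile: AlleleCountProfile, parental: pd.DataFrame, meta: pd.DataFrame
) -> AlleleCountProfile:
    """Join F1 allele counts with parental libraries as F0 allele sources.

    Each W-parent library contributes that gene's F0 wild-allele counts and
    each C-parent library the cultivated-allele counts. Only genes present in
    both tables are kept.
    """
    cols = {}
    for sample in parental.columns:
        geno = meta.loc[sample, "genotype"]
        rep = str(meta.loc[sample, "replicate"])
        if geno in ("W", "C"):
            cols[("F0", rep, geno)] = parental[sample]
    f0 = pd.DataFrame(cols)
    common = f1_profile.genes.intersection(f0.index)
    merged = pd.concat(
        [f0.loc[common], f1_profile.counts.loc[common]], axis=1
    ).sort_index(axis=1)
    return AlleleCountProfile(merged)
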
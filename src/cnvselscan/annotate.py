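"""Gene assignment and genomic feature-type classification of CNVs.

Each CNV gets exactly one category by the precedence order used by common
variant annotators:

    exonic > splicing > UTR5 > UTR3 > ncRNA_exonic > ncRNA_intronic >
    intronic > upstream/downstream (both -> upstream_and_downstream) >
    intergenic

A splicing call means the CNV touches a 2 bp splice site (the first or last
two bases of an intron) without touching an exon. Upstream/downstream means
within ``flank_bp`` (default 1 kb) of a gene end, respecting strand, without
overlapping any gene body. Gene ASSIGNMENT (used by the candidate filter)
is gene-body overlap only, no flank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import GeneFeature, SVRecord

CATEGORIES = (
    "exonic",
    "splicing",
    "UTR5",
    "UTR3",
    "ncRNA_exonic",
    "ncRNA_intronic",
    "intronic",
    "upstream",
    "downstream",
    "upstream_and_downstream",
    "intergenic",
)

_PRECEDENCE = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass
class FeatureCall:
    variant_id: str
    category: str
    genes: list[str] = field(default_factory=list)


class GeneIndex:
    """Interval-tree lookup over gene bodies and sub-features.

    Trees store 0-based half-open intervals internally (the intervaltree
    convention); the 1-based inclusive boundary conversion happens here.
    """

    def __init__(self, features: Sequence[GeneFeature], flank_bp: int = 1000):
        self.flank_bp = flank_bp
        self.genes: dict[str, GeneFeature] = {}
        self.subfeatures: dict[str, list[GeneFeature]] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        for f in features:
            if f.feature_kind in ("gene", "ncRNA_gene"):
                self.genes[f.gene_id] = f
                self._gene_trees.setdefault(f.chrom, IntervalTree()).addi(
                    f.start - 1, f.end, f
                )
            else:
                self.subfeatures.setdefault(f.gene_id, []).append(f)

    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[GeneFeature]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start - 1, end)]
        return sorted(hits, key=lambda g: g.gene_id)

    def assign_genes(self, variant: SVRecord) -> list[str]:
        """All gene ids whose body overlaps [pos, end] by >= 1 bp."""
        return [
            g.gene_id
            for g in self.overlapping_genes(variant.chrom, variant.pos, variant.end)
        ]


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def _introns(gene: GeneFeature, exons: list[GeneFeature]) -> list[tuple[int, int]]:
    """Intervals between consecutive exon-like features inside the gene."""
    if not exons:
        return []
    ex = sorted((e.start, e.end) for e in exons)
    out = []
    for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
        if s2 > e1 + 1:
            out.append((e1 + 1, s2 - 1))
    return out


def _classify_against_gene(
    variant: SVRecord, gene: GeneFeature, subs: list[GeneFeature]
) -> str:
    """Category of a variant that overlaps this gene's body."""
    vs, ve = variant.pos, variant.end
    if gene.feature_kind == "ncRNA_gene":
        ncx = [f for f in subs if f.feature_kind == "ncRNA_exon"]
        if any(_overlaps(vs, ve, f.start, f.end) for f in ncx):
            return "ncRNA_exonic"
        return "ncRNA_intronic"
    exons = [f for f in subs if f.feature_kind in ("exon", "CDS")]
    utr5 = [f for f in subs if f.feature_kind == "five_prime_UTR"]
    utr3 = [f for f in subs if f.feature_kind == "three_prime_UTR"]
    if any(_overlaps(vs, ve, f.start, f.end) for f in exons):
        return "exonic"
    exonic_like = exons + utr5 + utr3
    for i_s, i_e in _introns(gene, exonic_like):
        donor = (i_s, min(i_s + 1, i_e))
        acceptor = (max(i_e - 1, i_s), i_e)
        if _overlaps(vs, ve, *donor) or _overlaps(vs, ve, *acceptor):
            return "splicing"
    if any(_overlaps(vs, ve, f.start, f.end) for f in utr5):
        return "UTR5"
    if any(_overlaps(vs, ve, f.start, f.end) for f in utr3):
        return "UTR3"
    return "intronic"


def classify_feature(
    variant: SVRecord,
    index: GeneIndex,
) -> FeatureCall:
    """Assign the single highest-precedence category for one CNV."""
    hits = index.overlapping_genes(variant.chrom, variant.pos, variant.end)
    if hits:
        cats = [
            _classify_against_gene(
                variant, g, index.subfeatures.get(g.gene_id, [])
            )
            for g in hits
        ]
        best = min(cats, key=_PRECEDENCE.__getitem__)
        return FeatureCall(variant.id, best, [g.gene_id for g in hits])

    # no gene-body overlap: flanks
    flank = index.flank_bp
    up_genes, down_genes = [], []
    vs, ve = variant.pos, variant.end
    for g in index.overlapping_genes(variant.chrom, vs - flank, ve + flank):
        if g.strand == "+":
            if ve < g.start:  # variant left of gene start = upstream on +
                up_genes.append(g.gene_id)
            elif vs > g.end:
                down_genes.append(g.gene_id)
        else:
            if vs > g.end:  # variant right of gene end = upstream on -
                up_genes.append(g.gene_id)
            elif ve < g.start:
                down_genes.append(g.gene_id)
    if up_genes and down_genes:
        return FeatureCall(
            variant.id, "upstream_and_downstream", sorted(set(up_genes + down_genes))
        )
    if up_genes:
        return FeatureCall(variant.id, "upstream", sorted(set(up_genes)))
    if down_genes:
        return FeatureCall(variant.id, "downstream", sorted(set(down_genes)))
    return FeatureCall(variant.id, "intergenic", [])


def annotate_records(
    records: Sequence[SVRecord],
    features: Sequence[GeneFeature],
    flank_bp: int = 1000,
) -> list[FeatureCall]:
    index = GeneIndex(features, flank_bp=flank_bp)
    return [classify_feature(r, index) for r in records]


def feature_summary(calls: Sequence[FeatureCall]) -> pd.Series:
    """Category -> proportion table in fixed category order, summing to 1."""
    if not calls:
        raise ValueError("no feature calls to summarise")
    counts = pd.Series(0, index=list(CATEGORIES), dtype=float)
    for c in calls:
        counts[c.category] += 1
    return counts / counts.sum()


def calls_frame(calls: Sequence[FeatureCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.variant_id for c in calls],
            "category": [c.category for c in calls],
            "genes": [",".join(c.genes) for c in calls],
        }
    )
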
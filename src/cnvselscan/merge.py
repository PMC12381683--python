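"""Population-level SV deduplication.

Two calls of the same SV type on the same chromosome are duplicates when
their reciprocal overlap meets the type-specific threshold (50% for
deletions, 90% for insertions, inversions and duplications) AND their
population genotype consistency is >= 0.95. Duplicate groups are formed by
single-linkage clustering (the convention of common SV-merging tools), so
transitive chains can join pairs that are individually sub-threshold —
documented behaviour. Each cluster is collapsed to one representative
taking the component-wise median breakpoints (ties: lower) and the
per-sample majority genotype over non-missing member calls (ties or
all-missing: missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Genotype, SVRecord


@dataclass(frozen=True)
class MergeThresholds:
    del_overlap: float = 0.5
    other_overlap: float = 0.9
    gt_consistency: float = 0.95
    ins_breakpoint_bp: int = 100  # INS: breakpoint distance criterion

    def __post_init__(self) -> None:
        for v in (self.del_overlap, self.other_overlap, self.gt_consistency):
            if not 0.0 < v <= 1.0:
                raise ValueError("thresholds must lie in (0, 1]")


@dataclass
class MergedVariant:
    representative: SVRecord
    members: list[str]

    @property
    def support(self) -> int:
        return len(self.members)


def reciprocal_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> float:
    """min(shared/len(a), shared/len(b)) for 1-based inclusive intervals;
    0 for disjoint intervals or different chromosomes."""
    ca, sa, ea = a
    cb, sb, eb = b
    if ea < sa or eb < sb:
        raise ValueError("zero-length interval")
    if ca != cb:
        return 0.0
    shared = min(ea, eb) - max(sa, sb) + 1
    if shared <= 0:
        return 0.0
    return min(shared / (ea - sa + 1), shared / (eb - sb + 1))


def genotype_concordance(a: SVRecord, b: SVRecord) -> float:
    """Fraction of samples non-missing in both records with identical
    genotype; 1.0 when no sample is comparable."""
    ga, gb = a.genotypes, b.genotypes
    if ga.size != gb.size:
        raise ValueError("records come from different panels")
    comparable = (ga != Genotype.MISSING) & (gb != Genotype.MISSING)
    n = int(comparable.sum())
    if n == 0:
        return 1.0
    return float(np.sum(ga[comparable] == gb[comparable]) / n)


def _is_duplicate(a: SVRecord, b: SVRecord, thr: MergeThresholds) -> bool:
    if a.chrom != b.chrom or a.svtype != b.svtype:
        return False
    if a.svtype == "INS":
        # reciprocal overlap is undefined for near-zero-span insertions:
        # use breakpoint proximity plus length similarity instead.
        if abs(a.pos - b.pos) > thr.ins_breakpoint_bp:
            return False
        la, lb = abs(a.svlen), abs(b.svlen)
        if max(la, lb) == 0:
            ratio = 1.0
        else:
            ratio = min(la, lb) / max(la, lb)
        if ratio < thr.other_overlap:
            return False
    else:
        t = thr.del_overlap if a.svtype == "DEL" else thr.other_overlap
        ro = reciprocal_overlap(
            (a.chrom, a.pos, a.end), (b.chrom, b.pos, b.end)
        )
        if ro < t:
            return False
    return genotype_concordance(a, b) >= thr.gt_consistency


def _low_median(values: Sequence[int]) -> int:
    """Median taking the lower of the two middle values for even counts."""
    v = sorted(values)
    return v[(len(v) - 1) // 2]


def _majority_genotypes(members: Sequence[SVRecord]) -> np.ndarray:
    g = np.vstack([m.genotypes for m in members])
    n_samples = g.shape[1]
    out = np.full(n_samples, Genotype.MISSING, dtype=np.int8)
    for j in range(n_samples):
        col = g[:, j]
        col = col[col != Genotype.MISSING]
        if col.size == 0:
            continue
        vals, counts = np.unique(col, return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        out[j] = winners[0] if winners.size == 1 else Genotype.MISSING
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_population(
    records: Sequence[SVRecord],
    thresholds: MergeThresholds | None = None,
) -> list[MergedVariant]:
    """Single-linkage deduplication within each (chrom, svtype) stratum.

    Output is sorted by (chrom, pos) and invariant to input order.
    """
    thr = thresholds or MergeThresholds()
    if records:
        sizes = {r.genotypes.size for r in records}
        if len(sizes) != 1:
            raise ValueError("records carry mixed panel sizes")

    strata: dict[tuple[str, str], list[SVRecord]] = {}
    for r in records:
        strata.setdefault((r.chrom, r.svtype), []).append(r)

    merged: list[MergedVariant] = []
    for key in sorted(strata):
        recs = sorted(strata[key], key=lambda r: (r.pos, r.end, r.id))
        n = len(recs)
        uf = _UnionFind(n)
        max_span = max(r.span for r in recs)
        reach = max(max_span, thr.ins_breakpoint_bp + 1)
        # sorted sweep: only records whose starts are within the largest
        # span (or the INS breakpoint radius) can satisfy the predicate
        for i in range(n):
            for j in range(i + 1, n):
                if recs[j].pos - recs[i].pos > reach:
                    break
                if _is_duplicate(recs[i], recs[j], thr):
                    uf.union(i, j)
        clusters: dict[int, list[int]] = {}
        for i in range(n):
            clusters.setdefault(uf.find(i), []).append(i)
        for root in sorted(clusters):
            members = [recs[i] for i in clusters[root]]
            pos = _low_median([m.pos for m in members])
            end = _low_median([m.end for m in members])
            svlen = _low_median([m.svlen for m in members])
            rep_id = sorted(m.id for m in members)[0]
            rep = SVRecord(
                rep_id, members[0].chrom, pos, max(pos, end),
                members[0].svtype, svlen, _majority_genotypes(members),
            )
            merged.append(
                MergedVariant(rep, sorted(m.id for m in members))
            )
    merged.sort(key=lambda m: (m.representative.chrom, m.representative.pos,
                               m.representative.id))
    return merged


def merge_report_frame(merged: Sequence[MergedVariant]):
    """Merge-report table: cluster id, member ids, support."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cluster_id": [m.representative.id for m in merged],
            "members": [",".join(m.members) for m in merged],
            "support": [m.support for m in merged],
        }
    )
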
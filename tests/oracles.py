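"""Independent oracle implementations used only by the test suite.

Each oracle recomputes a statistic through a deliberately different route
(scalar longhand transcription, exact integer enumeration, brute-force
double loops) so that agreement with the package is a meaningful check,
not a tautology.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def wc_longhand(counts_1: tuple[int, int, int], counts_2: tuple[int, int, int]):
    """Weir & Cockerham (1984) variance components for two diploid samples,
    transcribed scalar-by-scalar from the original notation."""
    n1 = counts_1[0] + counts_1[1] + counts_1[2]
    n2 = counts_2[0] + counts_2[1] + counts_2[2]
    if n1 == 0 or n2 == 0:
        return None
    p1 = (counts_1[1] + 2 * counts_1[2]) / (2 * n1)
    p2 = (counts_2[1] + 2 * counts_2[2]) / (2 * n2)
    h1 = counts_1[1] / n1
    h2 = counts_2[1] / n2
    r = 2
    n_bar = (n1 + n2) / r
    if n_bar <= 1:
        return None
    n_c = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    if n_c == 0:
        return None
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s_sq = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)

    a = (n_bar / n_c) * (
        s_sq
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s_sq - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s_sq
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    if a + b + c == 0:
        return None
    return a, b, c


def pi_pairwise_bruteforce(n: int, alt: int) -> Fraction:
    """Mean pairwise difference over all C(n, 2) allele pairs, by counting."""
    diff = sum(
        1
        for i, j in itertools.combinations(range(n), 2)
        if (i < alt) != (j < alt)
    )
    return Fraction(diff, math.comb(n, 2))


def exchet_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Exact excess-het p-value by exhaustive enumeration of heterozygote
    counts with the same allele counts, in exact rational arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return Fraction(1)
    weights = {}
    for k in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - k) // 2
        hom_major = n - k - hom_minor
        weights[k] = (
            Fraction(math.factorial(n))
            / (
                math.factorial(hom_minor)
                * math.factorial(k)
                * math.factorial(hom_major)
            )
            * 2**k
        )
    total = sum(weights.values())
    return sum(w for k, w in weights.items() if k >= n_het) / total


def fisher_two_sided_enumeration(table) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration
    with exact integer weights: sum the probabilities of all tables with
    the same margins whose probability does not exceed the observed one."""
    (a, b), (c, d) = table
    r1, r2, k = a + b, c + d, a + c
    lo, hi = max(0, k - r2), min(k, r1)
    weights = {x: math.comb(r1, x) * math.comb(r2, k - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(weights.values())
    return float(
        Fraction(sum(w for w in weights.values() if w <= w_obs), total)
    )


def chi2_2x2_longhand(table, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table with optional Yates continuity
    correction, from the textbook formula, with the p-value from the
    chi-square survival function."""
    from scipy.stats import chi2 as chi2_dist

    t = np.asarray(table, dtype=float)
    n = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / n
            d = abs(t[i, j] - e)
            if yates:
                d = max(0.0, d - 0.5)
            stat += d * d / e
    return stat, float(chi2_dist.sf(stat, df=1))


def grm_double_loop(genotype_matrix: np.ndarray) -> np.ndarray:
    """VanRaden GRM by explicit double loops; missing coded as -1."""
    g = genotype_matrix.astype(float).T.copy()  # samples x variants
    g[g == -1] = np.nan
    n, m_all = g.shape
    freqs = []
    cols = []
    for j in range(m_all):
        col = g[:, j]
        p = np.nanmean(col) / 2.0
        if p <= 0 or p >= 1:
            continue
        filled = np.where(np.isnan(col), 2 * p, col)
        cols.append(filled)
        freqs.append(p)
    m = len(cols)
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for k in range(m):
                p = freqs[k]
                s += (
                    (cols[k][i] - 2 * p)
                    * (cols[k][j] - 2 * p)
                    / (2 * p * (1 - p))
                )
            G[i, j] = s / m
    return G


def connected_components_bruteforce(records, thresholds):
    """Cluster ids via explicit pairwise predicate graph + BFS, with the
    duplicate predicate re-derived from interval arithmetic in place."""
    n = len(records)

    def dup(x, y):
        if x.chrom != y.chrom or x.svtype != y.svtype:
            return False
        if x.svtype == "INS":
            if abs(x.pos - y.pos) > thresholds.ins_breakpoint_bp:
                return False
            la, lb = abs(x.svlen), abs(y.svlen)
            ok_len = (min(la, lb) / max(la, lb) if max(la, lb) else 1.0)
            if ok_len < thresholds.other_overlap:
                return False
        else:
            shared = min(x.end, y.end) - max(x.pos, y.pos) + 1
            if shared <= 0:
                return False
            ro = min(shared / (x.end - x.pos + 1), shared / (y.end - y.pos + 1))
            need = (
                thresholds.del_overlap if x.svtype == "DEL"
                else thresholds.other_overlap
            )
            if ro < need:
                return False
        ga, gb = x.genotypes, y.genotypes
        comp = [(p, q) for p, q in zip(ga, gb) if p != -1 and q != -1]
        conc = (
            sum(1 for p, q in comp if p == q) / len(comp) if comp else 1.0
        )
        return conc >= thresholds.gt_consistency

    adj = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if dup(records[i], records[j]):
                adj[i].append(j)
                adj[j].append(i)
    comp_id = [-1] * n
    cid = 0
    for i in range(n):
        if comp_id[i] != -1:
            continue
        stack = [i]
        comp_id[i] = cid
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if comp_id[v] == -1:
                    comp_id[v] = cid
                    stack.append(v)
        cid += 1
    groups: dict[int, frozenset] = {}
    for i, c in enumerate(comp_id):
        groups.setdefault(c, set()).add(records[i].id)
    return {frozenset(g) for g in groups.values()}


def classify_bruteforce(variant, features, flank_bp=1000):
    """Feature-category oracle: evaluate every category predicate
    independently over the flat feature list, then apply the precedence
    ladder."""
    vs, ve = variant.pos, variant.end

    def hits(kind_set, pad=0):
        return [
            f for f in features
            if f.chrom == variant.chrom
            and f.feature_kind in kind_set
            and f.start - pad <= ve and vs <= f.end + pad
        ]

    genes = hits({"gene"})
    nc_genes = hits({"ncRNA_gene"})
    exons = [f for f in hits({"exon", "CDS"})
             if any(g.gene_id == f.gene_id for g in genes)]
    if exons:
        return "exonic"
    # splice sites: 2 bp ends of every gap between exon-like features
    for g in genes:
        exl = sorted(
            (f.start, f.end) for f in features
            if f.gene_id == g.gene_id
            and f.feature_kind in ("exon", "CDS", "five_prime_UTR",
                                   "three_prime_UTR")
        )
        for (s1, e1), (s2, e2) in zip(exl, exl[1:]):
            if s2 <= e1 + 1:
                continue
            i_s, i_e = e1 + 1, s2 - 1
            for site in ((i_s, min(i_s + 1, i_e)), (max(i_e - 1, i_s), i_e)):
                if site[0] <= ve and vs <= site[1]:
                    return "splicing"
    if any(f.gene_id in {g.gene_id for g in genes}
           for f in hits({"five_prime_UTR"})):
        return "UTR5"
    if any(f.gene_id in {g.gene_id for g in genes}
           for f in hits({"three_prime_UTR"})):
        return "UTR3"
    if nc_genes:
        nx = [f for f in hits({"ncRNA_exon"})
              if any(g.gene_id == f.gene_id for g in nc_genes)]
        return "ncRNA_exonic" if nx else "ncRNA_intronic"
    if genes:
        return "intronic"
    up = down = False
    for f in features:
        if f.feature_kind not in ("gene", "ncRNA_gene") or f.chrom != variant.chrom:
            continue
        if f.start - flank_bp <= ve and vs <= f.end + flank_bp:
            before = ve < f.start
            after = vs > f.end
            if (f.strand == "+" and before) or (f.strand == "-" and after):
                up = True
            elif (f.strand == "+" and after) or (f.strand == "-" and before):
                down = True
    if up and down:
        return "upstream_and_downstream"
    if up:
        return "upstream"
    if down:
        return "downstream"
    return "intergenic"
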
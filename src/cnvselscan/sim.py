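"""Synthetic two-population deletion-CNV cohorts with known differentiation.

The generator emulates the output of a short-read SV-calling and population
genotyping workflow on a two-group cohort (HL vs LL, 15 + 15 diploids by
default): a genotyped biallelic deletion callset with Hardy–Weinberg
structure within each group and Balding–Nichols differentiation between
them, i.i.d. genotype missingness, and an optional planted low-diversity /
high-differentiation region to exercise the selection scan. It also
fragments a truth callset into jittered per-individual callsets (for merge
testing) and lays down toy gene models (for annotation testing).

Under the Balding–Nichols model each group's allele frequency at a site is
drawn Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p, so the
parameter F is the expected Weir–Cockerham FST between the groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import GeneFeature, Genotype, SamplePanel, SVRecord


@dataclass(frozen=True)
class SweepSpec:
    """A planted differentiated region: every variant falling inside
    [start, end] on ``chrom`` takes deletion-allele frequency ``hl_freq``
    in HL and ``ll_freq`` in LL instead of its neutral draw."""

    chrom: str
    start: int
    end: int
    hl_freq: float
    ll_freq: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("sweep start must be < end")
        for f in (self.hl_freq, self.ll_freq):
            if not 0.0 <= f <= 1.0:
                raise ValueError("sweep frequencies must lie in [0, 1]")


@dataclass
class SimConfig:
    """Study-design parameters for one simulated cohort.

    Defaults mirror the study design: 15 HL + 15 LL diploid individuals and
    deletion-only variants with lengths log-uniform on [1 kb, 100 kb] (most
    mass at short lengths, with a tail that exercises the length filter).
    Ancestral frequencies are Beta(0.8, 0.8) truncated to [0.05, 0.95].
    """

    n_hl: int = 15
    n_ll: int = 15
    n_variants: int = 1000
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 30_000_000})
    target_fst: float = 0.05
    anc_beta: tuple[float, float] = (0.8, 0.8)
    anc_trunc: tuple[float, float] = (0.05, 0.95)
    length_range: tuple[int, int] = (1_000, 100_000)
    missing_rate: float = 0.0
    sweep: SweepSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hl < 1 or self.n_ll < 1:
            raise ValueError("each group needs at least one sample")
        if not 0.0 <= self.target_fst <= 0.99:
            raise ValueError("target_fst must lie in [0, 0.99]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.sweep is not None:
            L = self.chrom_lengths.get(self.sweep.chrom)
            if L is None or self.sweep.end > L:
                raise ValueError("sweep region outside chrom_lengths")


def draw_pop_freqs(
    anc_freq: float, target_fst: float, seed: int | np.random.Generator
) -> tuple[float, float]:
    """Draw one (p_hl, p_ll) pair under the Balding–Nichols model.

    For ``target_fst`` = 0 the Beta collapses to a point mass and both
    groups keep the ancestral frequency exactly.
    """
    if not 0.0 < anc_freq < 1.0:
        raise ValueError("anc_freq must lie strictly inside (0, 1)")
    if not 0.0 <= target_fst < 1.0:
        raise ValueError("target_fst must lie in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if target_fst == 0.0:
        return anc_freq, anc_freq
    scale = (1.0 - target_fst) / target_fst
    a, b = anc_freq * scale, (1.0 - anc_freq) * scale
    return float(rng.beta(a, b)), float(rng.beta(a, b))


def _place_intervals(
    lengths: np.ndarray, chrom_len: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly place non-overlapping intervals of given lengths; returns
    sorted 1-based start positions. Stick-breaking: distribute the free
    space between intervals uniformly."""
    total = int(lengths.sum())
    free = chrom_len - total
    if free < 0:
        raise ValueError("genome too small for the requested variants")
    gaps = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])]) + 1
    return starts


def simulate_genotype_matrix(config: SimConfig) -> tuple[list[SVRecord], SamplePanel, "pd.DataFrame"]:
    """Simulate the genotyped deletion callset for one cohort.

    Returns the records (sorted by position), the sample panel, and a truth
    table (variant id, p_hl, p_ll, in_sweep). Identical configs produce
    identical output.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    samples = [f"HL{i+1:02d}" for i in range(config.n_hl)] + [
        f"LL{i+1:02d}" for i in range(config.n_ll)
    ]
    group = {s: ("HL" if s.startswith("HL") else "LL") for s in samples}
    panel = SamplePanel(samples, group)

    # allocate variant counts per chromosome proportional to length
    chroms = sorted(config.chrom_lengths)
    lens = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(config.n_variants * lens / lens.sum()).astype(int)
    for i in np.argsort(-(config.n_variants * lens / lens.sum() - alloc)):
        if alloc.sum() >= config.n_variants:
            break
        alloc[i] += 1

    lo, hi = config.length_range
    records: list[SVRecord] = []
    truth_rows = []
    k = 0
    for c, n_c in zip(chroms, alloc):
        if n_c == 0:
            continue
        svlens = np.exp(
            rng.uniform(np.log(lo), np.log(hi), size=n_c)
        ).astype(int)
        order = rng.permutation(n_c)  # decouple placement from length order
        svlens = svlens[order]
        starts = _place_intervals(svlens, config.chrom_lengths[c], rng)
        for pos, L in zip(starts, svlens):
            pos, L = int(pos), int(L)
            lo_t, hi_t = config.anc_trunc
            while True:
                anc = rng.beta(*config.anc_beta)
                if lo_t <= anc <= hi_t:
                    break
            p_hl, p_ll = draw_pop_freqs(anc, config.target_fst, rng)
            in_sweep = (
                config.sweep is not None
                and c == config.sweep.chrom
                and config.sweep.start <= pos <= config.sweep.end
            )
            if in_sweep:
                p_hl, p_ll = config.sweep.hl_freq, config.sweep.ll_freq
            g_hl = rng.binomial(2, p_hl, size=config.n_hl)
            g_ll = rng.binomial(2, p_ll, size=config.n_ll)
            gts = np.concatenate([g_hl, g_ll]).astype(np.int8)
            if config.missing_rate > 0:
                miss = rng.random(panel.n) < config.missing_rate
                gts[miss] = Genotype.MISSING
            rid = f"cnv_{k:05d}"
            k += 1
            records.append(
                SVRecord(rid, c, pos, pos + L - 1, "DEL", -L, gts)
            )
            truth_rows.append((rid, p_hl, p_ll, in_sweep))

    truth = pd.DataFrame(truth_rows, columns=["id", "p_hl", "p_ll", "in_sweep"])
    return records, panel, truth


def fragment_to_callsets(
    truth: Sequence[SVRecord],
    jitter_bp: int = 0,
    dropout: float = 0.0,
    seed: int = 0,
) -> dict[int, list[SVRecord]]:
    """Fragment a truth callset into noisy per-individual callsets.

    For each sample carrying a variant (het or hom-alt) a copy of the record
    is emitted, breakpoints translated by a uniform offset within
    +/- jitter_bp (capped at 50% of the variant span so that true duplicates
    stay mergeable) and dropped with probability ``dropout``. The emitted
    record's genotype vector carries only that sample's call; all other
    samples are missing. Keyed by panel sample index.
    """
    if jitter_bp < 0:
        raise ValueError("jitter_bp must be >= 0")
    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_samples = truth[0].genotypes.size if truth else 0
    out: dict[int, list[SVRecord]] = {i: [] for i in range(n_samples)}
    for rec in truth:
        j = min(jitter_bp, rec.span // 2)
        carriers = np.nonzero(rec.genotypes > 0)[0]
        for s in carriers:
            if dropout > 0 and rng.random() < dropout:
                continue
            delta = int(rng.integers(-j, j + 1)) if j > 0 else 0
            gts = np.full(n_samples, Genotype.MISSING, dtype=np.int8)
            gts[s] = rec.genotypes[s]
            out[int(s)].append(
                SVRecord(
                    f"{rec.id}_s{s}", rec.chrom, rec.pos + delta,
                    rec.end + delta, rec.svtype, rec.svlen, gts,
                )
            )
    return out


def simulate_annotation(
    chrom_lengths: dict[str, int],
    n_genes: int,
    seed: int = 0,
    gene_fraction: float = 0.2,
    ncrna_fraction: float = 0.1,
    n_exons: int = 4,
) -> list[GeneFeature]:
    """Place non-overlapping toy gene models covering ``gene_fraction`` of
    the genome.

    Genes are equal-length and uniformly placed; each coding gene carries a
    5' UTR, ``n_exons`` exons separated by introns, and a 3' UTR (strand
    chosen at random). A fraction of genes are emitted as ncRNA genes with
    ncRNA_exon sub-features instead. Deterministic under ``seed``.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_genes == 0:
        return []
    rng = np.random.default_rng(seed)
    total = sum(chrom_lengths.values())
    gene_len = max(200, int(gene_fraction * total / n_genes))
    chroms = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(n_genes * lens / lens.sum()).astype(int)
    for i in np.argsort(-(n_genes * lens / lens.sum() - alloc)):
        if alloc.sum() >= n_genes:
            break
        alloc[i] += 1

    feats: list[GeneFeature] = []
    gi = 0
    for c, n_c in zip(chroms, alloc):
        if n_c == 0:
            continue
        if n_c * gene_len > chrom_lengths[c]:
            raise ValueError("genome too small to place the requested genes")
        starts = _place_intervals(
            np.full(n_c, gene_len), chrom_lengths[c], rng
        )
        for s in starts:
            s = int(s)
            e = s + gene_len - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene_{gi:04d}"
            gi += 1
            if rng.random() < ncrna_fraction:
                feats.append(GeneFeature(c, s, e, strand, gid, "ncRNA_gene"))
                # two ncRNA exons at the gene ends
                exon_len = max(50, gene_len // 5)
                feats.append(GeneFeature(c, s, s + exon_len - 1, strand, gid, "ncRNA_exon"))
                feats.append(GeneFeature(c, e - exon_len + 1, e, strand, gid, "ncRNA_exon"))
                continue
            feats.append(GeneFeature(c, s, e, strand, gid, "gene"))
            utr5_len = max(20, gene_len // 20)
            utr3_len = max(30, gene_len // 15)
            body_s, body_e = s + utr5_len, e - utr3_len
            if strand == "+":
                feats.append(GeneFeature(c, s, s + utr5_len - 1, strand, gid, "five_prime_UTR"))
                feats.append(GeneFeature(c, e - utr3_len + 1, e, strand, gid, "three_prime_UTR"))
            else:
                feats.append(GeneFeature(c, s, s + utr5_len - 1, strand, gid, "three_prime_UTR"))
                feats.append(GeneFeature(c, e - utr3_len + 1, e, strand, gid, "five_prime_UTR"))
            body_len = body_e - body_s + 1
            exon_len = max(30, int(0.3 * body_len) // n_exons)
            intron_len = (body_len - n_exons * exon_len) // max(1, n_exons - 1)
            pos = body_s
            for x in range(n_exons):
                feats.append(GeneFeature(c, pos, pos + exon_len - 1, strand, gid, "exon"))
                pos += exon_len + intron_len
    return feats
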
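"""Per-site and sliding-window population-genetic statistics.

FST is the Weir & Cockerham (1984) estimator for two populations of
diploids, computed from per-group sample sizes, allele frequencies and
observed heterozygosities as the three variance components: among
populations (a), among individuals within populations (b) and within
individuals (c). Windowed FST is the weighted "ratio of sums"
sum(a) / sum(a+b+c) over the sites in each window — the standard output of
windowed VCF scans and robust to low-information sites.

Nucleotide diversity per site is the unbiased mean pairwise difference
2 p (1-p) n/(n-1) over n non-missing alleles; windowed diversity divides
the summed site values by the window's genomic span (clipped windows by
their actual span). The between-group contrast is log2(pi_HL / pi_LL),
defined only when both diversities are positive.

Sliding windows are 100 kb with a 10 kb step by default; a variant
contributes to a window iff its start breakpoint (POS) lies inside it, so
windows are independent of variant length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Genotype, SamplePanel, SVRecord


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window layout over a genome."""

    window_size: int = 100_000
    step: int = 10_000
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")
        if self.step <= 0:
            raise ValueError("step must be positive")

    def windows(self, chrom: str) -> np.ndarray:
        """(n, 2) array of 1-based inclusive [start, end] windows; starts at
        1, 1+step, ...; the trailing windows are clipped at the chromosome
        end."""
        L = self.chrom_lengths[chrom]
        starts = np.arange(1, L + 1, self.step, dtype=np.int64)
        ends = np.minimum(starts + self.window_size - 1, L)
        return np.column_stack([starts, ends])


def site_wc_components(
    counts_by_group: Sequence[tuple[int, int, int]],
) -> tuple[float, float, float] | None:
    """Weir–Cockerham variance components (a, b, c) for one site.

    ``counts_by_group`` holds (n_hom_ref, n_het, n_hom_alt) per group over
    non-missing genotypes. Returns None (site skipped) when any group has
    no genotyped sample, when fewer than two chromosomes are sampled per
    group on average, or when the site is monomorphic (a+b+c = 0).
    """
    n_i = np.array([sum(c) for c in counts_by_group], dtype=float)
    if np.any(n_i == 0):
        return None
    r = len(counts_by_group)
    if r < 2:
        raise ValueError("need at least two groups")
    p_i = np.array(
        [(c[1] + 2 * c[2]) / (2 * n) for c, n in zip(counts_by_group, n_i)]
    )
    h_i = np.array([c[1] / n for c, n in zip(counts_by_group, n_i)])

    nbar = n_i.mean()
    if nbar <= 1.0:
        return None
    nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
    if nc == 0:
        return None
    pbar = np.sum(n_i * p_i) / (r * nbar)
    s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
    hbar = np.sum(n_i * h_i) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    if a + b + c == 0:
        return None
    return float(a), float(b), float(c)


def site_pi(allele_total: int, alt_count: int) -> float:
    """Unbiased per-site nucleotide diversity (mean pairwise difference)."""
    n = allele_total
    if n < 2:
        raise ValueError("need at least two alleles")
    if not 0 <= alt_count <= n:
        raise ValueError("alt_count outside [0, n]")
    p = alt_count / n
    return 2.0 * p * (1.0 - p) * n / (n - 1)


def _group_counts(g: np.ndarray, idx: np.ndarray) -> tuple[int, int, int]:
    sub = g[idx]
    return (
        int(np.sum(sub == Genotype.HOM_REF)),
        int(np.sum(sub == Genotype.HET)),
        int(np.sum(sub == Genotype.HOM_ALT)),
    )


def site_table(records: Sequence[SVRecord], panel: SamplePanel) -> pd.DataFrame:
    """Per-site statistics: WC components, per-site FST and per-group pi.

    Sites where the FST estimator is undefined carry NaN components (they
    are skipped in windowed sums, with the skip visible as the NaN); pi for
    a group is NaN when fewer than two alleles were genotyped there.
    """
    hl, ll = panel.hl_indices, panel.ll_indices
    rows = []
    for r in records:
        c_hl = _group_counts(r.genotypes, hl)
        c_ll = _group_counts(r.genotypes, ll)
        comp = None
        if sum(c_hl) > 0 and sum(c_ll) > 0:
            comp = site_wc_components([c_hl, c_ll])
        a, b, c = comp if comp is not None else (np.nan, np.nan, np.nan)
        fst = a / (a + b + c) if comp is not None else np.nan

        def _pi(cnt):
            n = 2 * sum(cnt)
            if n < 2:
                return np.nan
            return site_pi(n, cnt[1] + 2 * cnt[2])

        rows.append(
            (r.id, r.chrom, r.pos, a, b, c, fst, _pi(c_hl), _pi(c_ll))
        )
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "pos", "wc_a", "wc_b", "wc_c", "fst_site",
                 "pi_hl_site", "pi_ll_site"],
    )


def window_table(
    records: Sequence[SVRecord],
    panel: SamplePanel,
    grid: WindowGrid,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sliding-window FST, per-group per-bp diversity, and log2 ratio.

    One row per window: chrom, start, end, n_sites, fst, pi_hl, pi_ll,
    log2_ratio. FST is NaN for windows without a usable site; pi is 0 for
    empty windows; the log2 ratio is NaN unless both diversities are
    positive. NaN-statistic windows are excluded from quantile ranking
    downstream.
    """
    if sites is None:
        sites = site_table(records, panel)
    out = []
    for chrom in sorted(grid.chrom_lengths):
        sub = sites[sites["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        a = np.nan_to_num(sub["wc_a"].to_numpy(), nan=0.0)
        abc = np.nan_to_num(
            (sub["wc_a"] + sub["wc_b"] + sub["wc_c"]).to_numpy(), nan=0.0
        )
        pi_hl = np.nan_to_num(sub["pi_hl_site"].to_numpy(), nan=0.0)
        pi_ll = np.nan_to_num(sub["pi_ll_site"].to_numpy(), nan=0.0)
        ca = np.concatenate([[0.0], np.cumsum(a)])
        cabc = np.concatenate([[0.0], np.cumsum(abc)])
        chl = np.concatenate([[0.0], np.cumsum(pi_hl)])
        cll = np.concatenate([[0.0], np.cumsum(pi_ll)])
        wins = grid.windows(chrom)
        lo = np.searchsorted(pos, wins[:, 0], side="left")
        hi = np.searchsorted(pos, wins[:, 1], side="right")
        for (start, end), i0, i1 in zip(wins, lo, hi):
            n_sites = int(i1 - i0)
            span = int(end - start + 1)
            sa = ca[i1] - ca[i0]
            sabc = cabc[i1] - cabc[i0]
            fst = sa / sabc if sabc > 0 else np.nan
            whl = (chl[i1] - chl[i0]) / span
            wll = (cll[i1] - cll[i0]) / span
            ratio = (
                np.log2(whl / wll) if (whl > 0 and wll > 0) else np.nan
            )
            out.append((chrom, int(start), int(end), n_sites, fst, whl, wll, ratio))
    return pd.DataFrame(
        out,
        columns=["chrom", "start", "end", "n_sites", "fst", "pi_hl", "pi_ll",
                 "log2_ratio"],
    )


def windowed_fst(
    records: Sequence[SVRecord], panel: SamplePanel, grid: WindowGrid
) -> pd.DataFrame:
    """Per-window weighted FST (subset of :func:`window_table` columns)."""
    return window_table(records, panel, grid)[
        ["chrom", "start", "end", "n_sites", "fst"]
    ]


def windowed_pi(
    records: Sequence[SVRecord],
    panel: SamplePanel,
    grid: WindowGrid,
    group: str,
) -> pd.DataFrame:
    """Per-window per-bp diversity for one group ("HL" or "LL")."""
    col = {"HL": "pi_hl", "LL": "pi_ll"}[group]
    tab = window_table(records, panel, grid)
    return tab[["chrom", "start", "end", "n_sites", col]].rename(
        columns={col: "pi"}
    )


def log2_pi_ratio(pi_hl: float, pi_ll: float) -> float:
    """log2(pi_hl / pi_ll); NaN (window excluded from ranking) unless both
    diversities are positive — no finite value exists otherwise."""
    if pi_hl > 0 and pi_ll > 0:
        return float(np.log2(pi_hl / pi_ll))
    return float("nan")


def genomewide_fst(records: Sequence[SVRecord], panel: SamplePanel) -> float:
    """Weighted (ratio of sums) FST over all usable sites."""
    sites = site_table(records, panel)
    a = sites["wc_a"].sum(skipna=True)
    abc = (sites["wc_a"] + sites["wc_b"] + sites["wc_c"]).sum(skipna=True)
    return float(a / abc)
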
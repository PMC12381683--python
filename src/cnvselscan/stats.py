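"""Cohort-level distribution statistics and GRM-based PCA.

Frequency spectra bin per-group deletion-allele frequencies into ten bins
[0,0.1), ..., [0.9,1.0]; bins are compared between the groups with
two-sided Fisher exact tests. The per-chromosome distribution contrast is a
2x2 chi-square (on-chromosome vs off-chromosome presence counts by group,
Yates-corrected by default) with a Bonferroni correction over the
chromosomes actually tested. Population structure uses a VanRaden-style
genetic relationship matrix from frequency-standardised genotype dosages,
eigendecomposed into principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Genotype, SamplePanel, SVRecord

BIN_EDGES = np.round(np.arange(0.0, 1.1, 0.1), 10)
N_BINS = 10


@dataclass
class FrequencySpectrum:
    counts_hl: np.ndarray  # length 10
    counts_ll: np.ndarray
    n_undefined_hl: int = 0
    n_undefined_ll: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": BIN_EDGES[:-1],
                "bin_high": BIN_EDGES[1:],
                "count_hl": self.counts_hl.astype(int),
                "count_ll": self.counts_ll.astype(int),
            }
        )


def _group_freq(g: np.ndarray, idx: np.ndarray) -> float:
    sub = g[idx]
    called = sub[sub != Genotype.MISSING]
    if called.size == 0:
        return float("nan")
    return float(called.sum() / (2 * called.size))


def group_frequencies(
    records: Sequence[SVRecord], panel: SamplePanel
) -> pd.DataFrame:
    """Per-variant deletion-allele frequency in each group over non-missing
    alleles; NaN when a group is entirely missing at the variant."""
    hl, ll = panel.hl_indices, panel.ll_indices
    rows = [
        (r.id, _group_freq(r.genotypes, hl), _group_freq(r.genotypes, ll))
        for r in records
    ]
    return pd.DataFrame(rows, columns=["id", "freq_hl", "freq_ll"])


def freq_bin(freq: float) -> int:
    """Bin index for half-open bins [x, x+0.1), last bin closed at 1.0."""
    return min(int(freq * 10), N_BINS - 1)


def frequency_spectrum(freqs: pd.DataFrame) -> FrequencySpectrum:
    spec = FrequencySpectrum(
        np.zeros(N_BINS, dtype=int), np.zeros(N_BINS, dtype=int)
    )
    for col, counts, undef in (
        ("freq_hl", spec.counts_hl, "n_undefined_hl"),
        ("freq_ll", spec.counts_ll, "n_undefined_ll"),
    ):
        vals = freqs[col]
        setattr(spec, undef, int(vals.isna().sum()))
        for f in vals.dropna():
            counts[freq_bin(float(f))] += 1
    return spec


def chrom_distribution_tests(
    records: Sequence[SVRecord],
    panel: SamplePanel,
    alpha: float = 0.05,
    yates: bool = True,
) -> pd.DataFrame:
    """Per-chromosome 2x2 chi-square of CNV presence by group.

    A variant is "present" in a group when its deletion-allele count there
    is at least one. Chromosomes with zero presence in both groups are
    skipped; the Bonferroni multiplier is the number of tests performed.
    """
    hl, ll = panel.hl_indices, panel.ll_indices
    per_chrom: dict[str, list[int]] = {}
    tot_hl = tot_ll = 0
    for r in records:
        p_hl = int(np.any(r.genotypes[hl] > 0))
        p_ll = int(np.any(r.genotypes[ll] > 0))
        c = per_chrom.setdefault(r.chrom, [0, 0])
        c[0] += p_hl
        c[1] += p_ll
        tot_hl += p_hl
        tot_ll += p_ll

    rows = []
    tested = []
    for chrom in sorted(per_chrom):
        on_hl, on_ll = per_chrom[chrom]
        if on_hl + on_ll == 0:
            continue
        table = np.array(
            [[on_hl, tot_hl - on_hl], [on_ll, tot_ll - on_ll]]
        )
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = sps.chi2_contingency(table, correction=yates)
        tested.append(chrom)
        rows.append((chrom, on_hl, on_ll, float(chi2), float(p)))
    k = len(tested)
    out = pd.DataFrame(
        rows, columns=["chrom", "present_hl", "present_ll", "chi2", "p"]
    )
    out["p_bonferroni"] = np.minimum(out["p"] * k, 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out


def bin_fisher_tests(spectrum: FrequencySpectrum) -> pd.DataFrame:
    """Two-sided Fisher exact test per frequency bin (in-bin vs out-of-bin
    by group). A bin empty in both groups yields p = 1 by convention."""
    tot_hl = int(spectrum.counts_hl.sum())
    tot_ll = int(spectrum.counts_ll.sum())
    if tot_hl + tot_ll == 0:
        raise ValueError("empty spectrum")
    rows = []
    for i in range(N_BINS):
        a, c = int(spectrum.counts_hl[i]), int(spectrum.counts_ll[i])
        if a + c == 0:
            rows.append((BIN_EDGES[i], BIN_EDGES[i + 1], a, c, np.nan, 1.0))
            continue
        table = [[a, tot_hl - a], [c, tot_ll - c]]
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        rows.append((BIN_EDGES[i], BIN_EDGES[i + 1], a, c, float(odds), float(p)))
    return pd.DataFrame(
        rows,
        columns=["bin_low", "bin_high", "count_hl", "count_ll", "odds_ratio", "p"],
    )


def dosage_matrix(records: Sequence[SVRecord]) -> np.ndarray:
    """(n_samples, n_variants) float dosage matrix; missing -> NaN."""
    g = np.vstack([r.genotypes for r in records]).T.astype(float)
    g[g == Genotype.MISSING] = np.nan
    return g


def grm(records: Sequence[SVRecord]) -> np.ndarray:
    """VanRaden-style genetic relationship matrix.

    Dosages are mean-imputed per variant, centred at 2p and scaled by
    sqrt(2p(1-p)); monomorphic variants are dropped. G = Z Z' / m.
    """
    d = dosage_matrix(records)
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not np.any(poly):
        raise ValueError("no polymorphic variants")
    d = d[:, poly]
    p = p[poly]
    mean = 2.0 * p
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    z = (d - mean) / np.sqrt(2.0 * p * (1.0 - p))
    m = z.shape[1]
    return z @ z.T / m


def grm_pca(
    records: Sequence[SVRecord],
    panel: SamplePanel,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the GRM.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue), sign-fixed so
    the largest-magnitude loading of each component is positive. Returns
    (per-sample coordinate table, variance-explained fractions).
    """
    G = grm(records)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0.0, None)
    var_explained = pos[:n_components] / pos.sum()
    coords = np.zeros((panel.n, n_components))
    for k in range(n_components):
        v = evecs[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, k] = v * np.sqrt(max(evals[k], 0.0))
    df = pd.DataFrame(
        coords, columns=[f"PC{k+1}" for k in range(n_components)]
    )
    df.insert(0, "sample", panel.samples)
    df.insert(1, "group", [panel.group[s] for s in panel.samples])
    return df, var_explained
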
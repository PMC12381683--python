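"""Post-merge variant quality control.

Four filters, applied in this order, with first-failing-filter attribution:

1. length:    |SVLEN| <= 10,000,000
2. exc_het:   exact excess-heterozygosity p-value >= 0.05 (pooled cohort)
3. f_missing: missing-genotype fraction <= 0.2
4. maf:       minor allele frequency > 0 (strict)

All boundary comparisons are exactly as written (<=, >=, <=, >). MAF and
the missing fraction are recomputed from genotypes rather than trusted from
INFO, since merging may have changed them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .core import Genotype, SVRecord

_LOG2 = math.log(2.0)


@dataclass(frozen=True)
class QcThresholds:
    max_abs_svlen: int = 10_000_000
    min_exchet_p: float = 0.05
    max_f_missing: float = 0.2
    min_maf: float = 0.0  # strict: maf must be > min_maf


@dataclass
class QcReport:
    input_count: int
    removed_by_filter: dict[str, int]
    output_count: int

    def balances(self) -> bool:
        return self.input_count == self.output_count + sum(
            self.removed_by_filter.values()
        )

    def to_frame(self):
        import pandas as pd

        rows = [("input", self.input_count)]
        rows += [(f"removed_{k}", v) for k, v in self.removed_by_filter.items()]
        rows.append(("output", self.output_count))
        return pd.DataFrame(rows, columns=["stage", "count"])


def exc_het_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-sided exact Hardy–Weinberg p-value for heterozygote EXCESS.

    P(het count >= observed) under the exact conditional distribution of
    heterozygote counts given the allele counts (the enumeration of
    Wigginton, Cutler & Abecasis), computed over the pooled cohort. A
    monomorphic site (zero minor alleles) returns 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    ks = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - ks) // 2
    hom_major = n - ks - hom_minor
    logw = (
        ks * _LOG2
        - gammaln(hom_minor + 1.0)
        - gammaln(ks + 1.0)
        - gammaln(hom_major + 1.0)
    )
    w = np.exp(logw - logw.max())
    total = w.sum()
    return float(min(1.0, w[ks >= n_het].sum() / total))


def f_missing(record: SVRecord) -> float:
    """Fraction of panel samples with a missing genotype."""
    g = record.genotypes
    if g.size == 0:
        raise ValueError("empty panel")
    return float(np.sum(g == Genotype.MISSING) / g.size)


def maf(record: SVRecord) -> float:
    """Minor allele frequency over non-missing alleles; NaN if none."""
    g = record.genotypes
    called = g[g != Genotype.MISSING]
    if called.size == 0:
        return float("nan")
    p = float(called.sum() / (2 * called.size))
    return min(p, 1.0 - p)


FILTER_ORDER = ("length", "exc_het", "f_missing", "maf")


def apply_filters(
    records: Sequence[SVRecord],
    thresholds: QcThresholds | None = None,
) -> tuple[list[SVRecord], QcReport]:
    """Apply the four filters in printed order; a failing record is
    attributed to the first filter it fails. Records with every genotype
    missing (undefined MAF) get their own accounting bucket when they
    survive the missingness filter."""
    thr = thresholds or QcThresholds()
    removed = {k: 0 for k in FILTER_ORDER}
    removed["maf_undefined"] = 0
    passing: list[SVRecord] = []
    for r in records:
        if abs(r.svlen) > thr.max_abs_svlen:
            removed["length"] += 1
            continue
        counts = r.genotype_counts()
        # a record with no called genotype cannot show het excess; it falls
        # through to the missingness filter
        if sum(counts) > 0 and exc_het_pvalue(*counts) < thr.min_exchet_p:
            removed["exc_het"] += 1
            continue
        if f_missing(r) > thr.max_f_missing:
            removed["f_missing"] += 1
            continue
        m = maf(r)
        if math.isnan(m):
            removed["maf_undefined"] += 1
            continue
        if not m > thr.min_maf:
            removed["maf"] += 1
            continue
        passing.append(r)
    if removed["maf_undefined"] == 0:
        del removed["maf_undefined"]
    report = QcReport(len(records), removed, len(passing))
    assert report.balances()
    return passing, report
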
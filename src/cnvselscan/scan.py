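"""Top-1% dual-criterion selection scan.

Candidate windows are those in the top 1% of the windowed FST distribution
AND in the top 1% of the log2(pi_HL/pi_LL) distribution. Quantiles are
computed over windows with a defined statistic only; ties at the threshold
are all included (deterministic, never fewer windows than the exact count).
The log-ratio tail defaults to BOTH (0.5% per tail) since diversity loss in
either group is a signal; it can be restricted to one tail when the scan
direction is known. Selected windows are then mapped to the CNVs whose
start breakpoint they contain, and candidates are kept only when they
overlap at least one gene body and their best supporting-window FST is
non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import GeneIndex
from .core import GeneFeature, SVRecord


@dataclass(frozen=True)
class ScanConfig:
    quantile: float = 0.01
    fst_tail: str = "upper"  # fixed by the method
    ratio_tail: str = "both"  # {"upper", "lower", "both"}

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 0.5:
            raise ValueError("quantile must lie in (0, 0.5)")
        if self.fst_tail != "upper":
            raise ValueError("fst_tail is fixed to 'upper'")
        if self.ratio_tail not in ("upper", "lower", "both"):
            raise ValueError("ratio_tail must be upper, lower or both")


@dataclass
class CandidateLocus:
    variant: SVRecord
    windows: pd.DataFrame  # supporting windows (rows of the window table)
    max_window_fst: float
    genes: list[str] = field(default_factory=list)


def top_quantile_windows(
    stats: pd.DataFrame,
    statistic: str,
    quantile: float = 0.01,
    tail: str = "upper",
) -> pd.DataFrame:
    """Windows in the extreme ``quantile`` tail of ``statistic``.

    The empirical quantile is computed over defined-statistic windows only;
    windows tied with the threshold value are all included. ``tail`` =
    "both" splits the quantile mass evenly between the two tails.
    """
    vals = stats[statistic]
    defined = stats[vals.notna()]
    if defined.empty:
        return defined
    v = defined[statistic].to_numpy(dtype=float)
    if np.all(v == v[0]):
        import logging

        logging.getLogger(__name__).warning(
            "top_quantile_windows: all %s values identical; empty tail",
            statistic,
        )
        return defined.iloc[0:0]
    if tail == "upper":
        thr = np.quantile(v, 1.0 - quantile)
        mask = defined[statistic] >= thr
    elif tail == "lower":
        thr = np.quantile(v, quantile)
        mask = defined[statistic] <= thr
    elif tail == "both":
        hi = np.quantile(v, 1.0 - quantile / 2.0)
        lo = np.quantile(v, quantile / 2.0)
        mask = (defined[statistic] >= hi) | (defined[statistic] <= lo)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return defined[mask]


def intersect_candidates(
    fst_top: pd.DataFrame, ratio_top: pd.DataFrame
) -> pd.DataFrame:
    """Windows present in both tails (keyed by chrom/start/end)."""
    key = ["chrom", "start", "end"]
    merged = fst_top.merge(ratio_top[key], on=key, how="inner")
    return merged


def select_windows(window_table: pd.DataFrame, config: ScanConfig | None = None) -> pd.DataFrame:
    """The dual-criterion selection: top-quantile FST windows intersected
    with extreme log2 pi-ratio windows."""
    cfg = config or ScanConfig()
    fst_top = top_quantile_windows(window_table, "fst", cfg.quantile, cfg.fst_tail)
    ratio_top = top_quantile_windows(
        window_table, "log2_ratio", cfg.quantile, cfg.ratio_tail
    )
    return intersect_candidates(fst_top, ratio_top)


def windows_to_loci(
    windows: pd.DataFrame, records: Sequence[SVRecord]
) -> list[CandidateLocus]:
    """Map selected windows to the CNVs whose POS they contain.

    A variant inside several overlapping selected windows yields one locus
    carrying all of its supporting windows and their maximum FST.
    """
    loci: list[CandidateLocus] = []
    if windows.empty:
        return loci
    by_chrom = {c: g for c, g in windows.groupby("chrom")}
    for r in records:
        g = by_chrom.get(r.chrom)
        if g is None:
            continue
        hit = g[(g["start"] <= r.pos) & (r.pos <= g["end"])]
        if hit.empty:
            continue
        loci.append(
            CandidateLocus(
                variant=r,
                windows=hit.reset_index(drop=True),
                max_window_fst=float(hit["fst"].max()),
            )
        )
    return loci


def filter_candidates(
    loci: Sequence[CandidateLocus], genes: Sequence[GeneFeature]
) -> list[CandidateLocus]:
    """Exclude loci without gene-body overlap or with negative best
    supporting-window FST (zero is not negative and is retained)."""
    index = GeneIndex(genes)
    kept: list[CandidateLocus] = []
    for locus in loci:
        hit_genes = index.assign_genes(locus.variant)
        if not hit_genes:
            continue
        if locus.max_window_fst < 0:
            continue
        locus.genes = hit_genes
        kept.append(locus)
    return kept


def loci_frame(loci: Sequence[CandidateLocus]) -> pd.DataFrame:
    rows = [
        (
            l.variant.id, l.variant.chrom, l.variant.pos, l.variant.end,
            len(l.windows), l.max_window_fst, ",".join(l.genes),
        )
        for l in loci
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "pos", "end", "n_windows", "max_window_fst",
                 "genes"],
    )


def manhattan_plots(window_table: pd.DataFrame, out_prefix: str) -> list[str]:
    """Genome-track plots of windowed FST and both diversity tracks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for col, label in (
        ("fst", "windowed $F_{ST}$"),
        ("pi_hl", r"$\pi_{HL}$ (per bp)"),
        ("pi_ll", r"$\pi_{LL}$ (per bp)"),
        ("log2_ratio", r"$\log_2(\pi_{HL}/\pi_{LL})$"),
    ):
        fig, ax = plt.subplots(figsize=(9, 3))
        offset = 0
        for i, (chrom, g) in enumerate(window_table.groupby("chrom", sort=True)):
            x = (g["start"] + g["end"]) / 2 + offset
            ax.scatter(x, g[col], s=4, color=f"C{i % 2}")
            offset += g["end"].max()
        ax.set_ylabel(label)
        ax.set_xlabel("genome position (bp, concatenated)")
        fig.tight_layout()
        path = f"{out_prefix}_{col}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
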
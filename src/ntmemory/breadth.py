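"""H3K4me3 domain breadth at transcription start sites.

Breadth is measured from called peak intervals: for each transcript the peaks
whose half-open interval contains the TSS base are found, the widest one is
taken, and transcripts without a spanning peak are omitted.  Breadth
distributions of gene sets are compared through their empirical cumulative
distribution functions and the two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF as _ECDF


@dataclass
class BreadthSample:
    """Widths (bp) of the TSS-spanning peaks of one gene set."""

    gene_set_name: str
    widths: pd.Series  # indexed by transcript_id

    def __post_init__(self) -> None:
        if (self.widths <= 0).any():
            raise ValueError("peak widths must be positive")


def tss_spanning_widths(peaks: pd.DataFrame, tss: pd.DataFrame,
                        transcript_set=None, gene_set_name: str = "",
                        auto_sort: bool = True) -> BreadthSample:
    """Width of the widest peak containing each transcript's TSS base.

    ``peaks`` must be sorted by (chrom, start); with ``auto_sort`` unsorted
    input is sorted, otherwise it is an error.  Transcripts whose TSS is
    covered by no peak are omitted.
    """
    key = peaks[["chrom", "start"]]
    sorted_ok = key.equals(key.sort_values(["chrom", "start"]))
    if not sorted_ok:
        if not auto_sort:
            raise ValueError("peaks are not sorted by (chrom, start)")
        peaks = peaks.sort_values(["chrom", "start"])
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("peak intervals must satisfy start < end")

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"].astype(int), sub["end"].astype(int)))

    sel = tss if transcript_set is None else tss[tss["name"].isin(set(transcript_set))]
    names, widths = [], []
    for row in sel.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        hits = tree[int(row.start)]  # intervaltree is half-open, like BED
        if not hits:
            continue
        names.append(row.name)
        widths.append(max(h.end - h.begin for h in hits))
    return BreadthSample(gene_set_name,
                         pd.Series(widths, index=pd.Index(names, name="transcript_id"),
                                   dtype=int, name="width"))


def ecdf(widths) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous ECDF: sorted unique support and F(x) = fraction ≤ x."""
    w = np.asarray(widths, dtype=float)
    if len(w) == 0:
        raise ValueError("ecdf of an empty sample")
    support = np.unique(w)
    return support, _ECDF(w)(support)


def compare_breadth(a: BreadthSample, b: BreadthSample) -> tuple[float, float]:
    """Two-sample two-sided KS test on peak widths of two gene sets."""
    if len(a.widths) < 2 or len(b.widths) < 2:
        raise ValueError("each breadth sample needs at least 2 widths")
    res = stats.ks_2samp(a.widths.to_numpy(), b.widths.to_numpy(),
                         alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def breadth_histogram(widths, bin_width: float, origin: float | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Counts of widths per fixed-width bin; returns (bin_edges, counts)."""
    w = np.asarray(widths, dtype=float)
    if len(w) == 0:
        raise ValueError("histogram of an empty sample")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo = float(w.min()) if origin is None else float(origin)
    if w.min() < lo:
        raise ValueError("origin exceeds the smallest width")
    n_bins = int(np.floor((w.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(w, bins=edges)
    return edges, counts
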
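"""Input-normalized H3K4me3 signal in binned windows around transcription start sites.

The histone methylation level over an interval is the difference of
per-million-scaled mean read depths,

    level = depth_IP / (N_IP / 1e6) − depth_input / (N_input / 1e6),

where N is the total number of aligned reads in the track.  Levels may be
negative.  A window (default 4 kb, centered on the TSS) is binned in 50 bp
bins; for minus-strand transcripts the bin order is reversed so bin 0 is
always the most upstream.  Gene-set metaplots are bin-wise means, and the
integral (sum over bins) per transcript feeds two-sample Kolmogorov–Smirnov
comparisons between gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Per-base read coverage by chromosome plus the track's total mapped reads."""

    coverage: dict
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        for chrom, arr in self.coverage.items():
            arr = np.asarray(arr)
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.coverage[chrom] = arr

    def chrom_length(self, chrom: str) -> int:
        return len(self.coverage[chrom])


@dataclass
class TSSWindowProfile:
    """Normalized signal per bin (5'→3' upstream-first) around one TSS."""

    transcript_id: str
    bins: np.ndarray
    integral: float = field(init=False)

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        self.integral = float(self.bins.sum())


def _interval_depth(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    if chrom not in track.coverage:
        raise ValueError(f"chromosome {chrom!r} not in track")
    if start < 0 or end > track.chrom_length(chrom) or start >= end:
        raise ValueError(f"interval {chrom}:{start}-{end} out of bounds")
    return float(track.coverage[chrom][start:end].mean())


def normalized_level(ip: CoverageTrack, input_: CoverageTrack,
                     chrom: str, start: int, end: int) -> float:
    """Input-subtracted, per-million-scaled mean depth over ``[start, end)``."""
    ip_d = _interval_depth(ip, chrom, start, end)
    in_d = _interval_depth(input_, chrom, start, end)
    return ip_d / (ip.total_reads / 1e6) - in_d / (input_.total_reads / 1e6)


def tss_window_profile(ip: CoverageTrack, input_: CoverageTrack,
                       chrom: str, tss: int, strand: str,
                       transcript_id: str = "",
                       window: int = 4000, bin_size: int = 50
                       ) -> TSSWindowProfile | None:
    """Binned normalized levels in ``[tss − window/2, tss + window/2)``.

    Bin values are mean per-base levels, making them bin-size invariant.
    Returns ``None`` (with a logged warning) when the window leaves the
    chromosome, mirroring how TSSs near contig edges are skipped.
    """
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    start = tss - window // 2
    end = start + window
    if start < 0 or end > ip.chrom_length(chrom) or end > input_.chrom_length(chrom):
        logger.warning("TSS window %s:%d-%d out of bounds; transcript %s skipped",
                       chrom, start, end, transcript_id)
        return None
    n_bins = window // bin_size
    ip_bins = ip.coverage[chrom][start:end].reshape(n_bins, bin_size).mean(axis=1)
    in_bins = input_.coverage[chrom][start:end].reshape(n_bins, bin_size).mean(axis=1)
    bins = ip_bins / (ip.total_reads / 1e6) - in_bins / (input_.total_reads / 1e6)
    if strand == "-":
        bins = bins[::-1]
    return TSSWindowProfile(transcript_id=transcript_id, bins=bins)


def profiles_for_transcripts(ip: CoverageTrack, input_: CoverageTrack,
                             tss_table: pd.DataFrame,
                             window: int = 4000, bin_size: int = 50
                             ) -> list[TSSWindowProfile]:
    """TSS window profiles for every row of a BED6-shaped TSS table."""
    profiles = []
    for row in tss_table.itertuples(index=False):
        p = tss_window_profile(ip, input_, row.chrom, int(row.start), row.strand,
                               transcript_id=row.name, window=window, bin_size=bin_size)
        if p is not None:
            profiles.append(p)
    return profiles


def metaplot(profiles: list[TSSWindowProfile]) -> np.ndarray:
    """Per-bin arithmetic mean of normalized levels across a gene set."""
    if not profiles:
        raise ValueError("metaplot requires at least one profile")
    return np.mean([p.bins for p in profiles], axis=0)


def compare_integral_levels(set_a: list[TSSWindowProfile],
                            set_b: list[TSSWindowProfile]) -> tuple[float, float]:
    """Two-sample two-sided KS test on integral window levels of two gene sets."""
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("each gene set needs at least 2 profiles")
    a = np.array([p.integral for p in set_a])
    b = np.array([p.integral for p in set_b])
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def profiles_to_frame(profiles: list[TSSWindowProfile]) -> pd.DataFrame:
    """Tidy table: one row per transcript, one column per bin, plus the integral."""
    if not profiles:
        raise ValueError("no profiles")
    n_bins = len(profiles[0].bins)
    df = pd.DataFrame([p.bins for p in profiles],
                      index=pd.Index([p.transcript_id for p in profiles],
                                     name="transcript_id"),
                      columns=[f"bin_{i:03d}" for i in range(n_bins)])
    df["integral"] = [p.integral for p in profiles]
    return df
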
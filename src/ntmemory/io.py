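"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as TSV (transcript_id, length, one integer column per sample)
with a samples.tsv sample sheet; coverage as bedGraph with a JSON sidecar
holding chromosome sizes and total mapped reads; annotation as BED6 and
broadPeak.  All genomic coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chip import CoverageTrack

BROADPEAK_COLS = ["chrom", "start", "end", "name", "score", "strand",
                  "signalValue", "pValue", "qValue"]
BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_counts(path, counts: pd.DataFrame, lengths: pd.Series) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index).astype(int))
    out.to_csv(path, sep="\t")


def read_counts(path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = df.pop("length").astype(int)
    return df.astype(np.int64), lengths


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "batch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"samples sheet missing columns: {sorted(missing)}")
    return df


def write_bedgraph(path, track: CoverageTrack) -> None:
    """Run-length encode per-base coverage; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom, cov in track.coverage.items():
            cov = np.asarray(cov)
            if len(cov) == 0:
                continue
            change = np.flatnonzero(np.diff(cov)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(cov)]])
            for s, e in zip(starts, ends):
                v = cov[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def write_track_sidecar(path, track: CoverageTrack) -> None:
    meta = {"total_reads": int(track.total_reads),
            "chrom_sizes": {c: int(len(v)) for c, v in track.coverage.items()}}
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_bedgraph(bedgraph_path, sidecar_path) -> CoverageTrack:
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    coverage = {c: np.zeros(int(n), dtype=np.int64)
                for c, n in meta["chrom_sizes"].items()}
    df = pd.read_csv(bedgraph_path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    for row in df.itertuples(index=False):
        if row.chrom not in coverage:
            raise ValueError(f"bedGraph chromosome {row.chrom!r} not in sidecar")
        coverage[row.chrom][int(row.start):int(row.end)] = row.value
    return CoverageTrack(coverage, total_reads=int(meta["total_reads"]))


def write_bed6(path, table: pd.DataFrame) -> None:
    table[BED6_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED6_COLS)


def write_broadpeak(path, table: pd.DataFrame) -> None:
    table[BROADPEAK_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_broadpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = BROADPEAK_COLS[: df.shape[1]]
    if not {"chrom", "start", "end"} <= set(df.columns):
        raise ValueError("peak file needs at least chrom/start/end columns")
    return df


def read_truth(path) -> pd.DataFrame:
    return pd.read_json(Path(path))
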
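"""Synthetic donor/IVF/NT expression and H3K4me3 chromatin data with planted memory structure.

The generator emulates the design of a nuclear-transfer (NT) memory study:
endoderm donor cells, IVF-embryo ectoderm and NT-embryo ectoderm are profiled
by RNA-seq, and each transcript belongs to one planted class —

* ``ON_memory``      — high in donor, low in IVF ectoderm, and only partially
  reset in NT ectoderm (a fraction ``nt_retention`` of the donor effect persists);
* ``OFF_memory``     — the mirror image (low in donor, incompletely re-activated in NT);
* ``reprogrammed_down`` / ``reprogrammed_up`` — donor-differential transcripts
  fully reset to the IVF level in NT ectoderm;
* ``unchanged``      — equal means everywhere.

Counts are negative-binomial with mean ``library_size × relative_expression``
and variance ``m + φ m²``; ``φ = 0`` degenerates to Poisson.  A per-batch
log-normal scale multiplier models the technical batch factor.

Matched chromatin data place one TSS per transcript on a single synthetic
chromosome and draw per-base IP/input coverage; memory classes receive
class-dependent H3K4me3 peak breadth and fold enrichment over background.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .chip import CoverageTrack

CLASSES = (
    "ON_memory",
    "OFF_memory",
    "reprogrammed_down",
    "reprogrammed_up",
    "unchanged",
)
GROUPS = ("donor", "IVF_ectoderm", "NT_ectoderm")

_DEFAULT_PROPORTIONS = {
    "ON_memory": 0.06,
    "OFF_memory": 0.06,
    "reprogrammed_down": 0.27,
    "reprogrammed_up": 0.27,
    "unchanged": 0.34,
}
# study design: 3 donor, 11 IVF-ectoderm, 12 NT-ectoderm samples
_DEFAULT_N_SAMPLES = {"donor": 3, "IVF_ectoderm": 11, "NT_ectoderm": 12}
_DEFAULT_PEAK_WIDTH = {
    "ON_memory": (3000.0, 300.0),
    "OFF_memory": (1200.0, 200.0),
    "reprogrammed_down": (800.0, 150.0),
    "reprogrammed_up": (1200.0, 200.0),
    "unchanged": (1000.0, 250.0),
}
_DEFAULT_PEAK_INTENSITY = {
    "ON_memory": 6.0,
    "OFF_memory": 3.0,
    "reprogrammed_down": 3.0,
    "reprogrammed_up": 3.0,
    "unchanged": 2.0,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic NT-memory experiment.

    Defaults describe the study conditions emulated throughout the package:
    the 3/11/12 donor/IVF/NT sample design across 3 batches, modest bulk
    sequencing depth, biological dispersion φ = 0.1, a 3 log2-unit planted
    donor-vs-IVF effect of which 80% persists in NT for memory classes, and
    broader/stronger H3K4me3 peaks at ON-memory TSSs than at
    reprogrammed-down TSSs.
    """

    seed: int = 0
    n_transcripts: int = 2000
    class_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    n_samples: dict = field(default_factory=lambda: dict(_DEFAULT_N_SAMPLES))
    n_batches: int = 3
    library_size_range: tuple = (1_000_000, 2_000_000)
    dispersion: float = 0.1
    base_log2_expression: tuple = (6.0, 1.5)
    memory_log2fc: float = 3.0
    nt_retention: float = 0.8
    transcript_length_range: tuple = (500, 5000)
    chrom_length: int | None = None  # None → sized to fit all transcripts
    chrom_name: str = "chrS"
    peak_width_params: dict = field(default_factory=lambda: dict(_DEFAULT_PEAK_WIDTH))
    peak_intensity_params: dict = field(default_factory=lambda: dict(_DEFAULT_PEAK_INTENSITY))
    batch_effect_sd: float = 0.2
    background_rate: float = 2.0  # per-base Poisson rate of input coverage
    tss_window: int = 4000  # margin kept free around every TSS

    def validate(self) -> None:
        props = self.class_proportions
        unknown = set(props) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in class_proportions: {sorted(unknown)}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1 within 1e-9")
        if any(p < 0 for p in props.values()):
            raise ValueError("class_proportions must be nonnegative")
        if set(self.n_samples) != set(GROUPS):
            raise ValueError(f"n_samples must define exactly the groups {GROUPS}")
        if any(n <= 0 for n in self.n_samples.values()):
            raise ValueError("every group needs at least one sample")
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        if self.n_batches <= 0:
            raise ValueError("n_batches must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be a positive, ordered pair")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if not 0.0 <= self.nt_retention <= 1.0:
            raise ValueError("nt_retention must lie in [0, 1]")
        tlo, thi = self.transcript_length_range
        if tlo <= 0 or thi < tlo:
            raise ValueError("transcript_length_range must be a positive, ordered pair")
        if self.memory_log2fc < 0:
            raise ValueError("memory_log2fc must be nonnegative")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        for name, table in (("peak_width_params", self.peak_width_params),
                            ("peak_intensity_params", self.peak_intensity_params)):
            if set(table) != set(CLASSES):
                raise ValueError(f"{name} must define every class in {CLASSES}")
        if self.chrom_length is not None and self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")

    # transcripts are laid out on a fixed pitch so TSS windows and peaks
    # never overlap and never leave the chromosome
    def _pitch(self) -> int:
        max_peak = max(m + 4 * s for m, s in self.peak_width_params.values())
        return int(max(self.tss_window, max_peak) + 1000)

    def resolved_chrom_length(self) -> int:
        pitch = self._pitch()
        needed = pitch * (self.n_transcripts + 1)
        if self.chrom_length is None:
            return needed
        if self.chrom_length < needed:
            raise ValueError(
                f"chrom_length {self.chrom_length} too small for "
                f"{self.n_transcripts} non-overlapping transcripts (need ≥ {needed})"
            )
        return self.chrom_length

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _group_log2_offsets(cls: str, fc: float, retention: float) -> dict:
    """Per-group log2 offsets relative to the baseline, by planted class."""
    low = -fc
    if cls == "ON_memory":
        return {"donor": 0.0, "IVF_ectoderm": low, "NT_ectoderm": low + retention * fc}
    if cls == "OFF_memory":
        return {"donor": low, "IVF_ectoderm": 0.0, "NT_ectoderm": -retention * fc}
    if cls == "reprogrammed_down":
        return {"donor": 0.0, "IVF_ectoderm": low, "NT_ectoderm": low}
    if cls == "reprogrammed_up":
        return {"donor": low, "IVF_ectoderm": 0.0, "NT_ectoderm": 0.0}
    return {g: 0.0 for g in GROUPS}


def generate_expression(config: SimConfig) -> tuple[dict, pd.DataFrame]:
    """Generate a planted-memory count matrix.

    Returns ``(data, truth)`` where ``data`` holds ``counts`` (DataFrame,
    transcripts × samples), ``samples`` (sample sheet with group/treatment/
    batch) and ``lengths`` (transcript lengths, bp), and ``truth`` records the
    planted class, expected group CPM, TSS position/strand and peak
    parameters per transcript.

    Draw order from the single seeded generator is fixed: classes, baseline
    expression, transcript lengths, strands, peak widths, library sizes,
    batch multipliers, then counts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    ids = np.array([f"tx{i:05d}" for i in range(n)])

    props = np.array([config.class_proportions.get(c, 0.0) for c in CLASSES])
    classes = rng.choice(len(CLASSES), size=n, p=props)
    class_names = np.array(CLASSES)[classes]

    mu, sd = config.base_log2_expression
    base = rng.normal(mu, sd, size=n)
    lengths = rng.integers(config.transcript_length_range[0],
                           config.transcript_length_range[1] + 1, size=n)
    strands = rng.choice(np.array(["+", "-"]), size=n)

    widths = np.empty(n)
    enrich = np.empty(n)
    for cls in CLASSES:
        mask = class_names == cls
        wm, ws = config.peak_width_params[cls]
        widths[mask] = rng.normal(wm, ws, size=int(mask.sum()))
        enrich[mask] = config.peak_intensity_params[cls]
    widths = np.clip(np.round(widths), 100, None).astype(int)

    pitch = config._pitch()
    config.resolved_chrom_length()  # validates fit
    tss = pitch // 2 + pitch * np.arange(n)

    # relative abundance per group, normalized within group
    log2_expr = np.empty((n, len(GROUPS)))
    for gi, g in enumerate(GROUPS):
        offs = np.array([
            _group_log2_offsets(c, config.memory_log2fc, config.nt_retention)[g]
            for c in class_names
        ])
        log2_expr[:, gi] = base + offs
    rel = np.exp2(log2_expr)
    frac = rel / rel.sum(axis=0, keepdims=True)
    group_cpm = frac * 1e6

    sample_ids, sample_groups = [], []
    for g in GROUPS:
        for j in range(config.n_samples[g]):
            sample_ids.append(f"{g}_{j + 1}")
            sample_groups.append(g)
    n_s = len(sample_ids)
    batches = [f"batch{(j % config.n_batches) + 1}" for j in range(n_s)]

    lib_lo, lib_hi = config.library_size_range
    lib_sizes = rng.integers(lib_lo, lib_hi + 1, size=n_s)
    batch_mult = np.exp(rng.normal(0.0, config.batch_effect_sd, size=config.n_batches))

    counts = np.empty((n, n_s), dtype=np.int64)
    gi_of = {g: i for i, g in enumerate(GROUPS)}
    for j, (sid, g, b) in enumerate(zip(sample_ids, sample_groups, batches)):
        mean = frac[:, gi_of[g]] * lib_sizes[j] * batch_mult[int(b[-1]) - 1]
        if config.dispersion == 0:
            counts[:, j] = rng.poisson(mean)
        else:
            r = 1.0 / config.dispersion
            p = r / (r + mean)
            counts[:, j] = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="transcript_id"),
                             columns=sample_ids)
    samples_df = pd.DataFrame({
        "sample_id": sample_ids,
        "group": sample_groups,
        "treatment": "none",
        "batch": batches,
    })
    truth = pd.DataFrame({
        "transcript_id": ids,
        "planted_class": class_names,
        "chrom": config.chrom_name,
        "tss": tss,
        "strand": strands,
        "peak_width": widths,
        "peak_enrichment": enrich,
        "length": lengths,
    })
    for gi, g in enumerate(GROUPS):
        truth[f"cpm_{g}"] = group_cpm[:, gi]
    data = {
        "counts": counts_df,
        "samples": samples_df,
        "lengths": pd.Series(lengths, index=counts_df.index, name="length"),
    }
    return data, truth


def generate_chromatin(truth: pd.DataFrame, config: SimConfig
                       ) -> tuple[CoverageTrack, CoverageTrack, pd.DataFrame, pd.DataFrame]:
    """Render IP/input coverage, planted peaks and TSS annotation from a truth table.

    Input coverage is Poisson(background) per base.  IP coverage is
    Poisson(background) outside peaks; inside each transcript's planted peak
    (centered on its TSS) the rate is multiplied by the class fold enrichment,
    so enrichment 1 makes IP and input exchangeable draws.  Each covered base
    counts as one aligned read, so a track's total mapped reads equal the sum
    of its per-base coverage.

    Returns ``(ip, input, peaks, tss)``; peaks use the broadPeak column
    layout, TSS annotation is BED6-shaped, both 0-based half-open.
    """
    config.validate()
    L = config.resolved_chrom_length()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    bg = config.background_rate
    input_cov = rng.poisson(bg, size=L)
    ip_cov = rng.poisson(bg, size=L)

    half = np.asarray(truth["peak_width"], dtype=int) // 2
    starts = np.asarray(truth["tss"], dtype=int) - half
    ends = starts + np.asarray(truth["peak_width"], dtype=int)
    if (starts < 0).any() or (ends > L).any():
        raise ValueError("peak interval outside chromosome; increase chrom_length")
    win = config.tss_window
    out = (np.asarray(truth["tss"]) - win // 2 < 0) | (np.asarray(truth["tss"]) + win // 2 > L)
    if out.any():
        raise ValueError("TSS window outside chromosome; increase chrom_length")

    for s, e, f in zip(starts, ends, np.asarray(truth["peak_enrichment"], dtype=float)):
        if f > 1.0:
            ip_cov[s:e] += rng.poisson(bg * (f - 1.0), size=e - s)

    chrom = config.chrom_name
    ip = CoverageTrack({chrom: ip_cov}, total_reads=int(ip_cov.sum()))
    inp = CoverageTrack({chrom: input_cov}, total_reads=int(input_cov.sum()))

    peaks = pd.DataFrame({
        "chrom": chrom,
        "start": starts,
        "end": ends,
        "name": truth["transcript_id"].to_numpy(),
        "score": np.minimum(1000, (truth["peak_enrichment"] * 100).astype(int)),
        "strand": truth["strand"].to_numpy(),
        "signalValue": truth["peak_enrichment"].to_numpy(),
        "pValue": -1.0,
        "qValue": -1.0,
    })
    tss = pd.DataFrame({
        "chrom": chrom,
        "start": truth["tss"].to_numpy(),
        "end": truth["tss"].to_numpy() + 1,
        "name": truth["transcript_id"].to_numpy(),
        "score": 0,
        "strand": truth["strand"].to_numpy(),
    })
    return ip, inp, peaks, tss


def write_simulation(outdir: str | Path, config: SimConfig,
                     data: Mapping, truth: pd.DataFrame,
                     ip: CoverageTrack | None = None,
                     inp: CoverageTrack | None = None,
                     peaks: pd.DataFrame | None = None,
                     tss: pd.DataFrame | None = None) -> None:
    """Persist a simulation to the on-disk dialect used by the pipeline."""
    from . import io as nio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nio.write_counts(outdir / "counts.tsv", data["counts"], data["lengths"])
    data["samples"].to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json", orient="records", indent=1)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    if ip is not None:
        nio.write_bedgraph(outdir / "ip.bedgraph", ip)
        nio.write_track_sidecar(outdir / "ip.json", ip)
    if inp is not None:
        nio.write_bedgraph(outdir / "input.bedgraph", inp)
        nio.write_track_sidecar(outdir / "input.json", inp)
    if peaks is not None:
        nio.write_broadpeak(outdir / "peaks.bed", peaks)
    if tss is not None:
        nio.write_bed6(outdir / "tss.bed", tss)
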
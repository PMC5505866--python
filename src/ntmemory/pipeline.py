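"""End-to-end orchestration: simulate (or load), normalize, test, classify, and
summarize chromatin structure, with machine-readable reports.

Every stage writes its tidy outputs under the run directory and the final
``report.json`` collects class counts, KS statistics, the sample clustering
and — in synthetic mode — the confusion matrix of assigned versus planted
classes, stamped with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import breadth as nbreadth
from . import chip as nchip
from . import classify as nclassify
from . import expression as nexpr
from . import io as nio
from . import simulate as nsim
from . import structure as nstruct

logger = logging.getLogger(__name__)

_XENOPUS_CONTRASTS = ("Donor_vs_IVF", "NT_vs_IVF", "Donor_vs_NT")


@dataclass
class PipelineConfig:
    """Run configuration: one input mode plus all analysis thresholds.

    Thresholds default to the study's printed cutoffs: FDR α 0.05, 3FC log2
    cutoff 1.5, human log2FC cutoffs 2.3/1.0, CPM and RPKM expression cuts of
    1, 70% expressed fraction, 4 kb TSS window in 50 bp bins.
    """

    sim: nsim.SimConfig | None = None
    input_dir: str | None = None
    outdir: str = "ntmemory_out"
    seed: int = 0
    fdr_alpha: float = 0.05
    fc3_log2: float = 1.5
    human_strong_log2: float = 2.3
    human_weak_log2: float = 1.0
    cpm_cut: float = 1.0
    rpkm_cut: float = 1.0
    frac_expressed: float = 0.7
    window: int = 4000
    bin_size: int = 50
    n_clusters: int = 3
    dispersion: float | None = None

    def validate(self) -> None:
        if (self.sim is None) == (self.input_dir is None):
            raise ValueError("exactly one of synthetic mode (sim) or input_dir must be set")
        if not 0 < self.frac_expressed <= 1:
            raise ValueError("frac_expressed must lie in (0, 1]")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        for name in ("fc3_log2", "human_strong_log2", "human_weak_log2",
                     "cpm_cut", "rpkm_cut", "window", "bin_size", "n_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window % self.bin_size != 0:
            raise ValueError("window must be a multiple of bin_size")
        if self.sim is not None:
            self.sim.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _expressed_in_group(rpkm: pd.DataFrame, samples: pd.DataFrame, group: str,
                        cut: float, frac: float) -> pd.Series:
    cols = list(samples.loc[samples["group"] == group, "sample_id"])
    return (rpkm[cols] > cut).mean(axis=1) >= frac


def run_full(config: PipelineConfig) -> dict:
    """Execute every stage and return the report dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                    "stage_log": []}

    def log_stage(name, **info):
        logger.info("stage %s: %s", name, info)
        report["stage_log"].append({"stage": name, **info})

    # ------------------------------------------------------------------ inputs
    truth = None
    if config.sim is not None:
        data, truth = nsim.generate_expression(config.sim)
        ip, inp, peaks, tss = nsim.generate_chromatin(truth, config.sim)
        nsim.write_simulation(outdir, config.sim, data, truth, ip, inp, peaks, tss)
        counts, lengths, samples = data["counts"], data["lengths"], data["samples"]
        log_stage("simulate", transcripts=len(counts), samples=len(samples))
    else:
        indir = Path(config.input_dir)
        counts, lengths = nio.read_counts(indir / "counts.tsv")
        samples = nio.read_samples(indir / "samples.tsv")
        ip = nio.read_bedgraph(indir / "ip.bedgraph", indir / "ip.json")
        inp = nio.read_bedgraph(indir / "input.bedgraph", indir / "input.json")
        peaks = nio.read_broadpeak(indir / "peaks.bed")
        tss = nio.read_bed6(indir / "tss.bed")
        log_stage("load", transcripts=len(counts), samples=len(samples))

    # -------------------------------------------------------- expression stats
    cpm = nexpr.compute_cpm(counts)
    rpkm = nexpr.compute_rpkm(counts, lengths)
    kept = nexpr.expression_filter(cpm, samples, cpm_cut=config.cpm_cut,
                                   frac_expressed=config.frac_expressed)
    log_stage("expression_filter", n_in=len(counts), n_kept=len(kept))
    fcounts = counts.loc[kept]

    de = {}
    for contrast in _XENOPUS_CONTRASTS:
        de[contrast] = nexpr.exact_nb_test(fcounts, samples, contrast=contrast,
                                           dispersion=config.dispersion)
        de[contrast].to_csv(outdir / f"de_{contrast}.tsv", sep="\t")
        n_sig = int((de[contrast]["fdr"] < config.fdr_alpha).sum())
        log_stage(f"de_{contrast}", n_tested=len(de[contrast]), n_significant=n_sig)

    # ------------------------------------------------------------ classification
    donor_cols = list(samples.loc[samples["group"] == "donor", "sample_id"])
    donor_rpkm = rpkm.loc[kept, donor_cols]
    expressed_ivf_nt = (
        _expressed_in_group(rpkm.loc[kept], samples, "IVF_ectoderm",
                            config.rpkm_cut, config.frac_expressed)
        | _expressed_in_group(rpkm.loc[kept], samples, "NT_ectoderm",
                              config.rpkm_cut, config.frac_expressed))
    labels = nclassify.classify_xenopus(
        de["Donor_vs_IVF"], de["NT_vs_IVF"], de["Donor_vs_NT"], donor_rpkm,
        expressed_ivf_nt=expressed_ivf_nt, fdr_alpha=config.fdr_alpha,
        fc3_log2=config.fc3_log2, rpkm_cut=config.rpkm_cut)
    labels.to_csv(outdir / "labels.tsv", sep="\t")
    counts_by_class = nclassify.class_counts(labels)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(counts_by_class, fh, indent=1)
    report["class_counts"] = counts_by_class
    log_stage("classify", **counts_by_class)

    # ----------------------------------------------------------- chromatin sets
    on_ids = set(labels.index[labels["primary_class"] == "ON_memory"])
    down_ids = set(labels.index[labels["primary_class"] == "reprogrammed_down"])
    tss_by_name = tss.set_index("name", drop=False)
    ks_report = {}
    profiles = {}
    for name, ids in (("ON_memory", on_ids), ("reprogrammed_down", down_ids),
                      ("genome_wide", set(tss["name"]))):
        sub = tss_by_name.loc[tss_by_name.index.intersection(list(ids))]
        profiles[name] = nchip.profiles_for_transcripts(
            ip, inp, sub, window=config.window, bin_size=config.bin_size)
    for name, profs in profiles.items():
        if profs:
            nchip.profiles_to_frame(profs).to_csv(outdir / f"profiles_{name}.tsv", sep="\t")
    meta = {name: nchip.metaplot(p).tolist() for name, p in profiles.items() if p}
    pd.DataFrame(meta).to_csv(outdir / "metaplot.tsv", sep="\t", index=False)
    if len(profiles["ON_memory"]) >= 2 and len(profiles["reprogrammed_down"]) >= 2:
        d, p = nchip.compare_integral_levels(profiles["ON_memory"],
                                             profiles["reprogrammed_down"])
        ks_report["tss_integral_on_vs_repdown"] = {"D": d, "p": p}

    widths = {}
    for name, ids in (("ON_memory", on_ids), ("reprogrammed_down", down_ids)):
        widths[name] = nbreadth.tss_spanning_widths(peaks, tss, transcript_set=ids,
                                                    gene_set_name=name)
        widths[name].widths.to_csv(outdir / f"widths_{name}.tsv", sep="\t")
    if min(len(w.widths) for w in widths.values()) >= 2:
        d, p = nbreadth.compare_breadth(widths["ON_memory"], widths["reprogrammed_down"])
        ks_report["breadth_on_vs_repdown"] = {"D": d, "p": p}
        ecdf_frames = []
        for name, w in widths.items():
            sup, frac = nbreadth.ecdf(w.widths)
            ecdf_frames.append(pd.DataFrame({"gene_set": name, "width": sup,
                                             "cum_fraction": frac}))
        pd.concat(ecdf_frames).to_csv(outdir / "ecdf.tsv", sep="\t", index=False)
    with open(outdir / "ks_report.json", "w") as fh:
        json.dump(ks_report, fh, indent=1)
    report["ks"] = ks_report
    log_stage("chromatin", **{k: v["p"] for k, v in ks_report.items()})

    # ------------------------------------------------------- structure analysis
    log_cpm = np.log2(cpm.loc[kept] + 1.0)
    batches = pd.Series(samples["batch"].to_numpy(), index=samples["sample_id"])
    scaled = nstruct.double_zscore(log_cpm, batches)
    dendro = nstruct.hierarchical_cluster(scaled, axis="samples")
    clusters = nstruct.cut_clusters(dendro, config.n_clusters)
    with open(outdir / "dendrogram.json", "w") as fh:
        json.dump({"merges": dendro["linkage"].tolist(),
                   "labels": dendro["labels"],
                   "heights": dendro["heights"]}, fh, indent=1)
    pca = nstruct.pca_samples(scaled)
    pca["scores"].to_csv(outdir / "pca.tsv", sep="\t")
    report["pca_variance_fractions"] = pca["variance_fractions"][:5].tolist()
    nstruct.heatmap_matrix(cpm.loc[kept], samples).to_csv(outdir / "heatmap.tsv", sep="\t")
    nstruct.ma_table(de["NT_vs_IVF"], rpkm.loc[kept, donor_cols], labels)\
        .to_csv(outdir / "ma.tsv", sep="\t")
    report["clusters"] = {str(k): int(v) for k, v in clusters.items()}
    report["cluster_vs_group"] = _crosstab(clusters, samples, "group")
    report["cluster_vs_batch"] = _crosstab(clusters, samples, "batch")
    log_stage("structure", n_clusters=config.n_clusters)

    # ------------------------------------------------------------ truth metrics
    if truth is not None:
        # transcripts dropped by the expression filter count as unclassified,
        # so confusion rows sum to the planted class counts
        planted = truth.set_index("transcript_id")["planted_class"]
        labels_full = labels["primary_class"].reindex(planted.index).fillna("unclassified")
        confusion = pd.crosstab(planted, labels_full)
        confusion.to_csv(outdir / "confusion.tsv", sep="\t")
        report["confusion"] = {r: confusion.loc[r].to_dict() for r in confusion.index}
        report["planted_class_counts"] = planted.value_counts().to_dict()
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _crosstab(clusters: pd.Series, samples: pd.DataFrame, col: str) -> dict:
    by = samples.set_index("sample_id")[col].reindex(clusters.index)
    tab = pd.crosstab(clusters, by)
    return {str(r): {str(c): int(tab.loc[r, c]) for c in tab.columns}
            for r in tab.index}
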
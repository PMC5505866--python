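"""Rule-based classification of transcripts into memory and reprogramming classes.

A transcript differentially expressed between donor cells and IVF ectoderm is
*ON-memory* when it stays significantly upregulated in NT ectoderm versus IVF
ectoderm (and is expressed, RPKM > 1, in every donor sample), *OFF-memory*
when it stays significantly downregulated, *reprogrammed* when the donor
difference is resolved in NT ectoderm, and *resistant-other* when the NT/IVF
difference is significant but sign-discordant with the donor difference.
The (3FC) subclass flags memory transcripts whose NT/IVF |log2FC| exceeds 1.5
(≈3-fold).  All threshold comparisons are strict: boundary values fail.

A fold-change-only variant (human NT/IVF fibroblast data, where replication
does not support an FDR) classifies on log2FC thresholds 2.3 and 1 with a
donor FPKM > 1 expression clause.

Rule evaluation order is fixed — treatment exclusion, memory classes,
reprogrammed classes, resistant-other, unclassified — and the clause that
fired is recorded per transcript in ``provenance``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

PRIMARY_CLASSES = (
    "ON_memory",
    "OFF_memory",
    "reprogrammed_down",
    "reprogrammed_up",
    "reprogrammed",
    "resistant_other_up",
    "resistant_other_down",
    "unclassified",
)

MEMORY_CLASSES = ("ON_memory", "OFF_memory")


def _check_universe(*frames: pd.DataFrame) -> pd.Index:
    idx = frames[0].index
    for f in frames[1:]:
        if not idx.equals(f.index):
            raise ValueError("transcript universes of the inputs differ")
    return idx


def classify_xenopus(de_donor_ivf: pd.DataFrame,
                     de_nt_ivf: pd.DataFrame,
                     de_donor_nt: pd.DataFrame,
                     donor_rpkm: pd.DataFrame,
                     expressed_ivf_nt: pd.Series | None = None,
                     fdr_alpha: float = 0.05,
                     fc3_log2: float = 1.5,
                     rpkm_cut: float = 1.0) -> pd.DataFrame:
    """FDR + log2FC classification from the three contrasts.

    ``donor_rpkm`` holds RPKM per donor sample (columns) per transcript; the
    expression clause requires RPKM > ``rpkm_cut`` in *all* donor samples.
    ``expressed_ivf_nt``, when given, marks transcripts expressed in the
    IVF/NT ectoderm groups; donor-expressed transcripts *not* expressed there
    stay reprogrammed-down even when NT/IVF reaches significance (they were
    successfully silenced, and low-expression significance is not held
    against them).
    """
    idx = _check_universe(de_donor_ivf, de_nt_ivf, de_donor_nt, donor_rpkm)
    if expressed_ivf_nt is not None:
        expressed_ivf_nt = expressed_ivf_nt.reindex(idx)
        if expressed_ivf_nt.isna().any():
            raise ValueError("expressed_ivf_nt does not cover the transcript universe")
        donor_only = ~expressed_ivf_nt.to_numpy(dtype=bool)
    else:
        donor_only = np.zeros(len(idx), dtype=bool)

    sig_di = (de_donor_ivf["fdr"] < fdr_alpha).to_numpy()
    sig_ni = (de_nt_ivf["fdr"] < fdr_alpha).to_numpy()
    sig_dn = (de_donor_nt["fdr"] < fdr_alpha).to_numpy()
    lfc_di = de_donor_ivf["logFC"].to_numpy()
    lfc_ni = de_nt_ivf["logFC"].to_numpy()
    lfc_dn = de_donor_nt["logFC"].to_numpy()
    donor_expr = (donor_rpkm > rpkm_cut).all(axis=1).to_numpy()

    on_mem = sig_di & (lfc_di > 0) & sig_ni & (lfc_ni > 0) & donor_expr
    on_fc3 = on_mem & (lfc_ni > fc3_log2)
    off_mem = sig_di & (lfc_di < 0) & sig_ni & (lfc_ni < 0)
    off_fc3 = off_mem & sig_dn & (lfc_dn < 0) & (lfc_ni < -fc3_log2)

    rep_down_base = sig_di & (lfc_di > 0) & sig_dn & (lfc_dn > 0) & donor_expr
    rep_down = rep_down_base & (~sig_ni | donor_only)
    rep_up = sig_di & (lfc_di < 0) & sig_dn & (lfc_dn < 0) & \
        (de_nt_ivf["fdr"].to_numpy() > fdr_alpha)
    rep_generic = sig_di & sig_dn & ~sig_ni
    res_down = sig_di & sig_ni & (lfc_di > 0) & (lfc_ni < 0)
    res_up = sig_di & sig_ni & (lfc_di < 0) & (lfc_ni > 0)

    cls = np.full(len(idx), "unclassified", dtype=object)
    prov = np.full(len(idx), "none", dtype=object)
    fc3 = np.zeros(len(idx), dtype=bool)

    def assign(mask, name, tag):
        free = (cls == "unclassified") & mask
        cls[free] = name
        prov[free] = tag

    assign(on_mem, "ON_memory", "on_memory")
    assign(off_mem, "OFF_memory", "off_memory")
    assign(rep_down_base & ~sig_ni, "reprogrammed_down", "reprogrammed_down")
    assign(rep_down & sig_ni, "reprogrammed_down", "reprogrammed_down_donor_only")
    assign(rep_up, "reprogrammed_up", "reprogrammed_up")
    assign(rep_generic, "reprogrammed", "reprogrammed")
    assign(res_down, "resistant_other_down", "resistant_other_down")
    assign(res_up, "resistant_other_up", "resistant_other_up")

    fc3[(cls == "ON_memory") & on_fc3] = True
    fc3[(cls == "OFF_memory") & off_fc3] = True

    return pd.DataFrame({"primary_class": cls, "fc3_flag": fc3, "provenance": prov},
                        index=idx.rename("transcript_id"))


def classify_human(human_de: pd.DataFrame,
                   donor_fpkm: pd.DataFrame,
                   expressed_ivf_nt: pd.Series | None = None,
                   strong_log2: float = 2.3,
                   weak_log2: float = 1.0,
                   fpkm_cut: float = 1.0) -> pd.DataFrame:
    """Fold-change-only classification (no FDR available).

    ``human_de`` needs columns ``logFC_donor_ivf`` and ``logFC_nt_ivf``.
    The >5-fold memory subclasses (|log2FC NT/IVF| > 2.3) carry
    ``fc3_flag=True``; the 2–5-fold subclasses carry ``False``; provenance
    records the printed subclass name.
    """
    idx = _check_universe(human_de, donor_fpkm)
    lfc_di = human_de["logFC_donor_ivf"].to_numpy(dtype=float)
    lfc_ni = human_de["logFC_nt_ivf"].to_numpy(dtype=float)
    donor_expr = (donor_fpkm > fpkm_cut).all(axis=1).to_numpy()
    if expressed_ivf_nt is not None:
        donor_only = ~expressed_ivf_nt.reindex(idx).to_numpy(dtype=bool)
    else:
        donor_only = np.zeros(len(idx), dtype=bool)

    on_strong = (lfc_di > strong_log2) & (lfc_ni > strong_log2) & donor_expr
    on_weak = (lfc_di > strong_log2) & (lfc_ni > weak_log2) & (lfc_ni < strong_log2) & donor_expr
    off_strong = (lfc_di < -strong_log2) & (lfc_ni < -strong_log2)
    off_weak = (lfc_di < -strong_log2) & (lfc_ni > -strong_log2) & (lfc_ni < -weak_log2)
    rep_down = (lfc_di > strong_log2) & donor_expr & (~(lfc_ni > weak_log2) | donor_only)
    rep_up = (lfc_di < -strong_log2) & (lfc_ni > -weak_log2)

    cls = np.full(len(idx), "unclassified", dtype=object)
    prov = np.full(len(idx), "none", dtype=object)
    fc3 = np.zeros(len(idx), dtype=bool)

    def assign(mask, name, tag, flag):
        free = (cls == "unclassified") & mask
        cls[free] = name
        prov[free] = tag
        fc3[free] = flag

    assign(on_strong, "ON_memory", "ON_memory(>5FC)", True)
    assign(on_weak, "ON_memory", "ON_memory(2-5FC)", False)
    assign(off_strong, "OFF_memory", "OFF_memory(>5FC)", True)
    assign(off_weak, "OFF_memory", "OFF_memory(2-5FC)", False)
    assign(rep_down, "reprogrammed_down", "reprogrammed_down", False)
    assign(rep_up, "reprogrammed_up", "reprogrammed_up", False)

    return pd.DataFrame({"primary_class": cls, "fc3_flag": fc3, "provenance": prov},
                        index=idx.rename("transcript_id"))


def intersect_replicates(labels_per_experiment: list[pd.DataFrame]) -> pd.DataFrame:
    """Keep a class only when every independent experiment assigned it.

    The 3FC flag is intersected too: it survives only if set in every
    experiment.  Transcripts disagreeing between experiments become
    unclassified.
    """
    if len(labels_per_experiment) < 2:
        raise ValueError("replicate intersection needs at least 2 experiments")
    idx = _check_universe(*labels_per_experiment)
    first = labels_per_experiment[0]
    cls = first["primary_class"].to_numpy(dtype=object).copy()
    fc3 = first["fc3_flag"].to_numpy(dtype=bool).copy()
    for other in labels_per_experiment[1:]:
        agree = cls == other["primary_class"].to_numpy(dtype=object)
        cls[~agree] = "unclassified"
        fc3 &= other["fc3_flag"].to_numpy(dtype=bool)
    fc3 &= np.isin(cls, MEMORY_CLASSES)
    prov = np.where(cls == "unclassified", "intersection_conflict", "intersection")
    return pd.DataFrame({"primary_class": cls, "fc3_flag": fc3, "provenance": prov},
                        index=idx.rename("transcript_id"))


def exclude_treatment_de(labels: pd.DataFrame, treatment_de: pd.DataFrame,
                         fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Unclassify transcripts differentially expressed by the treatment itself.

    Transcripts with treatment FDR < α (e.g. Kdm5b-wt vs catalytically
    inactive donors) are removed from every class before reporting.
    """
    fdr = treatment_de["fdr"].reindex(labels.index)
    if fdr.isna().any():
        raise ValueError("treatment_de does not cover the transcript universe")
    out = labels.copy()
    hit = (fdr < fdr_alpha).to_numpy()
    out.loc[hit, "primary_class"] = "unclassified"
    out.loc[hit, "fc3_flag"] = False
    out.loc[hit, "provenance"] = "excluded:treatment_de"
    return out


def class_counts(labels: pd.DataFrame) -> dict:
    """Per-class transcript counts, including the 3FC subclasses."""
    counts = {c: int((labels["primary_class"] == c).sum()) for c in PRIMARY_CLASSES}
    for c in MEMORY_CLASSES:
        counts[f"{c}_3FC"] = int(
            ((labels["primary_class"] == c) & labels["fc3_flag"]).sum())
    return counts


class MemoryClassifier(BaseEstimator):
    """sklearn-style front end to the rule-based memory classification.

    ``predict`` consumes a feature table with the per-transcript statistics
    of the three contrasts (``fdr_donor_ivf``, ``logFC_donor_ivf``, …) plus
    donor RPKM columns, and returns the primary class per transcript; the
    full label table (with 3FC flags and provenance) lands in ``labels_``.
    """

    def __init__(self, fdr_alpha: float = 0.05, fc3_log2: float = 1.5,
                 rpkm_cut: float = 1.0):
        self.fdr_alpha = fdr_alpha
        self.fc3_log2 = fc3_log2
        self.rpkm_cut = rpkm_cut

    def fit(self, X=None, y=None):
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.fc3_log2 <= 0 or self.rpkm_cut <= 0:
            raise ValueError("thresholds must be positive")
        self.is_fitted_ = True
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self.fit()
        need = ["fdr_donor_ivf", "logFC_donor_ivf", "fdr_nt_ivf", "logFC_nt_ivf",
                "fdr_donor_nt", "logFC_donor_nt"]
        missing = [c for c in need if c not in X.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        rpkm_cols = [c for c in X.columns if c.startswith("rpkm_donor")]
        if not rpkm_cols:
            raise ValueError("need at least one rpkm_donor* column")

        def de(prefix):
            return pd.DataFrame({"fdr": X[f"fdr_{prefix}"],
                                 "logFC": X[f"logFC_{prefix}"]}, index=X.index)

        self.labels_ = classify_xenopus(
            de("donor_ivf"), de("nt_ivf"), de("donor_nt"), X[rpkm_cols],
            fdr_alpha=self.fdr_alpha, fc3_log2=self.fc3_log2,
            rpkm_cut=self.rpkm_cut)
        return self.labels_["primary_class"].to_numpy()
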
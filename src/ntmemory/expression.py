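"""Normalization, expression filtering and differential expression for the memory pipeline.

Counts-per-million (CPM) and reads-per-kilobase-per-million (RPKM) are the
expression units; transcripts enter the analysis when CPM > 1 in all donor
samples or in ≥70% of IVF or NT samples.  Differential expression between two
sample groups uses an exact conditional negative-binomial test in the
Robinson–Smyth style: counts are library-size-adjusted to a common effective
library, a common dispersion φ (variance m + φm²) is estimated across
transcripts by method of moments unless supplied, and the split of the pooled
per-group count is tested against its conditional null distribution, summing
the probability of all splits no more likely than the observed one.  φ = 0
reduces the conditional law to a binomial.  Multiplicity is controlled with
Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

CONTRASTS = {
    "Donor_vs_IVF": ("donor", "IVF_ectoderm"),
    "NT_vs_IVF": ("NT_ectoderm", "IVF_ectoderm"),
    "Donor_vs_NT": ("donor", "NT_ectoderm"),
}

# relative slack when deciding whether an outcome is "no more likely" than the
# observed split; resolves floating-point near-ties of analytically tied pmfs
_TIE_REL = 1e-10


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: count / column total × 1e6."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")
    return counts / totals * 1e6


def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million: count / (length_kb × column total in millions)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing transcript length for {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    cpm = compute_cpm(counts)
    return cpm.div(lengths / 1e3, axis=0)


def expression_filter(cpm: pd.DataFrame, samples: pd.DataFrame,
                      cpm_cut: float = 1.0, frac_expressed: float = 0.7
                      ) -> pd.Index:
    """Transcripts with CPM > cut in all donor samples, or in ≥70% of IVF
    or of NT samples (strict > on CPM, ≥ on the fraction)."""
    keep = np.zeros(len(cpm), dtype=bool)
    rules = [("donor", "all"), ("IVF_ectoderm", "frac"), ("NT_ectoderm", "frac")]
    for group, mode in rules:
        cols = samples.loc[samples["group"] == group, "sample_id"]
        if len(cols) == 0:
            raise ValueError(f"no samples in group {group!r}")
        expressed = (cpm[list(cols)] > cpm_cut)
        if mode == "all":
            keep |= expressed.all(axis=1).to_numpy()
        else:
            keep |= (expressed.mean(axis=1) >= frac_expressed).to_numpy()
    return cpm.index[keep]


def estimate_common_dispersion(adjusted: np.ndarray, group_sizes: list[np.ndarray]
                               ) -> float:
    """Pooled method-of-moments NB dispersion across transcripts.

    For each group with ≥2 samples the within-group excess variance v − m is
    accumulated against m²; φ̂ = Σ(v − m)/Σm², clipped at 0.
    """
    num = 0.0
    den = 0.0
    for cols in group_sizes:
        if len(cols) < 2:
            continue
        sub = adjusted[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(cols) - 1
        num += w * float(np.sum(v - m))
        den += w * float(np.sum(m ** 2))
    if den == 0:
        raise ValueError("dispersion cannot be estimated: no group has ≥2 samples")
    return max(0.0, num / den)


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """log pmf of NB with mean m and variance m + φm² (φ>0)."""
    r = 1.0 / phi
    logp = np.log(mean) - np.log(r + mean)
    log1mp = np.log(r) - np.log(r + mean)
    return (special.gammaln(k + r) - special.gammaln(r) - special.gammaln(k + 1)
            + r * log1mp + k * logp)


def _exact_conditional_p(s_a: int, total: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact conditional p for the split (s_a, total−s_a).

    Under the null both groups share one mean per adjusted sample; the group
    sums are NB(n_g·m0, φ/n_g).  The p-value sums P(split) over all splits
    with probability ≤ that of the observed split.
    """
    if total == 0:
        return 1.0
    k = np.arange(total + 1)
    if phi == 0.0:
        logpmf = stats.binom.logpmf(k, total, n_a / (n_a + n_b))
    else:
        m0 = total / (n_a + n_b)
        la = _nb_logpmf(k, n_a * m0, phi / n_a)
        lb = _nb_logpmf(total - k, n_b * m0, phi / n_b)
        logpmf = la + lb
        logpmf -= special.logsumexp(logpmf)
    pmf = np.exp(logpmf)
    obs = pmf[s_a]
    return float(min(1.0, pmf[pmf <= obs * (1.0 + _TIE_REL)].sum()))


def exact_nb_test(counts: pd.DataFrame, samples: pd.DataFrame,
                  contrast: str | tuple = "Donor_vs_IVF",
                  dispersion: float | None = None,
                  prior_count: float = 0.5) -> pd.DataFrame:
    """Exact conditional NB test between the two groups of a contrast.

    Returns a per-transcript table with ``logFC`` (log2 of prior-count-
    stabilized group-mean CPMs, group A over group B), ``p_value``, ``fdr``
    (Benjamini–Hochberg over the tested transcripts) and the group-mean CPMs.
    """
    if isinstance(contrast, str):
        if contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {contrast!r}")
        group_a, group_b = CONTRASTS[contrast]
    else:
        group_a, group_b = contrast
    cols_a = list(samples.loc[samples["group"] == group_a, "sample_id"])
    cols_b = list(samples.loc[samples["group"] == group_b, "sample_id"])
    if not cols_a or not cols_b:
        raise ValueError(f"contrast {group_a}/{group_b}: empty group")
    sub = counts[cols_a + cols_b].to_numpy(dtype=float)
    libs = sub.sum(axis=0)
    if (libs == 0).any():
        raise ValueError("a sample has zero total counts")
    common = float(np.exp(np.mean(np.log(libs))))
    adjusted = sub * (common / libs)

    n_a, n_b = len(cols_a), len(cols_b)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_a + n_b)
    phi = (estimate_common_dispersion(adjusted, [idx_a, idx_b])
           if dispersion is None else float(dispersion))
    if phi < 0:
        raise ValueError("dispersion must be nonnegative")

    s_a = np.rint(adjusted[:, idx_a].sum(axis=1)).astype(np.int64)
    s_b = np.rint(adjusted[:, idx_b].sum(axis=1)).astype(np.int64)
    pvals = np.array([
        _exact_conditional_p(int(a), int(a + b), n_a, n_b, phi)
        for a, b in zip(s_a, s_b)
    ])

    cpm = compute_cpm(counts)
    mean_a = cpm[cols_a].mean(axis=1).to_numpy()
    mean_b = cpm[cols_b].mean(axis=1).to_numpy()
    logfc = np.log2((mean_a + prior_count) / (mean_b + prior_count))

    return pd.DataFrame({
        "logFC": logfc,
        "p_value": pvals,
        "fdr": bh_fdr(pvals),
        "mean_cpm_A": mean_a,
        "mean_cpm_B": mean_b,
    }, index=counts.index.rename("transcript_id"))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided unpaired Mann–Whitney U (Wilcoxon rank-sum) test.

    Exact enumeration when n_a + n_b ≤ 12 and there are no ties; otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


class ExactNBTest(BaseEstimator):
    """Per-feature exact conditional NB two-group test, sklearn style.

    ``X`` is (n_samples, n_transcripts) raw counts, ``y`` the group label per
    sample; exactly two distinct labels are required.  Fitted attributes
    carry the per-transcript statistics.

    Parameters
    ----------
    dispersion : float or None
        Common NB dispersion φ; estimated by method of moments when None.
    prior_count : float
        Prior added to per-million group means before log2 fold change.
    """

    def __init__(self, dispersion: float | None = None, prior_count: float = 0.5):
        self.dispersion = dispersion
        self.prior_count = prior_count

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n_samples, n_transcripts) with one label per sample")
        labels = pd.unique(y)
        if len(labels) != 2:
            raise ValueError("exactly two groups required")
        counts = pd.DataFrame(
            X.T, index=[f"f{i}" for i in range(X.shape[1])],
            columns=[f"s{i}" for i in range(X.shape[0])])
        samples = pd.DataFrame({"sample_id": counts.columns, "group": y})
        res = exact_nb_test(counts, samples, contrast=(labels[0], labels[1]),
                            dispersion=self.dispersion, prior_count=self.prior_count)
        self.classes_ = labels
        self.log_fold_change_ = res["logFC"].to_numpy()
        self.p_values_ = res["p_value"].to_numpy()
        self.fdr_ = res["fdr"].to_numpy()
        self.n_features_in_ = X.shape[1]
        return self
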
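"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from ntmemory import SimConfig, generate_chromatin, generate_expression


@pytest.fixture(scope="session")
def small_sim():
    """A modest planted-memory dataset: 300 transcripts, 3/4/4 samples."""
    cfg = SimConfig(seed=11, n_transcripts=300,
                    n_samples={"donor": 3, "IVF_ectoderm": 4, "NT_ectoderm": 4},
                    dispersion=0.05)
    data, truth = generate_expression(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def chrom_sim():
    """Chromatin-focused dataset with many ON-memory/reprogrammed-down TSSs."""
    cfg = SimConfig(
        seed=5, n_transcripts=120,
        class_proportions={"ON_memory": 0.3, "OFF_memory": 0.0,
                           "reprogrammed_down": 0.3, "reprogrammed_up": 0.0,
                           "unchanged": 0.4},
        n_samples={"donor": 3, "IVF_ectoderm": 3, "NT_ectoderm": 3})
    data, truth = generate_expression(cfg)
    ip, inp, peaks, tss = generate_chromatin(truth, cfg)
    return cfg, truth, ip, inp, peaks, tss


# --------------------------------------------------------------------- oracles

def conditional_binomial_p(s_a: int, total: int, n_a: int, n_b: int) -> float:
    """Exact-rational two-sided conditional binomial p-value.

    Enumerates every split of the pooled count under Binomial(total,
    n_a/(n_a+n_b)) and sums the probability of all splits no more likely
    than the observed one.  Independent of the package implementation.
    """
    p = Fraction(n_a, n_a + n_b)
    probs = [comb(total, k) * p ** k * (1 - p) ** (total - k)
             for k in range(total + 1)]
    obs = probs[s_a]
    return float(sum(q for q in probs if q <= obs))


def brute_force_ks_d(a, b) -> float:
    """Max ECDF gap over the pooled support, by direct counting."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    support = np.unique(np.concatenate([a, b]))
    gaps = [abs((a <= x).mean() - (b <= x).mean()) for x in support]
    return max(gaps)


def lance_williams_ward(dist: np.ndarray) -> list[tuple]:
    """Naive ward.D agglomeration oracle.

    Clusters are kept as frozensets of leaf indices in a dict of pairwise
    dissimilarities; at each step the closest pair (first-minimum order) is
    merged and distances to the rest recomputed by the Ward Lance–Williams
    update on the unsquared input dissimilarities.  Returns the merge history
    as (members_i, members_j, height) tuples.
    """
    clusters = {frozenset([i]): 1 for i in range(len(dist))}
    d = {}
    for i in range(len(dist)):
        for j in range(i + 1, len(dist)):
            d[frozenset([frozenset([i]), frozenset([j])])] = dist[i, j]
    history = []
    while len(clusters) > 1:
        pair, h = min(d.items(), key=lambda kv: kv[1])
        ci, cj = sorted(pair, key=lambda c: sorted(c))
        ni, nj = clusters[ci], clusters[cj]
        merged = ci | cj
        history.append((set(ci), set(cj), h))
        del clusters[ci], clusters[cj]
        for ck, nk in clusters.items():
            tot = ni + nj + nk
            d_new = ((ni + nk) * d[frozenset([ci, ck])]
                     + (nj + nk) * d[frozenset([cj, ck])]
                     - nk * h) / tot
            d[frozenset([merged, ck])] = d_new
            del d[frozenset([ci, ck])], d[frozenset([cj, ck])]
        del d[pair]
        clusters[merged] = ni + nj
    return history


# ----------------------------------------------- classifier truth table

def filter_truth_table() -> pd.DataFrame:
    """Hand-built transcripts exercising every classification clause and the
    FDR = 0.05, log2FC = 1.5 and RPKM = 1 boundaries.

    Columns: per-contrast fdr/logFC, donor RPKM (same in every donor
    sample), whether the transcript counts as expressed in IVF/NT, and the
    forced class and 3FC flag.
    """
    rows = [
        # id, fdr_di, lfc_di, fdr_ni, lfc_ni, fdr_dn, lfc_dn, rpkm, expr_ivf_nt, class, fc3
        ("on_fc3",          .01,  2.0, .01,  1.6, .50,  0.2, 5.0, True,  "ON_memory", True),
        ("on_at_1p5",       .01,  2.0, .01,  1.5, .50,  0.2, 5.0, True,  "ON_memory", False),
        ("on_lowfc",        .01,  2.0, .01,  0.4, .50,  0.2, 5.0, True,  "ON_memory", False),
        ("fdr_ni_boundary", .01,  2.0, .05,  1.6, .01,  2.0, 5.0, True,  "reprogrammed_down", False),
        ("on_rpkm_low",     .01,  2.0, .01,  1.6, .50,  0.2, 0.5, True,  "unclassified", False),
        ("on_rpkm_at_1",    .01,  2.0, .01,  1.6, .50,  0.2, 1.0, True,  "unclassified", False),
        ("off_fc3",         .01, -2.0, .01, -1.6, .01, -1.0, 5.0, True,  "OFF_memory", True),
        ("off_at_m1p5",     .01, -2.0, .01, -1.5, .01, -1.0, 5.0, True,  "OFF_memory", False),
        ("off_fc3_no_dn",   .01, -2.0, .01, -1.6, .50, -1.0, 5.0, True,  "OFF_memory", False),
        ("off_norpkm",      .01, -2.0, .01, -0.5, .50, -0.2, 0.1, True,  "OFF_memory", False),
        ("rep_down",        .01,  2.0, .50,  0.1, .01,  2.0, 5.0, True,  "reprogrammed_down", False),
        ("fdr_di_boundary", .05,  2.0, .50,  0.1, .01,  2.0, 5.0, True,  "unclassified", False),
        ("rep_up",          .01, -2.0, .50, -0.1, .01, -2.0, 5.0, True,  "reprogrammed_up", False),
        ("rep_up_ni_at_05", .01, -2.0, .05, -0.1, .01, -2.0, 5.0, True,  "reprogrammed", False),
        ("rep_generic",     .01,  2.0, .50,  0.0, .01, -2.0, 5.0, True,  "reprogrammed", False),
        ("donor_only",      .01,  2.0, .01, -2.0, .01,  2.0, 5.0, False, "reprogrammed_down", False),
        ("not_donor_only",  .01,  2.0, .01, -2.0, .01,  2.0, 5.0, True,  "resistant_other_down", False),
        ("res_down",        .01,  2.0, .01, -1.0, .50,  0.5, 5.0, True,  "resistant_other_down", False),
        ("res_up",          .01, -2.0, .01,  1.0, .50, -0.5, 5.0, True,  "resistant_other_up", False),
        ("null",            .50,  0.5, .50,  0.3, .50,  0.2, 5.0, True,  "unclassified", False),
        ("lfc_di_zero",     .01,  0.0, .01,  1.0, .50,  0.0, 5.0, True,  "unclassified", False),
    ]
    cols = ["transcript_id", "fdr_di", "lfc_di", "fdr_ni", "lfc_ni",
            "fdr_dn", "lfc_dn", "rpkm", "expr_ivf_nt", "expected_class",
            "expected_fc3"]
    return pd.DataFrame(rows, columns=cols).set_index("transcript_id")


def classify_truth_table(table: pd.DataFrame):
    """Run classify_xenopus on the hand-built table."""
    from ntmemory import classify_xenopus

    def de(f, l):
        return pd.DataFrame({"fdr": table[f], "logFC": table[l]}, index=table.index)

    donor_rpkm = pd.DataFrame({f"donor_{i}": table["rpkm"] for i in range(3)},
                              index=table.index)
    return classify_xenopus(de("fdr_di", "lfc_di"), de("fdr_ni", "lfc_ni"),
                            de("fdr_dn", "lfc_dn"), donor_rpkm,
                            expressed_ivf_nt=table["expr_ivf_nt"])
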
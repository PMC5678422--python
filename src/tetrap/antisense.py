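"""Pervasive antisense transcription: the TE "trap" statistic.

Per gene, sense and antisense read counts define an exact one-sided
binomial test of antisense excess against the globally estimated
antisense proportion, with Benjamini-Hochberg control.  A replicate-aware
differential antisense test (Welch t on log2 antisense RPM) is run in
parallel, and the intersection of the two significant sets defines the
pervasive-antisense (trap) gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("tetrap")


def gene_orientation_counts(counts: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Pool a long (feature, sample, orientation, count) table into per-gene
    sense/antisense/total counts (summed over the selected samples)."""
    sub = counts if samples is None else counts[counts["sample"].isin(samples)]
    wide = (
        sub.groupby(["feature", "orientation"])["count"].sum().unstack(fill_value=0)
        .reindex(columns=["sense", "antisense"], fill_value=0)
    )
    wide["total"] = wide["sense"] + wide["antisense"]
    return wide.reset_index().rename(columns={"feature": "gene"})


def global_antisense_proportion(counts: pd.DataFrame) -> float:
    """Total antisense reads over total reads across all genes."""
    total = counts["total"].sum()
    if total <= 0:
        raise ValueError("no reads over genes; cannot estimate antisense proportion")
    return float(counts["antisense"].sum() / total)


def binomial_antisense_test(
    counts: pd.DataFrame, p0: float, alpha: float = 0.05
) -> pd.DataFrame:
    """Exact one-sided upper-tail binomial test per gene.

    p = P(X >= antisense | n = total, p0), i.e. the probability of at
    least the observed antisense reads under the global proportion.
    Genes with zero total reads are excluded before BH correction (their
    count is logged); significance is q < ``alpha``.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    tested = counts[counts["total"] > 0].copy()
    n_zero = len(counts) - len(tested)
    if n_zero:
        logger.info("binomial_antisense_test: %d zero-coverage genes excluded", n_zero)
    n = tested["total"].to_numpy()
    k = tested["antisense"].to_numpy()
    # upper tail including the observed count
    p = stats.binom.sf(k - 1, n, p0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    tested["p_value"] = p
    tested["q_value"] = q
    tested["significant"] = q < alpha
    tested["global_p0"] = p0
    return tested.reset_index(drop=True)


def antisense_rpm(
    counts: pd.DataFrame, library_sizes: dict[str, int]
) -> pd.DataFrame:
    """Per-gene log2 antisense RPM matrix (gene x sample, +1 pseudocount)."""
    anti = counts[counts["orientation"] == "antisense"]
    wide = anti.pivot_table(index="feature", columns="sample", values="count",
                            aggfunc="sum", fill_value=0)
    libs = np.array([library_sizes[s] for s in wide.columns], dtype=float)
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    return pd.DataFrame(
        np.log2(wide.to_numpy() / (libs[None, :] / 1e6) + 1.0),
        index=wide.index, columns=wide.columns,
    )


def differential_antisense(
    log2_rpm: pd.DataFrame,
    wt_samples: list[str],
    ko_samples: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t per gene on log2 antisense RPM, KO vs WT, BH-corrected.

    Genes with no antisense signal in any replicate are untestable and are
    excluded before correction (their count is logged), mirroring the
    zero-count row filtering of count-based differential frameworks; they
    are reported with p = q = 1.
    """
    if len(wt_samples) < 2 or len(ko_samples) < 2:
        raise ValueError("at least 2 replicates per group required")
    testable = (log2_rpm[wt_samples + ko_samples] > 0).any(axis=1)
    n_zero = int((~testable).sum())
    if n_zero:
        logger.info("differential_antisense: %d all-zero genes excluded from testing", n_zero)
    zeros = log2_rpm.index[~testable]
    log2_rpm = log2_rpm[testable]
    ko = log2_rpm[ko_samples]
    wt = log2_rpm[wt_samples]
    t, p = stats.ttest_ind(ko, wt, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {"t": t, "p_value": p, "q_value": q,
         "mean_diff": ko.mean(axis=1) - wt.mean(axis=1),
         "significant": (q < alpha) & (ko.mean(axis=1) > wt.mean(axis=1))},
        index=log2_rpm.index,
    )
    if len(zeros):
        filler = pd.DataFrame(
            {"t": 0.0, "p_value": 1.0, "q_value": 1.0, "mean_diff": 0.0,
             "significant": False}, index=zeros,
        )
        out = pd.concat([out, filler]).sort_index()
    return out


@dataclass
class AntisenseSummary:
    genes: list[str]
    global_p0: float
    proportion_ko: float
    proportion_wt: float
    difference: float
    ratio: float
    n_binomial: int
    n_differential: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pervasive_genes": self.genes,
            "n_pervasive": len(self.genes),
            "global_p0": self.global_p0,
            "antisense_proportion_ko": self.proportion_ko,
            "antisense_proportion_wt": self.proportion_wt,
            "antisense_difference": self.difference,
            "antisense_ratio": self.ratio,
            "n_binomial_significant": self.n_binomial,
            "n_differential_significant": self.n_differential,
            **self.extras,
        }


def antisense_gene_set(
    binomial_results: pd.DataFrame,
    differential_results: pd.DataFrame,
    ko_counts: pd.DataFrame | None = None,
    wt_counts: pd.DataFrame | None = None,
) -> AntisenseSummary:
    """Intersect the binomial- and differential-significant gene sets.

    The summary reports the genic antisense read proportion in KO and WT
    and both their difference and ratio (the KO-relative-to-WT antisense
    quantity).
    """
    binom_sig = set(binomial_results.loc[binomial_results["significant"], "gene"])
    diff_sig = set(differential_results.index[differential_results["significant"]])
    genes = sorted(binom_sig & diff_sig)

    def _prop(c):
        return float(c["antisense"].sum() / c["total"].sum()) if c is not None and c["total"].sum() else float("nan")

    p_ko, p_wt = _prop(ko_counts), _prop(wt_counts)
    return AntisenseSummary(
        genes=genes,
        global_p0=float(binomial_results["global_p0"].iloc[0]) if len(binomial_results) else float("nan"),
        proportion_ko=p_ko,
        proportion_wt=p_wt,
        difference=p_ko - p_wt,
        ratio=(p_ko / p_wt) if p_wt else float("inf"),
        n_binomial=len(binom_sig),
        n_differential=len(diff_sig),
    )
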
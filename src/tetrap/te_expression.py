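"""TE-class expression: class summation, log2 RPM normalisation, Z-score
matrices and differential activation calls.

Counts come from strand-aware overlap counting on genic-exclusion-filtered
TE instances.  Instances are subject to an outlier cutoff (kept only if
their count exceeds 3 in at least one sample); retained instances are
summed per class and orientation, corrected for the summed class length
and the library size (log2 RPM per kb, +1 pseudocount), standardised per
class across samples, and compared between groups with a Welch t-test and
Benjamini-Hochberg control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("tetrap")


@dataclass
class ClassExpressionMatrix:
    """Per-class raw counts, log2 RPM and Z-scores (classes x samples)."""

    raw_counts: pd.DataFrame
    class_lengths: pd.Series
    log2_rpm: pd.DataFrame | None = None
    zscores: pd.DataFrame | None = None
    constant_classes: list[str] | None = None
    orientation: str = "both"


def summarize_te_classes(
    counts: pd.DataFrame,
    tes: pd.DataFrame,
    count_cutoff: int = 3,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Sum instance counts to class level after the instance outlier cutoff.

    An instance is retained when its per-sample total (orientations
    summed) exceeds ``count_cutoff`` in at least one sample.  Returns the
    class x (sample, orientation) count table, the summed lengths of
    retained instances per class, and the per-instance retention log.
    Classes with no retained instance are absent from the output (missing,
    not zero).
    """
    totals = counts.groupby(["feature", "sample"], sort=False)["count"].sum().unstack(fill_value=0)
    retained_ids = totals.index[(totals > count_cutoff).any(axis=1)]
    retention = pd.DataFrame(
        {"feature": totals.index,
         "max_count": totals.max(axis=1).to_numpy(),
         "retained": totals.index.isin(retained_ids)}
    )
    n_drop = int((~retention["retained"]).sum())
    logger.info("summarize_te_classes: %d instances retained, %d dropped (count <= %d in all samples)",
                len(retained_ids), n_drop, count_cutoff)

    te_index = tes.set_index("id")
    kept = counts[counts["feature"].isin(retained_ids)].copy()
    kept["te_class"] = kept["feature"].map(te_index["te_class"])
    class_counts = (
        kept.groupby(["te_class", "sample", "orientation"], sort=False)["count"]
        .sum()
        .reset_index()
    )
    lengths = te_index.loc[te_index.index.isin(retained_ids)]
    class_lengths = (lengths["end"] - lengths["start"]).groupby(lengths["te_class"]).sum()
    class_lengths.name = "class_length"
    return class_counts, class_lengths, retention


def normalize_log2_rpm(class_count, library_size, class_length) -> float | np.ndarray:
    """log2 reads-per-million per kb of summed class length, +1 pseudocount.

    value = log2( count / (library_size/1e6) / (class_length/1e3) + 1 )
    """
    library_size = np.asarray(library_size, dtype=float)
    class_length = np.asarray(class_length, dtype=float)
    if np.any(library_size <= 0):
        raise ValueError("library_size must be positive")
    if np.any(class_length <= 0):
        raise ValueError("class_length must be positive")
    value = np.log2(
        np.asarray(class_count, dtype=float) / (library_size / 1e6) / (class_length / 1e3) + 1.0
    )
    return value if value.ndim else float(value)


def class_log2_rpm_matrix(
    class_counts: pd.DataFrame,
    class_lengths: pd.Series,
    library_sizes: dict[str, int],
    orientation: str | None = None,
) -> pd.DataFrame:
    """Class x sample log2 RPM matrix for one orientation (or all summed)."""
    sub = class_counts if orientation is None else class_counts[
        class_counts["orientation"] == orientation
    ]
    wide = sub.groupby(["te_class", "sample"])["count"].sum().unstack(fill_value=0)
    libs = np.array([library_sizes[s] for s in wide.columns], dtype=float)
    lens = class_lengths.reindex(wide.index).to_numpy(dtype=float)
    return pd.DataFrame(
        normalize_log2_rpm(wide.to_numpy(), libs[None, :], lens[:, None]),
        index=wide.index, columns=wide.columns,
    )


def zscore_by_class(log2_rpm: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardise each class across samples (population SD).

    Returns the Z matrix and the list of constant classes (SD == 0),
    whose rows are all zero.
    """
    if log2_rpm.shape[1] < 2:
        raise ValueError("Z-scores require at least 2 samples")
    mean = log2_rpm.mean(axis=1)
    sd = log2_rpm.std(axis=1, ddof=0)
    constant = sd == 0
    z = log2_rpm.sub(mean, axis=0).div(sd.where(~constant, 1.0), axis=0)
    z[constant] = 0.0
    return z, list(log2_rpm.index[constant])


def differential_te(
    log2_rpm: pd.DataFrame,
    groups: dict[str, list[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t per class between the two groups, BH-corrected.

    ``groups`` maps the two group names (e.g. KO, WT) to replicate sample
    columns.  Classes missing in either group are excluded and logged.
    Direction is the sign of the first-group minus second-group mean.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (g1, s1), (g2, s2) = groups.items()
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("at least 2 replicates per group required")
    a = log2_rpm[s1]
    b = log2_rpm[s2]
    complete = a.notna().all(axis=1) & b.notna().all(axis=1)
    excluded = list(log2_rpm.index[~complete])
    if excluded:
        logger.info("differential_te: excluded classes with missing values: %s", excluded)
    a, b = a[complete], b[complete]
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # identical groups yield 0/0 -> no evidence of difference
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    diff = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame(
        {"t": t, "p_value": p, "q_value": q,
         "direction": np.sign(diff).astype(int),
         "mean_diff": diff,
         "significant": q < alpha},
        index=a.index,
    )
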
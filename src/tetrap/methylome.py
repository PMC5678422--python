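"""Bisulfite methylation quantitation.

Genome-wide levels are summarised in consecutive windows of 50 qualifying
CpGs (coverage >= 3); feature-level methylation averages per-CpG levels
over features with >= 50 qualifying CpGs; TE-class methylation pools raw
calls per class, subject to a minimum-observation filter applied across
all samples of a comparison.  Pairwise distribution comparisons use the
two-sided Wilcoxon rank-sum test with Bonferroni correction over the
family of comparisons requested in one invocation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("tetrap")


def window_methylation(
    calls: pd.DataFrame, window_cpgs: int = 50, min_cov: int = 3
) -> pd.DataFrame:
    """Call-weighted percent methylation in consecutive blocks of qualifying CpGs.

    CpGs with coverage < ``min_cov`` are removed first; the survivors are
    grouped per chromosome, left to right, into non-overlapping blocks of
    ``window_cpgs``; a terminal block with fewer CpGs is dropped.  The
    window percentage is 100 x sum(meth) / sum(meth + unmeth) over the
    block.  Input must be position-sorted within each chromosome.
    """
    frames = []
    n_low = 0
    for chrom, sub in calls.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if len(pos) > 1 and (np.diff(pos) < 0).any():
            raise ValueError(f"methylation calls on {chrom} are not position-sorted")
        cov = (sub["count_meth"] + sub["count_unmeth"]).to_numpy()
        qual = cov >= min_cov
        n_low += int((~qual).sum())
        q = sub[qual]
        n_windows = len(q) // window_cpgs
        if n_windows == 0:
            continue
        idx = np.arange(n_windows * window_cpgs)
        wid = idx // window_cpgs
        meth = q["count_meth"].to_numpy()[: len(idx)]
        unmeth = q["count_unmeth"].to_numpy()[: len(idx)]
        meth_sum = np.bincount(wid, weights=meth)
        tot_sum = np.bincount(wid, weights=meth + unmeth)
        pos_q = q["pos"].to_numpy()
        frames.append(pd.DataFrame(
            {"chrom": chrom,
             "start": pos_q[idx[::window_cpgs]],
             "end": pos_q[idx[window_cpgs - 1 :: window_cpgs]] + 1,
             "n_cpgs": window_cpgs,
             "percent_methylation": 100.0 * meth_sum / tot_sum}
        ))
    logger.info("window_methylation: %d CpGs below coverage %d discarded", n_low, min_cov)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs", "percent_methylation"])
    return pd.concat(frames, ignore_index=True)


def feature_methylation(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    min_cpgs: int = 50,
    min_cov: int = 3,
    id_column: str = "id",
) -> pd.Series:
    """CpG-weighted mean methylation per feature.

    Averages the individual per-CpG methylation levels (each site weighted
    equally, regardless of its coverage) over CpGs with coverage >=
    ``min_cov`` falling inside the feature; features with fewer than
    ``min_cpgs`` qualifying CpGs are reported missing (NaN).
    """
    cov = calls["count_meth"] + calls["count_unmeth"]
    qual = calls[cov >= min_cov].copy()
    qual["level"] = 100.0 * qual["count_meth"] / (qual["count_meth"] + qual["count_unmeth"])

    out = pd.Series(np.nan, index=features[id_column], dtype=float, name="percent_methylation")
    for chrom, fsub in features.groupby("chrom"):
        csub = qual[qual["chrom"] == chrom].sort_values("pos")
        pos = csub["pos"].to_numpy()
        levels = csub["level"].to_numpy()
        cum = np.concatenate([[0.0], np.cumsum(levels)])
        lo = np.searchsorted(pos, fsub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, fsub["end"].to_numpy(), side="left")
        n = hi - lo
        means = np.where(n >= min_cpgs, (cum[hi] - cum[lo]) / np.maximum(n, 1), np.nan)
        out.loc[fsub[id_column].to_numpy()] = means
    return out


def te_class_methylation(
    calls_by_sample: dict[str, pd.DataFrame],
    tes: pd.DataFrame,
    min_obs: int = 1000,
    min_cov: int = 0,
) -> pd.DataFrame:
    """Pooled-call percent methylation per TE class and sample.

    Sums methylated and unmethylated calls over all instances of each
    class; a class is reported only if its total observations reach
    ``min_obs`` in every sample of the comparison.
    """
    rows = []
    for sample, calls in calls_by_sample.items():
        cov = calls["count_meth"] + calls["count_unmeth"]
        qual = calls[cov >= min_cov] if min_cov > 0 else calls
        for cls, csub in tes.groupby("te_class"):
            meth_total = 0
            obs_total = 0
            for chrom, isub in csub.groupby("chrom"):
                on = qual[qual["chrom"] == chrom].sort_values("pos")
                pos = on["pos"].to_numpy()
                cm = np.concatenate([[0], np.cumsum(on["count_meth"].to_numpy())])
                ct = np.concatenate([[0], np.cumsum((on["count_meth"] + on["count_unmeth"]).to_numpy())])
                lo = np.searchsorted(pos, isub["start"].to_numpy(), side="left")
                hi = np.searchsorted(pos, isub["end"].to_numpy(), side="left")
                meth_total += (cm[hi] - cm[lo]).sum()
                obs_total += (ct[hi] - ct[lo]).sum()
            rows.append((cls, sample, int(obs_total),
                         100.0 * meth_total / obs_total if obs_total else np.nan))
    long = pd.DataFrame(rows, columns=["te_class", "sample", "observations", "percent"])
    ok = long.groupby("te_class")["observations"].min() >= min_obs
    keep = ok[ok].index
    dropped = sorted(set(long["te_class"]) - set(keep))
    if dropped:
        logger.info("te_class_methylation: classes below %d observations dropped: %s",
                    min_obs, dropped)
    wide = long[long["te_class"].isin(keep)].pivot(
        index="te_class", columns="sample", values="percent"
    )
    return wide


@dataclass
class MethylomeComparison:
    pair: tuple[str, str]
    statistic: float
    p_value: float
    p_bonferroni: float
    significant: bool


def compare_methylomes(
    window_sets: dict[str, np.ndarray | pd.Series],
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    exact_max_n: int = 50,
) -> list[MethylomeComparison]:
    """Two-sided Wilcoxon rank-sum tests with Bonferroni correction.

    ``pairs`` defaults to all pairwise comparisons among the supplied
    window sets; the Bonferroni family is the set of comparisons requested
    in this invocation.  Small tie-free samples use the exact null
    distribution, larger ones the normal approximation with tie
    correction.
    """
    names = list(window_sets)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    results = []
    for a, b in pairs:
        x = np.asarray(window_sets[a], dtype=float)
        y = np.asarray(window_sets[b], dtype=float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"empty window set in comparison {a} vs {b}")
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (max(len(x), len(y)) <= exact_max_n and not ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        results.append(MethylomeComparison(
            pair=(a, b), statistic=float(res.statistic), p_value=float(res.pvalue),
            p_bonferroni=min(1.0, float(res.pvalue) * len(pairs)),
            significant=float(res.pvalue) * len(pairs) < alpha,
        ))
    return results
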
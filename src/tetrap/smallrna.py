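"""Small RNA processing and the endosiRNA signature.

Libraries are filtered to 20-24 nt, partitioned by a hierarchical
exclusion (rRNA, then miRNA, then non-repeat genome; the remainder is
available for repeat assignment), and characterised by length/strand
distributions, 5'-nucleotide composition, the 5'-to-5' overlap signature
of opposite-strand pairs (siRNA duplexes with 2-nt 3' overhangs peak at
length - 2), consensus coverage profiles, and class-level differential
abundance between timepoints (two-tailed Student's t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("tetrap")

BINS = ("rRNA", "miRNA", "genome", "repeat")


def filter_by_length(reads: pd.DataFrame, min_nt: int = 20, max_nt: int = 24) -> pd.DataFrame:
    """Keep reads with length in [min_nt, max_nt] (inclusive); order preserved."""
    if min_nt > max_nt:
        raise ValueError(f"min_nt ({min_nt}) > max_nt ({max_nt})")
    lengths = reads["length"] if "length" in reads else reads["end"] - reads["start"]
    keep = (lengths >= min_nt) & (lengths <= max_nt)
    logger.info("filter_by_length: %d retained, %d discarded outside [%d, %d] nt",
                int(keep.sum()), int((~keep).sum()), min_nt, max_nt)
    return reads[keep]


def _overlaps_any(reads: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    hit = np.zeros(len(reads), dtype=bool)
    if intervals is None or len(intervals) == 0:
        return hit
    rchrom = reads["chrom"].to_numpy()
    rstart = reads["start"].to_numpy()
    rend = reads["end"].to_numpy()
    for chrom, sub in intervals.groupby("chrom"):
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        on = rchrom == chrom
        n = (
            np.searchsorted(starts, rend[on], side="left")
            - np.searchsorted(ends, rstart[on], side="right")
        )
        hit[on] = n > 0
    return hit


def hierarchical_exclusion(
    reads: pd.DataFrame,
    rrna: pd.DataFrame,
    mirna: pd.DataFrame,
    repeats: pd.DataFrame,
) -> pd.DataFrame:
    """Ordered partition of reads: rRNA, miRNA, non-repeat genome, repeat.

    First matching rule wins: reads overlapping an rRNA locus are binned
    rRNA; of the remainder, reads overlapping a miRNA locus are binned
    miRNA; reads not overlapping any annotated repeat are binned
    "genome"; everything else is available for repeat assignment.
    Returns a copy of the reads with a ``bin`` column.
    """
    out = reads.copy()
    bin_col = np.full(len(out), "repeat", dtype=object)
    is_rrna = _overlaps_any(out, rrna)
    is_mirna = _overlaps_any(out, mirna) & ~is_rrna
    in_repeat = _overlaps_any(out, repeats)
    is_genome = ~is_rrna & ~is_mirna & ~in_repeat
    bin_col[is_genome] = "genome"
    bin_col[is_mirna] = "miRNA"
    bin_col[is_rrna] = "rRNA"
    out["bin"] = bin_col
    sizes = pd.Series(bin_col).value_counts()
    logger.info("hierarchical_exclusion: %s (total %d)", sizes.to_dict(), len(out))
    return out


def assign_te_class(reads: pd.DataFrame, tes: pd.DataFrame) -> pd.DataFrame:
    """Assign repeat-bin reads to the TE class(es) they overlap.

    A read overlapping instances of several classes counts toward each;
    returns the reads with a ``te_class`` column, one row per (read,
    class) assignment.
    """
    pieces = []
    for cls, sub in tes.groupby("te_class"):
        hit = _overlaps_any(reads, sub)
        if hit.any():
            assigned = reads[hit].copy()
            assigned["te_class"] = cls
            pieces.append(assigned)
    if not pieces:
        out = reads.iloc[0:0].copy()
        out["te_class"] = pd.Series(dtype=object)
        return out
    return pd.concat(pieces, ignore_index=True)


def length_strand_distribution(reads: pd.DataFrame) -> pd.DataFrame:
    """Length x strand count table; the grand total equals the read count."""
    lengths = reads["length"] if "length" in reads else reads["end"] - reads["start"]
    return pd.crosstab(lengths.rename("length"), reads["strand"])


def five_prime_composition(reads: pd.DataFrame) -> dict[str, float]:
    """Fraction of reads starting with each base; T is reported as U."""
    if len(reads) == 0:
        raise ValueError("empty read set: no 5' composition")
    first = reads["sequence"].str[0].str.upper().replace({"T": "U"})
    frac = first.value_counts(normalize=True)
    return {base: float(frac.get(base, 0.0)) for base in "ACGU"}


@dataclass
class OverlapSignature:
    """Distribution of 5'-to-5' overlap lengths between opposite-strand reads."""

    counts: dict[int, int]
    zscores: dict[int, float] = field(default_factory=dict)
    mode: int | None = None
    n_pairs: int = 0

    def __post_init__(self) -> None:
        self.n_pairs = int(sum(self.counts.values()))
        vals = np.array([self.counts[o] for o in sorted(self.counts)], dtype=float)
        keys = sorted(self.counts)
        if self.n_pairs > 0:
            self.mode = int(keys[int(np.argmax(vals))])
            z = {}
            for i, o in enumerate(keys):
                others = np.delete(vals, i)
                sd = others.std(ddof=0)
                if sd > 0:
                    z[o] = float((vals[i] - others.mean()) / sd)
                else:
                    diff = vals[i] - others.mean()
                    z[o] = float(np.sign(diff) * np.inf) if diff else float("nan")
            self.zscores = z
        else:
            self.mode = None
            self.zscores = {o: float("nan") for o in keys}


def overlap_signature(reads: pd.DataFrame, max_overlap: int = 30) -> OverlapSignature:
    """Count 5'-to-5' overlaps between plus- and minus-strand reads.

    For a plus-strand read with 5' end at s (interval [s, s+L1)) and a
    minus-strand read covering [a, a+L2) (5' end at a+L2-1) on the same
    reference, the overlap is o = (a + L2 - 1) - s + 1; a pair counts when
    1 <= o <= max_overlap and the two intervals intersect.  Every
    qualifying pair counts (with multiplicity).
    """
    counts = {o: 0 for o in range(1, max_overlap + 1)}
    plus = reads[reads["strand"] == "+"]
    minus = reads[reads["strand"] == "-"]
    if len(plus) and len(minus):
        for chrom in np.intersect1d(plus["chrom"].unique(), minus["chrom"].unique()):
            psub = plus[plus["chrom"] == chrom]
            # index plus reads by 5' position
            p_start = psub["start"].to_numpy()
            p_len = (psub["end"] - psub["start"]).to_numpy()
            order = np.argsort(p_start, kind="stable")
            p_start, p_len = p_start[order], p_len[order]
            msub = minus[minus["chrom"] == chrom]
            m_start = msub["start"].to_numpy()
            m_five = (msub["end"] - 1).to_numpy()
            for a, f in zip(m_start, m_five):
                lo = np.searchsorted(p_start, f - max_overlap + 1, side="left")
                hi = np.searchsorted(p_start, f, side="right")
                for j in range(lo, hi):
                    s = p_start[j]
                    o = f - s + 1
                    # intervals must intersect: a < s + L1 (s < a + L2 holds since o >= 1)
                    if a < s + p_len[j]:
                        counts[int(o)] += 1
    return OverlapSignature(counts=counts)


def consensus_profile(reads: pd.DataFrame, consensus_length: int) -> np.ndarray:
    """Per-position read coverage over a consensus sequence.

    Uses consensus coordinates (``cons_start``/length when present,
    otherwise start/end).  The coverage sum equals the summed read
    lengths; out-of-bounds reads raise.
    """
    if "cons_start" in reads:
        starts = reads["cons_start"].to_numpy()
        lengths = reads["length"].to_numpy() if "length" in reads else (reads["end"] - reads["start"]).to_numpy()
    else:
        starts = reads["start"].to_numpy()
        lengths = (reads["end"] - reads["start"]).to_numpy()
    ends = starts + lengths
    if len(starts) and (starts.min() < 0 or ends.max() > consensus_length):
        raise ValueError("read outside consensus bounds")
    cover = np.zeros(consensus_length + 1, dtype=np.int64)
    np.add.at(cover, starts, 1)
    np.add.at(cover, ends, -1)
    return np.cumsum(cover[:-1])


def te_class_smallrna(
    rpm_by_sample: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    alpha_strong: float = 0.005,
) -> pd.DataFrame:
    """Two-tailed Student's t per class between two sample groups of
    reads-per-million values; tiers: '*' p < 0.05, '**' p < 0.005."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("at least 2 replicates per group required")
    a = rpm_by_sample[group_a]
    b = rpm_by_sample[group_b]
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    stars = np.where(p < alpha_strong, "**", np.where(p < alpha, "*", ""))
    return pd.DataFrame(
        {"t": t, "p_value": p,
         "mean_a": a.mean(axis=1), "mean_b": b.mean(axis=1),
         "significant": p < alpha, "stars": stars},
        index=rpm_by_sample.index,
    )


def class_rpm(reads_by_sample: dict[str, pd.DataFrame], tes: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million mapped to each TE class, per sample, computed on
    the filtered 20-24 nt library."""
    cols = {}
    for sample, reads in reads_by_sample.items():
        lib = len(reads)
        assigned = assign_te_class(reads, tes)
        counts = assigned.groupby("te_class").size()
        cols[sample] = counts / (lib / 1e6) if lib else counts * np.nan
    out = pd.DataFrame(cols).fillna(0.0)
    return out
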
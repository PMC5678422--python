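"""ChIP enrichment: 1 kb tile log2 observed/expected and TE-class fold rules.

Per tile, the expected count is the library size spread uniformly over
the genome (partial tiles pro-rated); enrichment is
log2((observed + c) / (expected + c)) with pseudocount c.  Class-level
enrichment is the mean tile value over tiles overlapping retained class
instances; classes whose KO linear enrichment is at least twice the WT
value (delta mean log2 O/E >= 1) are flagged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("tetrap")


def tile_log2_obs_exp(
    tile_counts: pd.DataFrame,
    library_size: int | None = None,
    genome_length: int | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Add expected counts and log2 observed/expected per tile.

    ``library_size`` defaults to the sum of tile counts and
    ``genome_length`` to the summed tile widths; expected = library_size x
    tile_width / genome_length.
    """
    widths = (tile_counts["end"] - tile_counts["start"]).to_numpy(dtype=float)
    if genome_length is None:
        genome_length = float(widths.sum())
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if library_size is None:
        library_size = float(tile_counts["count"].sum())
    expected = library_size * widths / genome_length
    out = tile_counts.copy()
    out["expected"] = expected
    out["log2_oe"] = np.log2(
        (out["count"].to_numpy(dtype=float) + pseudocount) / (expected + pseudocount)
    )
    return out


def _tiles_overlapping(tiles: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    hit = np.zeros(len(tiles), dtype=bool)
    tchrom = tiles["chrom"].to_numpy()
    tstart = tiles["start"].to_numpy()
    tend = tiles["end"].to_numpy()
    for chrom, sub in intervals.groupby("chrom"):
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        on = tchrom == chrom
        n = (
            np.searchsorted(starts, tend[on], side="left")
            - np.searchsorted(ends, tstart[on], side="right")
        )
        hit[on] = n > 0
    return hit


def te_class_chip_enrichment(
    enrichment_by_sample: dict[str, pd.DataFrame],
    tes: pd.DataFrame,
    wt_sample: str | None = None,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Mean tile log2 O/E per TE class and sample, with Z-scores and
    KO-vs-WT fold-change flags.

    A tile counts toward a class when it intersects at least one retained
    instance; tiles overlapping several classes count toward each.  When
    ``wt_sample`` is given, every other sample is compared against it and
    flagged when its linear enrichment reaches ``fold_threshold`` x WT
    (equivalently delta mean log2 O/E >= log2(fold_threshold)).  Classes
    with no overlapping tiles are reported missing.
    """
    samples = list(enrichment_by_sample)
    ref_tiles = enrichment_by_sample[samples[0]]
    rows = {}
    for cls, sub in tes.groupby("te_class"):
        hit = _tiles_overlapping(ref_tiles, sub)
        if not hit.any():
            logger.info("te_class_chip_enrichment: class %s has no overlapping tiles", cls)
            continue
        rows[cls] = {
            s: float(enrichment_by_sample[s].loc[hit, "log2_oe"].mean()) for s in samples
        }
    mat = pd.DataFrame.from_dict(rows, orient="index")[samples]
    mat.index.name = "te_class"

    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    constant = sd == 0
    z = mat.sub(mean, axis=0).div(sd.where(~constant, 1.0), axis=0)
    z[constant] = 0.0
    out = mat.copy()
    for s in samples:
        out[f"z_{s}"] = z[s]
    out["constant"] = constant

    if wt_sample is not None:
        if wt_sample not in samples:
            raise ValueError(f"wt_sample {wt_sample!r} not among samples {samples}")
        log_thresh = np.log2(fold_threshold)
        for s in samples:
            if s == wt_sample:
                continue
            delta = mat[s] - mat[wt_sample]
            out[f"fold_{s}_vs_{wt_sample}"] = 2.0 ** delta
            out[f"flag_{s}_vs_{wt_sample}"] = delta >= log_thresh
    return out
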
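"""Filter cascades for insertion and deletion call tables.

Call tables are pandas DataFrames with the following columns.

Insertion calls (discordant-read caller dialect)
    ``individual_id, chrom, position, family, filter_level, genotype_quality,
    clip5, clip3, support_reads`` — ``position`` is the 0-based empty
    pre-integration site.

Deletion calls (two dialects)
    ``individual_id, chrom, start, end, dialect, eval1, eval2, support_reads,
    genotype`` — ``dialect`` is ``"cnv"`` (read-depth caller; carries the two
    eval scores) or ``"sv"`` (split-read caller; carries ``support_reads``
    and a 0/1/2 deletion ``genotype``).  Fields not used by a dialect are NaN.

Similarity blocks
    ``chrom, start, end, family`` — reference intervals with sequence
    similarity to the ERV mapping library.

All thresholds are inclusive.  Filters are pure row selections, hence
idempotent and order-independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._intervals import expand_pairs, overlap_ranges
from .config import AnalysisConfig, DeletionFilter, InsertionFilter

INSERTION_COLUMNS = [
    "individual_id", "chrom", "position", "family", "filter_level",
    "genotype_quality", "clip5", "clip3", "support_reads",
]
DELETION_COLUMNS = [
    "individual_id", "chrom", "start", "end", "dialect",
    "eval1", "eval2", "support_reads", "genotype",
]
SIMILARITY_COLUMNS = ["chrom", "start", "end", "family"]


def _insertion_mask(calls: pd.DataFrame, thr: InsertionFilter) -> pd.Series:
    mask = (calls["support_reads"] >= thr.min_support_reads) & (
        calls["filter_level"] >= thr.min_filter_level
    )
    if thr.min_gq is not None:
        mask &= calls["genotype_quality"] >= thr.min_gq
    if thr.max_gq is not None:
        mask &= calls["genotype_quality"] <= thr.max_gq
    if thr.min_clip3 is not None:
        mask &= calls["clip3"] >= thr.min_clip3
    if thr.min_clip5 is not None:
        mask &= calls["clip5"] >= thr.min_clip5
    return mask


def filter_insertions_stringent(
    calls: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """High-confidence insertion calls used to define loci."""
    thr = (config or AnalysisConfig()).stringent
    return calls[_insertion_mask(calls, thr)].copy()


def filter_insertions_relaxed(
    calls: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Permissive insertion calls used to count carriers at known loci."""
    thr = (config or AnalysisConfig()).relaxed
    return calls[_insertion_mask(calls, thr)].copy()


def filter_deletions(
    calls: pd.DataFrame, mode: str = "stringent", config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Filter deletion calls, applying each dialect's own rule.

    ``cnv`` stringent keeps eval1/eval2 <= 0.05 and length <= 20 kb; the
    relaxed tier keeps eval1/eval2 <= 1 with no length cap.  ``sv`` calls are
    gated identically in both modes: length 90–20,000 bp and >=2 supporting
    reads.
    """
    if mode not in ("stringent", "relaxed"):
        raise ValueError(f"mode must be 'stringent' or 'relaxed', got {mode!r}")
    cfg = config or AnalysisConfig()
    thr: DeletionFilter = cfg.deletion_stringent if mode == "stringent" else cfg.deletion_relaxed
    length = calls["end"] - calls["start"]
    is_cnv = calls["dialect"] == "cnv"
    cnv_ok = (calls["eval1"] <= thr.max_eval1) & (calls["eval2"] <= thr.max_eval2)
    if thr.cnv_max_length is not None:
        cnv_ok &= length <= thr.cnv_max_length
    sv_ok = (
        (length >= thr.sv_min_length)
        & (length <= thr.sv_max_length)
        & (calls["support_reads"] >= thr.sv_min_support_reads)
    )
    return calls[np.where(is_cnv, cnv_ok, sv_ok)].copy()


def annotate_with_similarity(
    deletions: pd.DataFrame, blocks: pd.DataFrame
) -> pd.DataFrame:
    """Keep deletions overlapping >=1 similarity block; annotate the family.

    Each surviving deletion gains a ``family`` column from the block with
    the largest overlap; ties go to the block with the lower start, then the
    lexicographically smaller family, so output is deterministic.
    """
    if deletions.empty or blocks.empty:
        out = deletions.iloc[0:0].copy()
        out["family"] = pd.Series(dtype=object)
        return out
    kept_parts = []
    blocks = blocks.sort_values(["chrom", "start", "family"], kind="mergesort")
    for chrom, dels in deletions.groupby("chrom", sort=False):
        blk = blocks[blocks["chrom"] == chrom]
        if blk.empty:
            continue
        bs = blk["start"].to_numpy(np.int64)
        be = blk["end"].to_numpy(np.int64)
        # blocks may overlap each other, so search on running-max ends
        lo = np.searchsorted(np.maximum.accumulate(be), dels["start"].to_numpy(np.int64), side="right")
        # running-max can overshoot: lo is a lower bound, scan candidates exactly
        hi = np.searchsorted(bs, dels["end"].to_numpy(np.int64), side="left")
        d_idx, b_idx = expand_pairs(lo, hi)
        if d_idx.size == 0:
            continue
        ds = dels["start"].to_numpy(np.int64)[d_idx]
        de = dels["end"].to_numpy(np.int64)[d_idx]
        ov = np.minimum(de, be[b_idx]) - np.maximum(ds, bs[b_idx])
        real = ov > 0
        d_idx, b_idx, ov = d_idx[real], b_idx[real], ov[real]
        if d_idx.size == 0:
            continue
        pairs = pd.DataFrame(
            {
                "d": d_idx,
                "overlap": ov,
                "block_start": bs[b_idx],
                "family": blk["family"].to_numpy(object)[b_idx],
            }
        )
        best = (
            pairs.sort_values(
                ["d", "overlap", "block_start", "family"],
                ascending=[True, False, True, True],
                kind="mergesort",
            )
            .drop_duplicates("d")
            .set_index("d")
        )
        out = dels.iloc[best.index].copy()
        out["family"] = best["family"].to_numpy()
        kept_parts.append(out)
    if not kept_parts:
        out = deletions.iloc[0:0].copy()
        out["family"] = pd.Series(dtype=object)
        return out
    return pd.concat(kept_parts).sort_index()
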
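"""Build the unified polymorphic-ERV locus frame and the presence matrix.

A locus frame is a DataFrame with columns ``locus_id, chrom, start, end,
family, source`` (0-based half-open intervals; ``source`` is
``"non_assembly"`` for loci defined from insertion calls — where the
interval marks the empty pre-integration site — or ``"assembly"`` for loci
present in the reference and defined from deletion calls).

The presence matrix is a loci x individuals integer DataFrame: for
non-assembly loci the number of relaxed-filter insertion calls assigned to
the locus; for assembly loci a 0/1 indicator of carrying the reference ERV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._intervals import expand_pairs, overlap_ranges, union_groups


def _majority_family(calls: pd.DataFrame, group: np.ndarray, n_groups: int) -> np.ndarray:
    """Per-group majority family; ties broken by the earliest call position."""
    tmp = pd.DataFrame(
        {"group": group, "family": calls["family"].to_numpy(object),
         "position": calls["position"].to_numpy(np.int64)}
    )
    counts = (
        tmp.groupby(["group", "family"])
        .agg(n=("position", "size"), first_pos=("position", "min"))
        .reset_index()
    )
    best = (
        counts.sort_values(["group", "n", "first_pos", "family"],
                           ascending=[True, False, True, True], kind="mergesort")
        .drop_duplicates("group")
        .set_index("group")["family"]
    )
    out = np.empty(n_groups, dtype=object)
    out[best.index.to_numpy()] = best.to_numpy()
    return out


def merge_insertions_to_loci(
    stringent_calls: pd.DataFrame, extension_bp: int = 50
) -> pd.DataFrame:
    """Union extended insertion calls into non-assembly loci.

    Each call position p becomes the window [p - ext, p + ext + 1), clamped
    at 0; per chromosome, transitively overlapping windows merge into one
    locus annotated with the majority family among its calls.
    """
    pieces = []
    for chrom in sorted(stringent_calls["chrom"].unique()):
        calls = stringent_calls[stringent_calls["chrom"] == chrom]
        pos = calls["position"].to_numpy(np.int64)
        starts = np.maximum(pos - extension_bp, 0)
        ends = pos + extension_bp + 1
        group, merged = union_groups(starts, ends)
        merged["chrom"] = chrom
        merged["family"] = _majority_family(calls, group, len(merged))
        pieces.append(merged[["chrom", "start", "end", "family"]])
    if not pieces:
        return pd.DataFrame(columns=["locus_id", "chrom", "start", "end", "family", "source"])
    out = pd.concat(pieces, ignore_index=True)
    out["source"] = "non_assembly"
    out["locus_id"] = _serial_ids(out)
    return out[["locus_id", "chrom", "start", "end", "family", "source"]]


def build_assembly_loci(annotated_deletions: pd.DataFrame) -> pd.DataFrame:
    """Union similarity-annotated deletion intervals into assembly loci.

    Dialects are reduced separately and concatenated, so per-dialect locus
    counts add up in the combined frame.
    """
    pieces = []
    for dialect in ("cnv", "sv"):
        dels = annotated_deletions[annotated_deletions["dialect"] == dialect]
        for chrom in sorted(dels["chrom"].unique()):
            d = dels[dels["chrom"] == chrom]
            group, merged = union_groups(d["start"].to_numpy(np.int64), d["end"].to_numpy(np.int64))
            fam = (
                pd.DataFrame({"group": group, "family": d["family"].to_numpy(object),
                              "position": d["start"].to_numpy(np.int64)})
                .pipe(lambda t: _majority_family(t, t["group"].to_numpy(), len(merged)))
            )
            merged["chrom"] = chrom
            merged["family"] = fam
            pieces.append(merged[["chrom", "start", "end", "family"]])
    if not pieces:
        return pd.DataFrame(columns=["locus_id", "chrom", "start", "end", "family", "source"])
    out = pd.concat(pieces, ignore_index=True)
    out["source"] = "assembly"
    out["locus_id"] = _serial_ids(out)
    return out[["locus_id", "chrom", "start", "end", "family", "source"]]


def _serial_ids(frame: pd.DataFrame) -> list[str]:
    # Gifford-style <family>.<serial>, serial counted within family
    serial = frame.groupby("family").cumcount() + 1
    return [f"{f}.{s}" for f, s in zip(frame["family"], serial)]


def unify_locus_frame(
    non_assembly_loci: pd.DataFrame, assembly_loci: pd.DataFrame
) -> pd.DataFrame:
    """Concatenate the two locus sources into one frame with unique ids."""
    frame = pd.concat([non_assembly_loci, assembly_loci], ignore_index=True)
    if frame.empty:
        return frame
    if frame["locus_id"].duplicated().any():
        # per-source serials can clash across sources: renumber within
        # family over the combined frame (deterministic given input order)
        frame = frame.reset_index(drop=True)
        frame["locus_id"] = _serial_ids(frame)
    if frame["locus_id"].duplicated().any():
        bad = frame.loc[frame["locus_id"].duplicated(), "locus_id"].iloc[0]
        raise ValueError(f"locus id collision: {bad!r}")
    return frame.reset_index(drop=True)


def genotype_presence(
    loci: pd.DataFrame,
    relaxed_calls: pd.DataFrame,
    relaxed_deletions: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
    extension_bp: int = 50,
) -> pd.DataFrame:
    """Count per-individual identifications at each locus.

    Non-assembly loci: entry = number of relaxed insertion calls whose
    extended window overlaps the locus (a call overlapping two adjacent loci
    counts in both).  Assembly loci: an individual is scored present (1)
    unless a passing deletion call covering the locus shows full absence —
    any read-depth (cnv) deletion, or a split-read (sv) call with
    homozygous-deletion genotype 2.  A heterozygous sv deletion (genotype 1)
    leaves one ERV-bearing haplotype, so the individual still counts as a
    carrier.

    ``samples`` supplies the column order; calls from individuals absent
    from it raise.
    """
    if samples is not None:
        individuals = samples["individual_id"].tolist()
    else:
        pools = [relaxed_calls["individual_id"]]
        if relaxed_deletions is not None:
            pools.append(relaxed_deletions["individual_id"])
        individuals = sorted(pd.concat(pools).unique())
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    unknown = set(relaxed_calls["individual_id"].unique()) - set(individuals)
    if relaxed_deletions is not None:
        unknown |= set(relaxed_deletions["individual_id"].unique()) - set(individuals)
    if unknown:
        raise ValueError(f"calls from individuals missing in metadata: {sorted(unknown)[:5]}")

    mat = np.zeros((len(loci), len(individuals)), dtype=np.int64)
    loci = loci.reset_index(drop=True)
    for chrom, lrows in loci.groupby("chrom", sort=False):
        for source, src_rows in lrows.groupby("source", sort=False):
            order = np.argsort(src_rows["start"].to_numpy(), kind="mergesort")
            row_idx = src_rows.index.to_numpy()[order]
            ls = src_rows["start"].to_numpy(np.int64)[order]
            le = src_rows["end"].to_numpy(np.int64)[order]
            if source == "non_assembly":
                calls = relaxed_calls[relaxed_calls["chrom"] == chrom]
                if calls.empty:
                    continue
                pos = calls["position"].to_numpy(np.int64)
                qs = np.maximum(pos - extension_bp, 0)
                qe = pos + extension_bp + 1
                lo, hi = overlap_ranges(ls, le, qs, qe)
                ci, li = expand_pairs(lo, hi)
                if ci.size == 0:
                    continue
                cols = np.array([ind_index[i] for i in calls["individual_id"].to_numpy(object)[ci]])
                np.add.at(mat, (row_idx[li], cols), 1)
            else:
                mat[row_idx[:, None], :] = 1
                if relaxed_deletions is None or relaxed_deletions.empty:
                    continue
                dels = relaxed_deletions[relaxed_deletions["chrom"] == chrom]
                if dels.empty:
                    continue
                absent = (dels["dialect"] == "cnv") | (
                    (dels["dialect"] == "sv") & (dels["genotype"] >= 2)
                )
                dels = dels[absent]
                if dels.empty:
                    continue
                ds = dels["start"].to_numpy(np.int64)
                de = dels["end"].to_numpy(np.int64)
                # assembly loci from different dialects may interleave, so
                # search on running-max ends and verify overlap exactly
                lo = np.searchsorted(np.maximum.accumulate(le), ds, side="right")
                hi = np.searchsorted(ls, de, side="left")
                di, li = expand_pairs(lo, hi)
                real = np.minimum(de[di], le[li]) - np.maximum(ds[di], ls[li]) > 0
                di, li = di[real], li[real]
                if di.size == 0:
                    continue
                cols = np.array([ind_index[i] for i in dels["individual_id"].to_numpy(object)[di]])
                mat[row_idx[li], cols] = 0
    return pd.DataFrame(mat, index=loci["locus_id"].to_numpy(), columns=individuals)
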
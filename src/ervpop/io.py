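"""Readers and writers for the pipeline's tables and intervals.

Conventions
-----------
Internal coordinates are 0-based half-open everywhere.  BED input/output is
taken as-is; TSV call tables default to 1-based inclusive positions on disk
(``one_based=True``), mirroring how the upstream callers print them, and
are shifted on read/write.  Numeric TSV columns accept both dot and comma
decimal separators (published frequency tables print comma decimals).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .filtering import DELETION_COLUMNS, INSERTION_COLUMNS, SIMILARITY_COLUMNS

logger = logging.getLogger("ervpop")

SAMPLE_COLUMNS = ["individual_id", "species", "island", "is_hybrid", "mean_coverage"]

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}


def _parse_bool(v) -> bool:
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean value {v!r}")


def _to_float(series: pd.Series, col: str, path) -> pd.Series:
    """Float conversion accepting comma decimals; errors carry line numbers."""
    s = series.astype(str).str.strip().str.replace(",", ".", regex=False)
    # U+2212 minus occasionally appears in published tables
    s = s.str.replace("−", "-", regex=False)
    out = pd.to_numeric(s, errors="coerce")
    bad = out.isna() & ~series.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
        raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
    return out


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata TSV (individual_id, species, island,
    is_hybrid, mean_coverage)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[SAMPLE_COLUMNS].copy()
    for col in ("individual_id", "species", "island"):
        df[col] = df[col].str.strip()
    dup = df.loc[df["individual_id"].duplicated(), "individual_id"].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate individual_id values: {dup}")
    df["is_hybrid"] = df["is_hybrid"].map(_parse_bool)
    df["mean_coverage"] = _to_float(df["mean_coverage"], "mean_coverage", path)
    bad = df.loc[df["mean_coverage"] <= 0, "individual_id"].tolist()
    if bad:
        raise ValueError(f"{path}: non-positive mean_coverage for {bad}")
    logger.info("read %d samples from %s", len(df), path)
    return df


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def _check_chroms(df: pd.DataFrame, chrom_lengths, path) -> None:
    if chrom_lengths is None:
        return
    unknown = sorted(set(df["chrom"]) - set(chrom_lengths))
    if unknown:
        raise ValueError(f"{path}: chromosome(s) not in sequence dictionary: {unknown}")


def read_insertion_calls(
    path: str | Path, one_based: bool = True, chrom_lengths=None
) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in INSERTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = df[INSERTION_COLUMNS].copy()
    for col in ("position", "filter_level", "clip5", "clip3", "support_reads"):
        out[col] = _to_float(out[col], col, path).astype(np.int64)
    out["genotype_quality"] = _to_float(out["genotype_quality"], "genotype_quality", path)
    if one_based:
        out["position"] -= 1
    if (out["position"] < 0).any():
        line = int((out["position"] < 0).idxmax()) + 2
        raise ValueError(f"{path}: negative position at line {line}")
    _check_chroms(out, chrom_lengths, path)
    logger.info("read %d insertion calls from %s", len(out), path)
    return out


def write_insertion_calls(calls: pd.DataFrame, path: str | Path, one_based: bool = True) -> None:
    out = calls.copy()
    if one_based:
        out["position"] = out["position"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_deletion_calls(
    path: str | Path, dialect: str, one_based: bool = True, chrom_lengths=None
) -> pd.DataFrame:
    """Read one deletion-call dialect from TSV.

    ``cnv`` expects ``individual_id, chrom, start, end, eval1, eval2``;
    ``sv`` expects ``individual_id, chrom, start, end, support_reads,
    genotype``.  On-disk intervals default to 1-based inclusive.
    """
    if dialect not in ("cnv", "sv"):
        raise ValueError(f"dialect must be 'cnv' or 'sv', got {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = ["individual_id", "chrom", "start", "end"] + (
        ["eval1", "eval2"] if dialect == "cnv" else ["support_reads", "genotype"]
    )
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = pd.DataFrame({"individual_id": df["individual_id"].str.strip(),
                        "chrom": df["chrom"].str.strip()})
    out["start"] = _to_float(df["start"], "start", path).astype(np.int64)
    out["end"] = _to_float(df["end"], "end", path).astype(np.int64)
    if one_based:
        out["start"] -= 1  # 1-based inclusive [s,e] -> 0-based half-open [s-1,e)
    out["dialect"] = dialect
    if dialect == "cnv":
        out["eval1"] = _to_float(df["eval1"], "eval1", path)
        out["eval2"] = _to_float(df["eval2"], "eval2", path)
        out["support_reads"] = np.nan
        out["genotype"] = np.nan
    else:
        out["eval1"] = np.nan
        out["eval2"] = np.nan
        out["support_reads"] = _to_float(df["support_reads"], "support_reads", path)
        out["genotype"] = _to_float(df["genotype"], "genotype", path)
    if (out["end"] <= out["start"]).any():
        line = int((out["end"] <= out["start"]).idxmax()) + 2
        raise ValueError(f"{path}: interval with end <= start at line {line}")
    _check_chroms(out, chrom_lengths, path)
    logger.info("read %d %s deletion calls from %s", len(out), dialect, path)
    return out[DELETION_COLUMNS]


def write_deletion_calls(calls: pd.DataFrame, path: str | Path, one_based: bool = True) -> None:
    dialects = set(calls["dialect"].unique())
    if len(dialects) > 1:
        raise ValueError("write one dialect per file")
    dialect = dialects.pop() if dialects else "cnv"
    cols = ["individual_id", "chrom", "start", "end"] + (
        ["eval1", "eval2"] if dialect == "cnv" else ["support_reads", "genotype"]
    )
    out = calls[cols].copy()
    if one_based:
        out["start"] = out["start"] + 1
    if dialect == "sv":
        out["support_reads"] = out["support_reads"].astype(np.int64)
        out["genotype"] = out["genotype"].astype(np.int64)
    out.to_csv(path, sep="\t", index=False)


def _validate_vcf_end_fields(path: str | Path) -> None:
    """Reject records with INFO/END before POS (htslib drops them silently)."""
    import gzip
    import re

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            m = re.search(r"(?:^|;)END=(\d+)", fields[7]) if len(fields) > 7 else None
            if m and int(m.group(1)) < int(fields[1]):
                raise ValueError(
                    f"{path}: record at {fields[0]}:{fields[1]} has END < POS"
                )


def read_sv_deletions_vcf(path: str | Path, chrom_lengths=None) -> pd.DataFrame:
    """Read split-read deletion calls from a merged multi-sample VCF.

    One output row per sample carrying a non-reference genotype; the
    deletion genotype is the alternate-allele count, interval is
    ``[POS, INFO/END)`` after the 1-based shift, and supporting reads come
    from ``INFO/PE``.
    """
    _validate_vcf_end_fields(path)
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            end = rec.info.get("END", rec.stop)
            if end < rec.pos:
                raise ValueError(f"{path}: record at {rec.chrom}:{rec.pos} has END < POS")
            support = rec.info.get("PE", 0)
            if isinstance(support, tuple):
                support = support[0]
            for sample_name, sample in rec.samples.items():
                gt = sample.get("GT")
                if gt is None:
                    continue
                alt_count = sum(1 for a in gt if a not in (None, 0))
                if alt_count == 0:
                    continue
                rows.append(
                    (sample_name, rec.chrom, rec.pos - 1, int(end), "sv",
                     np.nan, np.nan, int(support), alt_count)
                )
    out = pd.DataFrame(rows, columns=DELETION_COLUMNS)
    _check_chroms(out, chrom_lengths, path)
    logger.info("read %d sv deletion genotypes from %s", len(out), path)
    return out


def read_similarity_blocks(path: str | Path, chrom_lengths=None) -> pd.DataFrame:
    """Read ERV-similarity blocks from BED (name column = family)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str,
                     keep_default_na=False)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: similarity BED needs 4 columns (chrom/start/end/family)")
    out = pd.DataFrame({
        "chrom": df[0].str.strip(),
        "start": _to_float(df[1], "start", path).astype(np.int64),
        "end": _to_float(df[2], "end", path).astype(np.int64),
        "family": df[3].str.strip(),
    }, columns=SIMILARITY_COLUMNS)
    if (out["end"] <= out["start"]).any():
        line = int((out["end"] <= out["start"]).idxmax()) + 1
        raise ValueError(f"{path}: interval with end <= start at line {line}")
    _check_chroms(out, chrom_lengths, path)
    return out


def write_similarity_blocks(blocks: pd.DataFrame, path: str | Path) -> None:
    blocks[SIMILARITY_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_call_tables(
    insertions: str | Path,
    cnv_deletions: str | Path,
    sv_deletions: str | Path,
    similarity_blocks: str | Path,
    one_based: bool = True,
    chrom_lengths=None,
) -> dict[str, pd.DataFrame]:
    """Read all raw call collections; sv deletions may be TSV or VCF."""
    sv_path = Path(sv_deletions)
    if sv_path.suffix == ".vcf" or "".join(sv_path.suffixes[-2:]) == ".vcf.gz":
        sv = read_sv_deletions_vcf(sv_path, chrom_lengths)
    else:
        sv = read_deletion_calls(sv_path, "sv", one_based, chrom_lengths)
    return {
        "insertions": read_insertion_calls(insertions, one_based, chrom_lengths),
        "cnv_deletions": read_deletion_calls(cnv_deletions, "cnv", one_based, chrom_lengths),
        "sv_deletions": sv,
        "similarity_blocks": read_similarity_blocks(similarity_blocks, chrom_lengths),
    }


def read_regions(path: str | Path) -> pd.DataFrame:
    """Read differentiated-region intervals from BED.

    Returns ``region_id, chrom, start, end``.  Ids come from the name
    column or are auto-numbered; zero-length intervals are dropped with a
    warning; duplicate ids are kept with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        return pd.DataFrame(columns=["region_id", "chrom", "start", "end"])
    out = pd.DataFrame({
        "chrom": df[0].str.strip(),
        "start": _to_float(df[1], "start", path).astype(np.int64),
        "end": _to_float(df[2], "end", path).astype(np.int64),
    })
    if df.shape[1] >= 4 and (df[3].str.strip() != "").all():
        out["region_id"] = df[3].str.strip()
    else:
        out["region_id"] = [f"region_{i + 1}" for i in range(len(out))]
    zero = out["end"] <= out["start"]
    if zero.any():
        warnings.warn(f"{path}: dropping {int(zero.sum())} zero-length region(s)")
        out = out[~zero]
    if out["region_id"].duplicated().any():
        dups = out.loc[out["region_id"].duplicated(), "region_id"].unique().tolist()
        warnings.warn(f"{path}: duplicate region ids kept: {dups}")
    return out[["region_id", "chrom", "start", "end"]].reset_index(drop=True)


def write_loci_bed(loci: pd.DataFrame, path: str | Path) -> None:
    """Write a locus frame as BED: name column carries the locus id
    (which embeds the family), score column the source."""
    bed = loci[["chrom", "start", "end", "locus_id", "source"]]
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_loci_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    out = pd.DataFrame({
        "locus_id": df[3].str.strip(),
        "chrom": df[0].str.strip(),
        "start": _to_float(df[1], "start", path).astype(np.int64),
        "end": _to_float(df[2], "end", path).astype(np.int64),
        "source": df[4].str.strip() if df.shape[1] > 4 else "non_assembly",
    })
    # family = locus id minus its serial suffix
    out["family"] = out["locus_id"].str.rsplit(".", n=1).str[0]
    return out[["locus_id", "chrom", "start", "end", "family", "source"]]


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "locus_id") -> None:
    """Write a labelled matrix (presence, frequency, MIR ...) as TSV with
    dot decimals."""
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    for col in df.columns:
        df[col] = _to_float(df[col], col, path)
    return df


def read_region_frequency_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a published-style per-locus frequency listing.

    Expected columns: ``locus_id, chrom, position`` (1-based) followed by
    one frequency column per species; decimal commas accepted.  Returns
    ``(loci, freq)`` ready for the region screen: loci get a 1 bp half-open
    interval at the stated position.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("locus_id", "chrom", "position"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    pos = _to_float(df["position"], "position", path).astype(np.int64) - 1
    loci = pd.DataFrame({
        "locus_id": df["locus_id"].str.strip(),
        "chrom": df["chrom"].str.strip(),
        "start": pos,
        "end": pos + 1,
        "family": df["locus_id"].str.strip().str.rsplit(".", n=1).str[0],
        "source": "non_assembly",
    })
    freq_cols = [c for c in df.columns if c not in ("locus_id", "chrom", "position")]
    freq = pd.DataFrame(
        {c: _to_float(df[c], c, path).to_numpy() for c in freq_cols},
        index=loci["locus_id"].to_numpy(),
    )
    return loci, freq
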
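"""Locus sharing, chromosomal density, the differentiated-region screen,
and the group-comparison statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SHARING_CLASSES = ("all_species", "multi_species", "private", "undetected")


@dataclass
class SharingSummary:
    per_locus: pd.DataFrame  # columns: n_groups_present, sharing_class
    class_counts: dict[str, int]
    all_species_percent: float

    def summary_line(self) -> str:
        total = int(sum(self.class_counts.values()))
        n_all = self.class_counts.get("all_species", 0)
        return (
            f"{n_all} of {total} loci ({self.all_species_percent:.1f}%) "
            "detected in all species"
        )


def classify_sharing(freq: pd.DataFrame) -> SharingSummary:
    """Classify each locus by the number of groups it is detected in.

    ``all_species``: detected in every group of the frequency table (the
    fixed-candidate set); ``private``: exactly one group; ``multi_species``:
    anything in between; ``undetected``: no group at all.
    """
    n_groups = len(freq.columns)
    present = (freq > 0).sum(axis=1)
    cls = np.select(
        [present == n_groups, present == 1, present == 0],
        ["all_species", "private", "undetected"],
        default="multi_species",
    )
    per_locus = pd.DataFrame({"n_groups_present": present, "sharing_class": cls})
    counts = {c: int((cls == c).sum()) for c in SHARING_CLASSES}
    total = len(freq)
    pct = round(100.0 * counts["all_species"] / total, 1) if total else float("nan")
    return SharingSummary(per_locus, counts, pct)


@dataclass
class ChromDensity:
    per_chrom: pd.DataFrame        # chrom, n_loci, length_bp, density_per_mbp
    profiles: pd.DataFrame         # chrom, bin, bin_start, bin_end, n_loci
    end_enrichment_ratio: float    # pooled terminal vs interior density
    pairwise_relative_diff: pd.DataFrame = field(default_factory=pd.DataFrame)


def chromosome_density(
    loci: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bins: int = 20,
    terminal_fraction: float = 0.1,
) -> ChromDensity:
    """Per-chromosome locus density and positional profile.

    Uses locus midpoints.  The end-enrichment ratio pools all chromosomes:
    mean density inside the two terminal windows of width
    ``terminal_fraction * L`` divided by mean density in the interior.
    """
    rows, prof_rows = [], []
    term_count = term_len = mid_count = mid_len = 0.0
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        sub = loci[loci["chrom"] == chrom]
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy(np.int64)
        rows.append((chrom, len(sub), length, len(sub) / (length / 1e6)))
        edges = np.linspace(0, length, bins + 1)
        counts, _ = np.histogram(mids, bins=edges)
        for b in range(bins):
            prof_rows.append((chrom, b, int(edges[b]), int(edges[b + 1]), int(counts[b])))
        t = terminal_fraction * length
        n_term = int(((mids < t) | (mids >= length - t)).sum())
        term_count += n_term
        term_len += 2 * t
        mid_count += len(sub) - n_term
        mid_len += length - 2 * t
    per_chrom = pd.DataFrame(rows, columns=["chrom", "n_loci", "length_bp", "density_per_mbp"])
    profiles = pd.DataFrame(prof_rows, columns=["chrom", "bin", "bin_start", "bin_end", "n_loci"])
    interior_density = mid_count / mid_len if mid_len else float("nan")
    terminal_density = term_count / term_len if term_len else float("nan")
    ratio = terminal_density / interior_density if interior_density else float("inf")
    d = per_chrom.set_index("chrom")["density_per_mbp"]
    pair = pd.DataFrame(
        {
            ci: {
                cj: abs(d[ci] - d[cj]) / min(d[ci], d[cj]) if min(d[ci], d[cj]) > 0 else np.nan
                for cj in d.index
            }
            for ci in d.index
        }
    )
    return ChromDensity(per_chrom, profiles, float(ratio), pair)


def region_contrast_screen(
    freq: pd.DataFrame,
    loci: pd.DataFrame,
    regions: pd.DataFrame,
    species_a: str,
    species_b: str,
    mid_species: str | None = None,
    min_delta: float = 0.4,
) -> pd.DataFrame:
    """Frequency-contrast screen over differentiated regions.

    Intersects loci with region intervals (>=1 bp overlap) and reports
    every in-region locus with ``|f_A - f_B| >= min_delta``, sorted by
    delta descending.  The mid-species frequency is carried along for
    inspection but not filtered on.

    ``regions`` needs columns ``region_id, chrom, start, end``.
    """
    for sp in (species_a, species_b) + ((mid_species,) if mid_species else ()):
        if sp not in freq.columns:
            raise ValueError(f"species {sp!r} absent from frequency table")
    if regions.empty or loci.empty:
        cols = ["locus_id", "region_id", "chrom", "start", "end",
                "f_high_species", "f_mid_species", "f_low_species", "delta"]
        return pd.DataFrame(columns=cols)
    rows = []
    for _, reg in regions.iterrows():
        hit = loci[
            (loci["chrom"] == reg["chrom"])
            & (loci["start"] < reg["end"])
            & (loci["end"] > reg["start"])
        ]
        for _, loc in hit.iterrows():
            lid = loc["locus_id"]
            if lid not in freq.index:
                continue
            fa = float(freq.at[lid, species_a])
            fb = float(freq.at[lid, species_b])
            fm = float(freq.at[lid, mid_species]) if mid_species else float("nan")
            rows.append(
                (lid, reg["region_id"], loc["chrom"], loc["start"], loc["end"],
                 fa, fm, fb, fa - fb)
            )
    out = pd.DataFrame(
        rows,
        columns=["locus_id", "region_id", "chrom", "start", "end",
                 "f_high_species", "f_mid_species", "f_low_species", "delta"],
    ).drop_duplicates("locus_id")
    out = out[out["delta"].abs() >= min_delta]
    return out.sort_values("delta", ascending=False, kind="mergesort").reset_index(drop=True)


def welch_t(group_x, group_y) -> tuple[float, float, float]:
    """Welch's two-sample t-test (two-sided): (t, Satterthwaite df, p)."""
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def one_way_anova(groups) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA: (F, df_between, df_within, p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    k = len(arrays)
    n = sum(a.size for a in arrays)
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, k - 1, n - k, 1.0
    res = stats.f_oneway(*arrays)
    # identical group means can leave float noise (tiny negative F, nan p)
    f = max(float(res.statistic), 0.0)
    return f, k - 1, n - k, float(stats.f.sf(f, k - 1, n - k))
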
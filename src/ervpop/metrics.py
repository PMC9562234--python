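"""Population-level ERV statistics.

Frequencies here are individual-level detection frequencies (the fraction
of a group's individuals in which a locus was identified), not allele
frequencies: the callers report presence, not zygosity.  The false-negative
calibration exploits ancestral loci expected to be carried homozygously by
everyone — any shortfall of their observed frequency from 1.0 measures the
miss rate of the detection pipeline.

Relative abundance normalises per-individual family counts by the
individual's total identifications, removing coverage-driven scale
differences; the median identification ratio (MIR) then contrasts a group's
typical relative abundance of a family against the cohort-wide typical
value (MIR > 1: the family makes up a larger share of that group's ERVs).
The modified MIR applies the same contrast island-population vs own
species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CalibrationResult:
    fixed_locus_ids: list[str]
    mean_fixed_frequency: float
    false_negative_rate: float


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    degenerate: bool = False


def resolve_scope(
    samples: pd.DataFrame, scope: str, outgroup_species: tuple[str, ...] | list[str] = ()
) -> list[str]:
    """Group labels included in a fixed-locus scope.

    ``species_only`` keeps non-hybrid focal species; ``species_plus_outgroups``
    adds the outgroup species; ``all_groups`` also keeps hybrid groups.
    """
    species = samples["species"].unique().tolist()
    hybrids = set(samples.loc[samples["is_hybrid"], "species"].unique())
    outgroups = set(outgroup_species)
    if scope == "all_groups":
        return species
    if scope == "species_plus_outgroups":
        return [s for s in species if s not in hybrids]
    if scope == "species_only":
        return [s for s in species if s not in hybrids and s not in outgroups]
    raise ValueError(f"unknown fixed_locus_scope {scope!r}")


def species_frequency(presence: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-locus detection frequency within each species group.

    ``presence`` is the loci x individuals count matrix; an individual
    counts as a carrier when its entry is >= 1.
    """
    missing = set(presence.columns) - set(samples["individual_id"])
    if missing:
        raise ValueError(f"individuals without metadata: {sorted(missing)[:5]}")
    binary = (presence >= 1).astype(float)
    out = {}
    for group, members in samples.groupby("species")["individual_id"]:
        cols = [m for m in members if m in binary.columns]
        if not cols:
            raise ValueError(f"group {group!r} has no individuals in the presence matrix")
        out[group] = binary[cols].mean(axis=1)
    return pd.DataFrame(out)


def fixed_locus_calibration(
    freq: pd.DataFrame,
    groups_in_scope: list[str] | None = None,
    loci: pd.DataFrame | None = None,
    sources: tuple[str, ...] = ("non_assembly",),
) -> CalibrationResult:
    """Estimate the false-negative rate from putatively fixed loci.

    Candidates are loci detected (frequency > 0) in *every* in-scope group;
    under the assumption that such loci pre-date the radiation and are fixed
    homozygous, their expected frequency is 1.0 and the shortfall of the
    grand mean frequency is the false-negative rate.

    When a locus frame is supplied, candidates are restricted to the given
    ``sources`` (non-assembly by default): the calibration measures the
    miss rate of insertion detection, whereas assembly-side presence is
    scored by the *absence* of a deletion call and so errs towards false
    positives, which would bias the estimate.
    """
    cols = list(groups_in_scope) if groups_in_scope is not None else list(freq.columns)
    missing = [c for c in cols if c not in freq.columns]
    if missing:
        raise ValueError(f"groups absent from frequency table: {missing}")
    sub = freq[cols]
    if loci is not None:
        eligible = loci.loc[loci["source"].isin(sources), "locus_id"]
        sub = sub.loc[sub.index.intersection(eligible)]
    fixed = sub.index[(sub > 0).all(axis=1)].tolist()
    if not fixed:
        return CalibrationResult([], float("nan"), float("nan"))
    mean_freq = float(sub.loc[fixed].mean(axis=1).mean())
    return CalibrationResult(fixed, mean_freq, 1.0 - mean_freq)


def relative_abundance(presence: pd.DataFrame, loci: pd.DataFrame) -> pd.DataFrame:
    """Individuals x families matrix of relative identification shares.

    Family counts sum identification counts over the loci annotated with
    each family, then divide by the individual's total; rows sum to 1.
    Individuals with zero identifications are dropped with a warning.
    """
    fam = loci.set_index("locus_id")["family"].reindex(presence.index)
    by_family = presence.groupby(fam.to_numpy()).sum()  # families x individuals
    totals = by_family.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"dropping {len(empty)} individual(s) with zero identifications")
    keep = totals.index[totals > 0]
    return (by_family[keep] / totals[keep]).T  # individuals x families


def compute_mir(
    abundance: pd.DataFrame, samples: pd.DataFrame, grouping: str = "species"
) -> pd.DataFrame:
    """Median identification ratio per family and group.

    ``grouping="species"``: group median over the cohort-wide median.
    ``grouping="species_island"``: island-population median over that
    species' median (columns are ``species|island`` labels).  Entries where
    the denominator median is 0 are NaN.
    """
    meta = samples.set_index("individual_id").loc[abundance.index]
    if grouping == "species":
        denom = abundance.median(axis=0)
        out = {}
        for group, members in meta.groupby("species").groups.items():
            num = abundance.loc[list(members)].median(axis=0)
            out[group] = num / denom.where(denom > 0)
        return pd.DataFrame(out)
    if grouping == "species_island":
        out = {}
        for (sp, isl), members in meta.groupby(["species", "island"]).groups.items():
            sp_members = meta.index[meta["species"] == sp]
            denom = abundance.loc[sp_members].median(axis=0)
            num = abundance.loc[list(members)].median(axis=0)
            out[f"{sp}|{isl}"] = num / denom.where(denom > 0)
        return pd.DataFrame(out)
    raise ValueError(f"grouping must be 'species' or 'species_island', got {grouping!r}")


def loci_vs_identifications_fit(
    loci: pd.DataFrame, presence: pd.DataFrame
) -> RegressionSummary:
    """OLS of per-family total identifications on per-family locus count."""
    fam = loci.set_index("locus_id")["family"].reindex(presence.index)
    locus_counts = loci.groupby("family").size()
    idents = presence.sum(axis=1).groupby(fam.to_numpy()).sum()
    families = locus_counts.index.intersection(idents.index)
    if len(families) < 3:
        raise ValueError("need at least 3 families for a regression")
    return _ols(locus_counts[families].to_numpy(float), idents[families].to_numpy(float))


def detection_vs_coverage_fit(
    presence: pd.DataFrame,
    samples: pd.DataFrame,
    fixed_locus_ids: list[str],
) -> RegressionSummary:
    """OLS of per-individual fixed-locus detection rate on mean coverage."""
    if len(samples) < 3:
        raise ValueError("need at least 3 individuals")
    rate = (presence.loc[fixed_locus_ids] >= 1).mean(axis=0)
    cov = samples.set_index("individual_id")["mean_coverage"].reindex(rate.index)
    return _ols(cov.to_numpy(float), rate.to_numpy(float))


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionSummary:
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=len(x),
        degenerate=len(x) == 2,
    )
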
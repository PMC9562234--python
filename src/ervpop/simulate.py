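"""Synthetic multi-species, multi-island ERV cohort with known truth.

The generator emulates the structure of a songbird radiation cohort: a set
of focal species, each subdivided into island populations, plus optional
outgroup species; a backbone of ancestral ERV loci fixed (homozygous) in
every individual; and a larger set of younger polymorphic loci, each
segregating in a subset of species under Hardy–Weinberg proportions, with
optional per-species bursts of particular ERV families.

Detection is modelled per individual x carried locus as an independent
Bernoulli draw whose probability depends on zygosity and sequencing
coverage: homozygous loci are missed at a flat rate (default 8%),
heterozygous loci follow a sensitivity line rising from 45% at 4x coverage
to 100% at 30x.  Detected loci are emitted as caller-style call tables —
insertion calls for loci absent from the reference assembly, and deletion
calls (two dialects) plus similarity blocks for the small fraction of loci
present in the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import DELETION_COLUMNS, INSERTION_COLUMNS, SIMILARITY_COLUMNS

DEFAULT_CHROM_LENGTHS = {
    "chr1": 120_000_000,
    "chr1A": 74_000_000,
    "chr2": 156_000_000,
    "chr3": 112_000_000,
    "chr4": 70_000_000,
}


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort.

    Detection defaults encode the study conditions: 8% miss rate for
    homozygous loci regardless of coverage, 45% heterozygous sensitivity at
    4x rising linearly to saturation at 30x, individual coverages uniform on
    6–49x.  ``assembly_fraction`` defaults to the observed share of
    reference-assembly loci (698 of 26,964).  Polymorphic loci are each
    restricted to a proper subset of the focal species (every segregating
    locus is missing from at least one species), with the number of carrier
    species geometrically distributed towards 1.
    """

    n_species: int = 5
    n_outgroup_species: int = 0
    islands_per_species: int = 2
    individuals_per_population: int = 10
    n_fixed_ancestral_loci: int = 300
    n_polymorphic_loci: int = 700
    n_families: int = 8
    family_enrichment: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    hom_miss_prob: float = 0.08
    het_sensitivity_at_4x: float = 0.45
    het_anchor_coverage: float = 4.0
    het_saturation_coverage: float = 30.0
    coverage_range: tuple[float, float] = (6.0, 49.0)
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    end_enrichment_factor: float = 2.0
    terminal_fraction: float = 0.1
    assembly_fraction: float = 698 / 26_964
    sv_dialect_fraction: float = 491 / 698
    stringent_pass_prob: float = 0.8
    poly_freq_beta: tuple[float, float] = (0.8, 2.0)
    carrier_species_geom_p: float = 0.5
    family_weight_alpha: float = 1.0  # Zipf exponent over family ranks; 0 = uniform sizes
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("hom_miss_prob", "het_sensitivity_at_4x", "assembly_fraction",
                     "sv_dialect_fraction", "stringent_pass_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_species", "islands_per_species", "individuals_per_population",
                     "n_families"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_fixed_ancestral_loci < 0 or self.n_polymorphic_loci < 0:
            raise ValueError("locus counts must be non-negative")
        if self.het_saturation_coverage <= self.het_anchor_coverage:
            raise ValueError("het_saturation_coverage must exceed het_anchor_coverage")
        if self.end_enrichment_factor < 1.0:
            raise ValueError("end_enrichment_factor must be >= 1")
        if not 0.0 < self.terminal_fraction < 0.5:
            raise ValueError("terminal_fraction must lie in (0, 0.5)")
        if self.coverage_range[0] <= 0 or self.coverage_range[1] < self.coverage_range[0]:
            raise ValueError("coverage_range must be positive and ordered")

    @property
    def family_names(self) -> list[str]:
        return [f"cPa{100 + i}" for i in range(self.n_families)]


@dataclass
class TruthSet:
    """Ground truth of a simulated cohort.

    ``loci`` has columns ``truth_id, chrom, position, length, family,
    is_assembly`` (position is the 0-based insertion point; ``length`` is
    the reference footprint of assembly-side loci, 0 otherwise).
    ``zygosity`` is a loci x individuals int matrix of true ERV copy
    numbers (0/1/2), column order matching ``individuals``.
    """

    loci: pd.DataFrame
    zygosity: np.ndarray
    individuals: list[str]

    def carrier_matrix(self) -> pd.DataFrame:
        """Binary loci x individuals truth: 1 where >=1 copy is carried."""
        return pd.DataFrame(
            (self.zygosity >= 1).astype(np.int8),
            index=self.loci["truth_id"].to_numpy(),
            columns=self.individuals,
        )

    def family_counts(self) -> pd.DataFrame:
        """True per-individual counts of carried loci per family."""
        carrier = self.zygosity >= 1
        fam = self.loci["family"].to_numpy()
        out = {}
        for f in np.unique(fam):
            out[f] = carrier[fam == f].sum(axis=0)
        return pd.DataFrame(out, index=self.individuals).T.sort_index()


def detection_probability(
    zygosity: int | np.ndarray,
    coverage: float | np.ndarray,
    params: SimulationParams,
) -> float | np.ndarray:
    """Probability that a locus with the given true zygosity yields a call.

    Zygosity 0 is never detected; homozygous loci (2 copies) are detected at
    ``1 - hom_miss_prob`` independent of coverage; heterozygous loci follow
    a line through (4x, het_sensitivity_at_4x) and (saturation, 1.0),
    clamped to [0, 1] and held at 1.0 above saturation.
    """
    z = np.asarray(zygosity)
    cov = np.asarray(coverage, dtype=float)
    if np.any(cov <= 0):
        raise ValueError("coverage must be positive")
    slope = (1.0 - params.het_sensitivity_at_4x) / (
        params.het_saturation_coverage - params.het_anchor_coverage
    )
    het = np.clip(
        params.het_sensitivity_at_4x + (cov - params.het_anchor_coverage) * slope,
        0.0,
        1.0,
    )
    p = np.select(
        [z == 0, z == 1, z == 2],
        [np.zeros_like(het), het, np.full_like(het, 1.0 - params.hom_miss_prob)],
    )
    if np.isscalar(zygosity) and np.isscalar(coverage):
        return float(p)
    return p


def _draw_positions(n: int, length: int, params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Positions on one chromosome, uniform with optional terminal excess.

    Density in the two terminal windows of width ``terminal_fraction * L``
    is ``end_enrichment_factor`` times the density elsewhere.
    """
    t = params.terminal_fraction
    g = params.end_enrichment_factor
    p_terminal = 2 * t * g / (2 * t * g + (1 - 2 * t))
    in_terminal = rng.random(n) < p_terminal
    u = rng.random(n)
    pos = np.empty(n, dtype=np.int64)
    tlen = t * length
    # terminal mass splits evenly between the two ends
    left = in_terminal & (rng.random(n) < 0.5)
    right = in_terminal & ~left
    pos[left] = (u[left] * tlen).astype(np.int64)
    pos[right] = length - 1 - (u[right] * tlen).astype(np.int64)
    mid = ~in_terminal
    pos[mid] = (tlen + u[mid] * (length - 2 * tlen)).astype(np.int64)
    return np.clip(pos, 0, length - 1)


def _spaced_positions(
    n: int, params: SimulationParams, rng: np.random.Generator, min_gap: int = 250
) -> tuple[np.ndarray, np.ndarray]:
    """(chrom_index, position) for n loci, no two closer than min_gap."""
    chroms = list(params.chrom_lengths)
    lengths = np.array([params.chrom_lengths[c] for c in chroms], dtype=np.int64)
    if n > lengths.sum() // min_gap:
        raise ValueError("more loci requested than the genome can hold")
    weights = lengths / lengths.sum()
    ci = rng.choice(len(chroms), size=n, p=weights)
    pos = np.empty(n, dtype=np.int64)
    for k, length in enumerate(lengths):
        idx = np.flatnonzero(ci == k)
        pos[idx] = _draw_positions(idx.size, int(length), params, rng)
    for _ in range(100):
        order = np.lexsort((pos, ci))
        gaps_ok = np.ones(n, dtype=bool)
        same = np.diff(ci[order]) == 0
        close = np.diff(pos[order]) < min_gap
        gaps_ok[order[1:][same & close]] = False
        if gaps_ok.all():
            return ci, pos
        # redraw only the colliding loci
        n_bad = int((~gaps_ok).sum())
        ci_new = rng.choice(len(chroms), size=n_bad, p=weights)
        pos_new = np.empty(n_bad, dtype=np.int64)
        for k, length in enumerate(lengths):
            idx = np.flatnonzero(ci_new == k)
            pos_new[idx] = _draw_positions(idx.size, int(length), params, rng)
        ci[~gaps_ok] = ci_new
        pos[~gaps_ok] = pos_new
    raise RuntimeError("could not place loci with the requested spacing")


def simulate_cohort(params: SimulationParams) -> tuple[TruthSet, pd.DataFrame]:
    """Draw a cohort: sample table plus true loci and zygosities.

    Fixed ancestral loci are homozygous in every individual, outgroups
    included.  Each polymorphic locus is assigned a carrier subset of the
    focal species (never all of them), and within each carrier island
    population an insertion allele frequency from a low-skewed Beta
    distribution; individual zygosities are Hardy–Weinberg draws.  Species
    listed in ``family_enrichment`` are proportionally more likely to carry
    loci of the enriched family.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    species = [f"species_{i + 1:02d}" for i in range(params.n_species)]
    outgroups = [f"outgroup_{i + 1:02d}" for i in range(params.n_outgroup_species)]
    rows = []
    for sp in species:
        for isl in range(params.islands_per_species):
            island = f"island_{chr(ord('A') + isl)}"
            for k in range(params.individuals_per_population):
                rows.append((f"{sp}.{island}.ind{k + 1:02d}", sp, island, False))
    for og in outgroups:
        for k in range(params.individuals_per_population):
            rows.append((f"{og}.ind{k + 1:02d}", og, "", False))
    samples = pd.DataFrame(rows, columns=["individual_id", "species", "island", "is_hybrid"])
    samples["mean_coverage"] = rng.uniform(*params.coverage_range, size=len(samples))
    n_ind = len(samples)

    n_loci = params.n_fixed_ancestral_loci + params.n_polymorphic_loci
    chroms = list(params.chrom_lengths)
    ci, pos = _spaced_positions(n_loci, params, rng)
    # family sizes are strongly skewed in real ERV landscapes
    fam_w = (np.arange(1, params.n_families + 1, dtype=float)) ** (-params.family_weight_alpha)
    fam_idx = rng.choice(params.n_families, size=n_loci, p=fam_w / fam_w.sum())
    families = np.array(params.family_names, dtype=object)[fam_idx]
    is_assembly = rng.random(n_loci) < params.assembly_fraction
    loci = pd.DataFrame(
        {
            "truth_id": [f"T{i:06d}" for i in range(n_loci)],
            "chrom": np.array(chroms, dtype=object)[ci],
            "position": pos,
            "length": np.where(is_assembly, rng.integers(500, 8_000, size=n_loci), 0),
            "family": families,
            "is_assembly": is_assembly,
            "is_fixed": np.arange(n_loci) < params.n_fixed_ancestral_loci,
        }
    )

    zyg = np.zeros((n_loci, n_ind), dtype=np.int8)
    zyg[: params.n_fixed_ancestral_loci, :] = 2

    # population index: species -> list of individual row-index arrays
    pop_members = {}
    for (sp, _isl), idx in samples.groupby(["species", "island"]).groups.items():
        pop_members.setdefault(sp, []).append(np.asarray(idx))
    a, b = params.poly_freq_beta
    # carrier-species count: truncated geometric over 1..n_species-1
    max_k = max(1, params.n_species - 1)
    ks = np.arange(1, max_k + 1)
    kw = (1 - params.carrier_species_geom_p) ** (ks - 1)
    kw /= kw.sum()
    for j in range(params.n_fixed_ancestral_loci, n_loci):
        fam = loci.at[j, "family"]
        weights = np.array(
            [params.family_enrichment.get(sp, {}).get(fam, 1.0) for sp in species], float
        )
        k = rng.choice(ks, p=kw)
        carriers = rng.choice(species, size=k, replace=False, p=weights / weights.sum())
        for sp in carriers:
            for idx in pop_members[sp]:
                q = min(rng.beta(a, b), 0.95)
                zyg[j, idx] = rng.binomial(2, q, size=idx.size)
    return TruthSet(loci=loci, zygosity=zyg, individuals=samples["individual_id"].tolist()), samples


def emit_call_tables(
    truth: TruthSet,
    samples: pd.DataFrame,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Push the truth through the detection model into caller-style tables.

    Returns ``{"insertions", "cnv_deletions", "sv_deletions",
    "similarity_blocks"}``.  Non-assembly carried loci yield insertion calls
    with probability :func:`detection_probability`; emitted calls always
    pass the relaxed filter and pass the stringent filter with probability
    ``stringent_pass_prob``.  Assembly-side loci are represented inversely:
    individuals *lacking* copies yield deletion calls (read-depth dialect
    for homozygous absence only; split-read dialect with a 0/1/2 genotype),
    and each assembly locus contributes one similarity block.
    """
    if list(samples["individual_id"]) != truth.individuals:
        raise ValueError("samples and truth describe different individuals")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed + 1)
    cov = samples["mean_coverage"].to_numpy(float)
    ind_ids = np.array(truth.individuals, dtype=object)
    loci = truth.loci
    zyg = truth.zygosity

    # --- non-assembly loci -> insertion calls -------------------------------
    na = ~loci["is_assembly"].to_numpy()
    na_idx = np.flatnonzero(na)
    z = zyg[na_idx, :]
    p = detection_probability(z, cov[None, :], params)
    hit = rng.random(p.shape) < p
    li, ii = np.nonzero(hit)
    li = na_idx[li]
    n_calls = li.size
    stringent = rng.random(n_calls) < params.stringent_pass_prob
    insertions = pd.DataFrame(
        {
            "individual_id": ind_ids[ii],
            "chrom": loci["chrom"].to_numpy(object)[li],
            "position": loci["position"].to_numpy(np.int64)[li],
            "family": loci["family"].to_numpy(object)[li],
            "filter_level": np.where(stringent, 8, 5),
            "genotype_quality": rng.uniform(10, 200, size=n_calls).round(1),
            "clip5": 2,
            "clip3": 2,
            "support_reads": np.where(
                stringent, 5 + rng.poisson(3, size=n_calls), 1 + rng.poisson(1, size=n_calls)
            ),
        },
        columns=INSERTION_COLUMNS,
    )

    # --- assembly loci -> deletion calls + similarity blocks ----------------
    asm_idx = np.flatnonzero(loci["is_assembly"].to_numpy())
    sim_blocks = pd.DataFrame(
        {
            "chrom": loci["chrom"].to_numpy(object)[asm_idx],
            "start": loci["position"].to_numpy(np.int64)[asm_idx],
            "end": loci["position"].to_numpy(np.int64)[asm_idx]
            + loci["length"].to_numpy(np.int64)[asm_idx],
            "family": loci["family"].to_numpy(object)[asm_idx],
        },
        columns=SIMILARITY_COLUMNS,
    )
    is_sv = rng.random(asm_idx.size) < params.sv_dialect_fraction
    cnv_rows, sv_rows = [], []
    det_hom = 1.0 - params.hom_miss_prob
    for k, j in enumerate(asm_idx):
        start = int(loci.at[j, "position"])
        end = start + int(loci.at[j, "length"])
        chrom = loci.at[j, "chrom"]
        zj = zyg[j, :]
        if is_sv[k]:
            for i in np.flatnonzero(zj < 2):
                gt = 2 - int(zj[i])  # deletion-allele count
                p_det = det_hom if gt == 2 else float(
                    detection_probability(1, cov[i], params)
                )
                if rng.random() < p_det:
                    sv_rows.append(
                        (ind_ids[i], chrom, start, end, "sv", np.nan, np.nan,
                         2 + rng.poisson(5), gt)
                    )
        else:
            # read-depth dialect: only full absence produces a deletion signal
            for i in np.flatnonzero(zj == 0):
                if rng.random() < det_hom:
                    good = rng.random() < params.stringent_pass_prob
                    e1 = rng.uniform(0, 0.05) if good else rng.uniform(0.051, 1.0)
                    e2 = rng.uniform(0, 0.05)
                    cnv_rows.append(
                        (ind_ids[i], chrom, start, end, "cnv", round(e1, 4),
                         round(e2, 4), np.nan, np.nan)
                    )
    cnv_deletions = pd.DataFrame(cnv_rows, columns=DELETION_COLUMNS)
    sv_deletions = pd.DataFrame(sv_rows, columns=DELETION_COLUMNS)
    return {
        "insertions": insertions,
        "cnv_deletions": cnv_deletions,
        "sv_deletions": sv_deletions,
        "similarity_blocks": sim_blocks,
    }
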
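"""Run configuration for the ERV population pipeline.

All thresholds used by the filter cascades and downstream screens live in a
single :class:`AnalysisConfig` so that a run is fully described by one YAML
file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

FIXED_LOCUS_SCOPES = ("species_only", "species_plus_outgroups", "all_groups")


@dataclass
class InsertionFilter:
    """Thresholds for one insertion-call filter tier (RetroSeq-style fields)."""

    min_support_reads: int
    min_filter_level: int
    min_gq: float | None = None
    max_gq: float | None = None
    min_clip3: int | None = None
    min_clip5: int | None = None


@dataclass
class DeletionFilter:
    """Thresholds for the two deletion-call dialects.

    ``cnv`` calls (read-depth caller) are gated on two p-value-like scores;
    ``sv`` calls (split/discordant-read caller) on length and read support.
    """

    max_eval1: float = 0.05
    max_eval2: float = 0.05
    cnv_max_length: int | None = 20_000
    sv_min_length: int = 90
    sv_max_length: int = 20_000
    sv_min_support_reads: int = 2


@dataclass
class AnalysisConfig:
    """Tunable parameters of the pipeline.

    Defaults reproduce the published filter settings: stringent insertion
    calls need >=5 supporting reads at the top confidence tier (FL 8) with
    genotype quality in [10, 200] and soft-clip support on both sides;
    relaxed re-counting accepts single-read calls at FL 5.  Point insertion
    calls are extended 50 bp in both directions before merging into loci.
    """

    extension_bp: int = 50
    stringent: InsertionFilter = field(
        default_factory=lambda: InsertionFilter(
            min_support_reads=5, min_filter_level=8,
            min_gq=10.0, max_gq=200.0, min_clip3=2, min_clip5=2,
        )
    )
    relaxed: InsertionFilter = field(
        default_factory=lambda: InsertionFilter(min_support_reads=1, min_filter_level=5)
    )
    deletion_stringent: DeletionFilter = field(default_factory=DeletionFilter)
    deletion_relaxed: DeletionFilter = field(
        # relaxed tier re-states only the score thresholds; no length cap
        default_factory=lambda: DeletionFilter(max_eval1=1.0, max_eval2=1.0, cnv_max_length=None)
    )
    contrast_min_delta: float = 0.4
    fixed_locus_scope: str = "species_plus_outgroups"
    outgroup_species: Sequence[str] = ()
    terminal_fraction: float = 0.1
    density_bins: int = 20
    rng_seed: int = 0

    def validate(self) -> None:
        if self.extension_bp < 0:
            raise ValueError("extension_bp must be non-negative")
        if not 0.0 <= self.contrast_min_delta <= 1.0:
            raise ValueError("contrast_min_delta must lie in [0, 1]")
        if self.fixed_locus_scope not in FIXED_LOCUS_SCOPES:
            raise ValueError(
                f"fixed_locus_scope must be one of {FIXED_LOCUS_SCOPES}, "
                f"got {self.fixed_locus_scope!r}"
            )
        if not 0.0 < self.terminal_fraction < 0.5:
            raise ValueError("terminal_fraction must lie in (0, 0.5)")
        if self.density_bins < 1:
            raise ValueError("density_bins must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("stringent", "relaxed"):
            if key in raw:
                raw[key] = InsertionFilter(**raw[key])
        for key in ("deletion_stringent", "deletion_relaxed"):
            if key in raw:
                raw[key] = DeletionFilter(**raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
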
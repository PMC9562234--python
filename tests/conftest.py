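from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import ervpop as e
from ervpop.filtering import INSERTION_COLUMNS

DATA = Path(__file__).parent / "data"


def make_insertion_calls(rows):
    """Build an insertion-call frame from (individual, chrom, pos, family,
    FL, GQ, clip5, clip3, reads) tuples."""
    return pd.DataFrame(rows, columns=INSERTION_COLUMNS)


@pytest.fixture(scope="session")
def data_dir():
    return DATA


@pytest.fixture(scope="session")
def small_params():
    return e.SimulationParams(
        n_species=3,
        islands_per_species=2,
        individuals_per_population=5,
        n_fixed_ancestral_loci=60,
        n_polymorphic_loci=120,
        n_families=5,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    truth, samples = e.simulate_cohort(small_params)
    tables = e.emit_call_tables(truth, samples, small_params)
    return truth, samples, tables


def run_pipeline(tables, samples, config=None):
    """Filtered calls -> locus frame -> presence matrix -> frequencies."""
    cfg = config or e.AnalysisConfig()
    stringent = e.filter_insertions_stringent(tables["insertions"], cfg)
    relaxed = e.filter_insertions_relaxed(tables["insertions"], cfg)
    dels = pd.concat(
        [tables["cnv_deletions"], tables["sv_deletions"]], ignore_index=True
    )
    dels_str = e.annotate_with_similarity(
        e.filter_deletions(dels, "stringent", cfg), tables["similarity_blocks"]
    )
    dels_rel = e.annotate_with_similarity(
        e.filter_deletions(dels, "relaxed", cfg), tables["similarity_blocks"]
    )
    frame = e.unify_locus_frame(
        e.merge_insertions_to_loci(stringent, cfg.extension_bp),
        e.build_assembly_loci(dels_str),
    )
    presence = e.genotype_presence(frame, relaxed, dels_rel, samples, cfg.extension_bp)
    freq = e.species_frequency(presence, samples)
    return frame, presence, freq


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    truth, samples, tables = small_cohort
    frame, presence, freq = run_pipeline(tables, samples)
    return truth, samples, frame, presence, freq


@pytest.fixture(scope="session")
def perfect_params():
    # error-free detection: every carried locus is called and passes stringent
    return e.SimulationParams(
        n_species=3,
        islands_per_species=1,
        individuals_per_population=8,
        n_fixed_ancestral_loci=40,
        n_polymorphic_loci=80,
        n_families=4,
        hom_miss_prob=0.0,
        het_sensitivity_at_4x=1.0,
        stringent_pass_prob=1.0,
        rng_seed=5,
    )


@pytest.fixture(scope="session")
def perfect_pipeline(perfect_params):
    truth, samples = e.simulate_cohort(perfect_params)
    tables = e.emit_call_tables(truth, samples, perfect_params)
    frame, presence, freq = run_pipeline(tables, samples)
    return truth, samples, frame, presence, freq
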
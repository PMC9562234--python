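import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ervpop as e
from ervpop.metrics import fixed_locus_calibration, resolve_scope


def samples_frame(rows):
    return pd.DataFrame(
        rows, columns=["individual_id", "species", "island", "is_hybrid", "mean_coverage"]
    )


def presence_frame(data, individuals):
    return pd.DataFrame(data, columns=individuals)


class TestSpeciesFrequency:
    def test_detection_fraction_within_group(self):
        samples = samples_frame(
            [(f"b{i}", "A", "", False, 20.0) for i in range(4)]
        )
        presence = presence_frame([[1, 1, 2, 0]], [f"b{i}" for i in range(4)])
        freq = e.species_frequency(presence, samples)
        assert freq.iloc[0]["A"] == 0.75  # count >=1 marks a carrier

    def test_all_present_gives_one_everywhere(self):
        samples = samples_frame(
            [("b1", "A", "", False, 20.0), ("b2", "B", "", False, 20.0)]
        )
        presence = presence_frame([[3, 1], [1, 1]], ["b1", "b2"])
        freq = e.species_frequency(presence, samples)
        assert (freq == 1.0).all().all()

    def test_empty_group_named_in_error(self):
        samples = samples_frame(
            [("b1", "A", "", False, 20.0), ("zz", "Empty", "", False, 20.0)]
        )
        presence = presence_frame([[1]], ["b1"])
        with pytest.raises(ValueError, match="Empty"):
            e.species_frequency(presence, samples)

    def test_recovers_truth_frequency_under_perfect_detection(self, perfect_pipeline):
        truth, samples, frame, presence, freq = perfect_pipeline
        carrier = truth.carrier_matrix()
        sp = samples.set_index("individual_id")["species"]
        truth_freq = carrier.T.groupby(sp).mean().T
        # match loci by position and compare frequency vectors exactly
        na = frame[frame["source"] == "non_assembly"].set_index("locus_id")
        checked = 0
        for tid, row in truth.loci[~truth.loci["is_assembly"]].iterrows():
            hit = na[(na["chrom"] == row["chrom"])
                     & (na["start"] <= row["position"]) & (na["end"] > row["position"])]
            if len(hit) == 1:
                got = freq.loc[hit.index[0]]
                want = truth_freq.loc[row["truth_id"]]
                assert np.allclose(got[want.index], want)
                checked += 1
        assert checked > 50

    def test_invariant_to_individual_order(self, small_pipeline):
        _, samples, _, presence, freq = small_pipeline
        shuffled = presence[presence.columns[::-1]]
        freq2 = e.species_frequency(shuffled, samples.iloc[::-1])
        pd.testing.assert_frame_equal(freq.sort_index(axis=1), freq2.sort_index(axis=1))


class TestFixedLocusCalibration:
    def test_mean_fixed_frequency_092_gives_fn_008(self):
        freq = pd.DataFrame(
            {"A": [0.92, 0.94, 1.0], "B": [0.92, 0.90, 0.84]},
            index=["L1", "L2", "L3"],
        )
        calib = fixed_locus_calibration(freq)
        assert calib.mean_fixed_frequency == pytest.approx(0.92)
        assert calib.false_negative_rate == pytest.approx(0.08)

    def test_candidates_require_detection_in_every_group(self):
        freq = pd.DataFrame({"A": [1.0, 1.0], "B": [0.9, 0.0]}, index=["L1", "L2"])
        calib = fixed_locus_calibration(freq)
        assert calib.fixed_locus_ids == ["L1"]

    def test_no_candidates_gives_undefined_rate(self):
        freq = pd.DataFrame({"A": [1.0], "B": [0.0]}, index=["L1"])
        calib = fixed_locus_calibration(freq)
        assert calib.fixed_locus_ids == []
        assert np.isnan(calib.false_negative_rate)

    def test_perfect_detection_gives_zero_fn(self, perfect_pipeline):
        truth, samples, frame, presence, freq = perfect_pipeline
        calib = fixed_locus_calibration(freq, loci=frame)
        assert calib.false_negative_rate == pytest.approx(0.0)
        assert len(calib.fixed_locus_ids) >= 30

    def test_scope_resolution(self):
        samples = samples_frame([
            ("b1", "A", "", False, 10.0),
            ("b2", "B", "", False, 10.0),
            ("b3", "out1", "", False, 10.0),
            ("b4", "AxB", "", True, 10.0),
        ])
        assert set(resolve_scope(samples, "species_only", ("out1",))) == {"A", "B"}
        assert set(resolve_scope(samples, "species_plus_outgroups", ("out1",))) == {"A", "B", "out1"}
        assert set(resolve_scope(samples, "all_groups", ("out1",))) == {"A", "B", "out1", "AxB"}


class TestRelativeAbundance:
    def loci_frame(self, fams):
        return pd.DataFrame({
            "locus_id": [f"L{i}" for i in range(len(fams))],
            "chrom": "chr1",
            "start": range(0, 1000 * len(fams), 1000),
            "end": range(100, 1000 * len(fams) + 100, 1000),
            "family": fams,
            "source": "non_assembly",
        })

    def test_family_shares(self):
        loci = self.loci_frame(["famA", "famA", "famB"])
        presence = pd.DataFrame({"b1": [2, 1, 1]}, index=["L0", "L1", "L2"])
        ab = e.relative_abundance(presence, loci)
        assert ab.loc["b1", "famA"] == pytest.approx(0.75)
        assert ab.loc["b1", "famB"] == pytest.approx(0.25)

    def test_single_family_is_one(self):
        loci = self.loci_frame(["famA", "famA"])
        presence = pd.DataFrame({"b1": [3, 2]}, index=["L0", "L1"])
        ab = e.relative_abundance(presence, loci)
        assert ab.loc["b1", "famA"] == 1.0

    def test_zero_total_individual_dropped_with_warning(self):
        loci = self.loci_frame(["famA"])
        presence = pd.DataFrame({"b1": [2], "b2": [0]}, index=["L0"])
        with pytest.warns(UserWarning, match="zero identifications"):
            ab = e.relative_abundance(presence, loci)
        assert list(ab.index) == ["b1"]

    @given(st.lists(
        st.lists(st.integers(0, 9), min_size=4, max_size=4), min_size=1, max_size=8,
    ))
    @settings(derandomize=True, max_examples=80)
    def test_rows_sum_to_one(self, matrix):
        loci = self.loci_frame(["famA", "famB", "famC", "famD"])
        presence = pd.DataFrame(
            np.array(matrix).T,
            index=["L0", "L1", "L2", "L3"],
            columns=[f"b{i}" for i in range(len(matrix))],
        )
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ab = e.relative_abundance(presence, loci)
        if not ab.empty:
            assert np.allclose(ab.sum(axis=1), 1.0)


class TestMIR:
    def abundance(self, data, individuals):
        return pd.DataFrame(data, index=individuals)

    def test_group_equal_to_global_gives_one(self):
        samples = samples_frame(
            [(f"b{i}", "A", "", False, 10.0) for i in range(4)]
        )
        ab = self.abundance({"famA": [0.2, 0.4, 0.6, 0.8]}, [f"b{i}" for i in range(4)])
        mir = e.compute_mir(ab, samples, "species")
        assert mir.loc["famA", "A"] == pytest.approx(1.0)

    def test_hand_checked_ratio(self):
        # group median 0.08 over global median 0.053 -> 1.509...
        samples = samples_frame([
            ("b1", "A", "", False, 10.0), ("b2", "A", "", False, 10.0),
            ("b3", "B", "", False, 10.0), ("b4", "B", "", False, 10.0),
            ("b5", "B", "", False, 10.0),
        ])
        ab = self.abundance(
            {"famA": [0.08, 0.08, 0.05, 0.053, 0.02]},
            [f"b{i}" for i in range(1, 6)],
        )
        mir = e.compute_mir(ab, samples, "species")
        assert mir.loc["famA", "A"] == pytest.approx(0.08 / 0.053, rel=1e-12)
        assert mir.loc["famA", "A"] == pytest.approx(1.509, abs=1e-3)

    def test_single_island_species_modified_mir_is_one(self):
        samples = samples_frame(
            [(f"b{i}", "A", "Santiago", False, 10.0) for i in range(5)]
        )
        ab = self.abundance({"famA": [0.1, 0.2, 0.3, 0.4, 0.5],
                             "famB": [0.9, 0.8, 0.7, 0.6, 0.5]},
                            [f"b{i}" for i in range(5)])
        mir = e.compute_mir(ab, samples, "species_island")
        assert np.allclose(mir["A|Santiago"], 1.0)

    def test_zero_denominator_is_missing(self):
        samples = samples_frame([
            ("b1", "A", "", False, 10.0), ("b2", "B", "", False, 10.0),
            ("b3", "B", "", False, 10.0),
        ])
        ab = self.abundance({"famA": [0.5, 0.0, 0.0]}, ["b1", "b2", "b3"])
        mir = e.compute_mir(ab, samples, "species")
        assert np.isnan(mir.loc["famA", "B"])  # global median is 0

    def test_enriched_family_has_elevated_mir(self):
        params = e.SimulationParams(
            n_species=4, islands_per_species=1, individuals_per_population=12,
            n_fixed_ancestral_loci=50, n_polymorphic_loci=500, assembly_fraction=0.0,
            family_enrichment={"species_01": {"cPa100": 8.0}}, rng_seed=13,
        )
        truth, samples = e.simulate_cohort(params)
        tables = e.emit_call_tables(truth, samples, params)
        from conftest import run_pipeline
        frame, presence, freq = run_pipeline(tables, samples)
        ab = e.relative_abundance(presence, frame)
        mir = e.compute_mir(ab, samples, "species")
        fam_col = [f for f in mir.index if f.endswith("cPa100")]
        assert len(fam_col) == 1
        assert mir.loc[fam_col[0], "species_01"] > 1.2


class TestRegressions:
    def test_exact_line_r2_one(self):
        loci = pd.DataFrame({
            "locus_id": [f"L{i}" for i in range(12)],
            "chrom": "chr1",
            "start": np.arange(12) * 1000,
            "end": np.arange(12) * 1000 + 100,
            "family": ["f1"] * 2 + ["f2"] * 4 + ["f3"] * 6,
            "source": "non_assembly",
        })
        # identifications exactly 2x the locus count per family
        presence = pd.DataFrame(
            {"b1": [2] * 12}, index=[f"L{i}" for i in range(12)]
        )
        fit = e.loci_vs_identifications_fit(loci, presence)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_fewer_than_three_families_rejected(self):
        loci = pd.DataFrame({
            "locus_id": ["L0", "L1"], "chrom": "chr1", "start": [0, 1000],
            "end": [100, 1100], "family": ["f1", "f2"], "source": "non_assembly",
        })
        presence = pd.DataFrame({"b1": [1, 1]}, index=["L0", "L1"])
        with pytest.raises(ValueError, match="3 families"):
            e.loci_vs_identifications_fit(loci, presence)

    def test_correlated_counts_give_high_r2(self, small_pipeline):
        _, _, frame, presence, _ = small_pipeline
        fit = e.loci_vs_identifications_fit(frame, presence)
        assert fit.r_squared > 0.5 and fit.p_value < 0.05

    def test_identical_coverage_rejected(self):
        samples = samples_frame([(f"b{i}", "A", "", False, 20.0) for i in range(5)])
        presence = pd.DataFrame(
            {f"b{i}": [1] for i in range(5)}, index=["L0"]
        )
        with pytest.raises(ValueError, match="variance"):
            e.detection_vs_coverage_fit(presence, samples, ["L0"])

    def test_coverage_predicts_detection_under_linear_het_model(self):
        """Individuals spanning 6-49x coverage genotyped at heterozygous
        loci show a significantly positive coverage-detection slope."""
        params = e.SimulationParams(
            n_species=5, islands_per_species=1, individuals_per_population=40,
            n_fixed_ancestral_loci=0, n_polymorphic_loci=200, assembly_fraction=0.0,
            rng_seed=21,
        )
        truth, samples = e.simulate_cohort(params)
        truth.zygosity[:] = 1  # all heterozygous: coverage drives detection
        tables = e.emit_call_tables(truth, samples, params)
        from conftest import run_pipeline
        frame, presence, freq = run_pipeline(tables, samples)
        fit = e.detection_vs_coverage_fit(presence, samples, list(presence.index))
        assert fit.slope > 0 and fit.p_value < 0.01

    def test_no_coverage_effect_under_perfect_detection(self, perfect_pipeline):
        truth, samples, frame, presence, freq = perfect_pipeline
        calib = fixed_locus_calibration(freq, loci=frame)
        fit = e.detection_vs_coverage_fit(presence, samples, calib.fixed_locus_ids)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
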
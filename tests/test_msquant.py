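"""MS quantitation: evidence filters, spectrum counting, XIC fold change, m/z."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleoshift import synthdata
from nucleoshift.msquant import (
    ChromatogramTrace,
    FilterCriteria,
    PsmRecord,
    abundance_ratio,
    extract_apex,
    filter_psms,
    fold_change_from_apexes,
    normalized_fold_change,
    peak_area,
    peptide_mz,
    psms_to_frame,
    round_fold,
    spectrum_count,
)

# Monoisotopic residue masses for the independent m/z oracle (kept separate
# from the implementation's mass backend).
MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_MONO = 18.010565
PROTON = 1.007276


def oracle_mz(seq: str, charge: int) -> float:
    return (sum(MONO[c] for c in seq) + WATER_MONO + charge * PROTON) / charge


def make_psm_frame(rows):
    return psms_to_frame([PsmRecord(**r) for r in rows])


BASE = dict(sample_id="treated", protein_accession="P001", peptide="LLVSASQDGK", charge=2)


class TestFilterPsms:
    def test_boundary_values_retained_inclusively(self):
        # a PSM exactly at 15 product ions and ion score 30 passes
        frame = make_psm_frame(
            [dict(BASE, ion_score=30.0, product_ion_count=15, validated=True)]
        )
        retained, proteins = filter_psms(frame, FilterCriteria())
        assert len(retained) == 1
        assert proteins == ["P001"]

    def test_below_ion_count_boundary_rejected(self):
        frame = make_psm_frame(
            [dict(BASE, ion_score=99.0, product_ion_count=14, validated=True)]
        )
        retained, proteins = filter_psms(frame, FilterCriteria())
        assert retained.empty and proteins == []

    def test_below_score_boundary_rejected(self):
        frame = make_psm_frame(
            [dict(BASE, ion_score=29.99, product_ion_count=20, validated=True)]
        )
        retained, _ = filter_psms(frame, FilterCriteria())
        assert retained.empty

    def test_protein_needs_validated_signature_peptide(self):
        frame = make_psm_frame(
            [dict(BASE, ion_score=50.0, product_ion_count=20, validated=False)]
        )
        retained, proteins = filter_psms(frame, FilterCriteria())
        assert len(retained) == 1  # the PSM survives
        assert proteins == []  # but the protein is not positively identified

    def test_matches_bruteforce_row_scan(self):
        table = synthdata.gen_psm_table(n_records=200, seed=21)
        retained, proteins = filter_psms(table, FilterCriteria())
        # naive per-row oracle
        keep = [
            row["product_ion_count"] >= 15 and row["ion_score"] >= 30.0
            for _, row in table.iterrows()
        ]
        assert list(retained.index) == [i for i, k in enumerate(keep) if k]
        expected_proteins = sorted(
            {
                row["protein_accession"]
                for (_, row), k in zip(table.iterrows(), keep)
                if k and row["validated"]
            }
        )
        assert proteins == expected_proteins

    def test_idempotent(self):
        table = synthdata.gen_psm_table(n_records=200, seed=22)
        once, prot_once = filter_psms(table, FilterCriteria())
        twice, prot_twice = filter_psms(once, FilterCriteria())
        assert once.equals(twice) and prot_once == prot_twice

    @given(
        ions=st.integers(min_value=0, max_value=40),
        score=st.floats(min_value=0, max_value=100, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_raising_thresholds_never_grows_retained_set(self, ions, score):
        table = synthdata.gen_psm_table(n_records=80, seed=23)
        base, _ = filter_psms(table, FilterCriteria())
        stricter, _ = filter_psms(
            table, FilterCriteria(min_product_ions=15 + ions, min_ion_score=30.0 + score)
        )
        assert set(stricter.index) <= set(base.index)

    def test_empty_table(self):
        empty = synthdata.gen_psm_table(n_records=0, seed=0)
        retained, proteins = filter_psms(empty, FilterCriteria())
        assert retained.empty and proteins == []

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            FilterCriteria(min_ion_score=-1.0)


class TestSpectrumCount:
    def test_empty_table_empty_counts(self):
        assert spectrum_count(pd.DataFrame(columns=["protein_accession", "sample_id"])).empty

    def test_three_psms_one_group(self):
        frame = make_psm_frame(
            [dict(BASE, ion_score=40.0, product_ion_count=16, validated=True)] * 3
        )
        counts = spectrum_count(frame)
        assert len(counts) == 1
        assert counts.iloc[0].tolist() == ["P001", "treated", 3]

    def test_matches_bruteforce_group_and_count(self):
        table = synthdata.gen_psm_table(n_records=500, seed=24)
        counts = spectrum_count(table)
        # naive oracle
        expected = {}
        for _, row in table.iterrows():
            key = (row["protein_accession"], row["sample_id"])
            expected[key] = expected.get(key, 0) + 1
        got = {
            (r["protein_accession"], r["sample_id"]): r["count"]
            for _, r in counts.iterrows()
        }
        assert got == expected
        assert counts["count"].sum() == len(table)


class TestExtractApex:
    def test_all_zero_trace(self):
        trace = ChromatogramTrace(
            retention_times=np.arange(10.0), intensities=np.zeros(10), mz_window=(1, 2)
        )
        assert extract_apex(trace) == 0.0

    def test_noiseless_gaussian_recovers_amplitude(self):
        trace = synthdata.gen_trace(synthdata.TraceSpec(noise_sd=0.0, apex_amplitude=1.3e6))
        assert extract_apex(trace) == pytest.approx(1.3e6)

    def test_two_peaks_returns_larger(self):
        times = np.arange(0.0, 600.0)
        small = 5e5 * np.exp(-((times - 150.0) ** 2) / 128.0)
        big = 1.3e6 * np.exp(-((times - 450.0) ** 2) / 128.0)
        trace = ChromatogramTrace(times, small + big, (509.5, 511.5))
        assert extract_apex(trace) == pytest.approx(float((small + big).max()))
        assert extract_apex(trace) == pytest.approx(1.3e6, rel=1e-6)
        # restricting to the early window isolates the smaller peak
        assert extract_apex(trace, rt_range=(0, 300)) == pytest.approx(5e5, rel=1e-6)

    def test_equals_exhaustive_maximum(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 200))
            trace = ChromatogramTrace(
                retention_times=np.arange(n, dtype=float),
                intensities=rng.uniform(0, 1e6, n),
                mz_window=(400, 402),
            )
            assert extract_apex(trace) == max(trace.intensities)

    def test_empty_restriction_window_rejected(self):
        trace = synthdata.gen_trace(synthdata.TraceSpec(noise_sd=0.0))
        with pytest.raises(ValueError, match="no data points"):
            extract_apex(trace, rt_range=(1000.0, 2000.0))

    def test_peak_area_of_flat_trace(self):
        trace = ChromatogramTrace(
            np.arange(11.0), np.full(11, 2.0), mz_window=(1, 2)
        )
        assert peak_area(trace) == pytest.approx(20.0)


class TestRatiosAndFold:
    def test_published_apex_pair(self):
        # 1.3e6 treated vs 5.5e5 control gives 2.36 by direct division
        assert abundance_ratio(1.3e6, 5.5e5) == pytest.approx(2.3636, abs=1e-3)

    def test_identical_apexes_ratio_one(self):
        assert abundance_ratio(7.7e5, 7.7e5) == 1.0

    def test_zero_treated_apex(self):
        assert abundance_ratio(0.0, 5.5e5) == 0.0

    def test_zero_control_apex_rejected(self):
        with pytest.raises(ZeroDivisionError):
            abundance_ratio(1.3e6, 0.0)

    def test_worked_example_normalization(self):
        # target ratio 2.47 over spike-in ratio 0.79 reports as 3.13
        assert round_fold(normalized_fold_change(2.47, 0.79)) == 3.13

    def test_equal_ratios_fold_one(self):
        assert normalized_fold_change(1.7, 1.7) == pytest.approx(1.0)

    def test_hand_division(self):
        assert normalized_fold_change(5.5, 1.1) == pytest.approx(5.0)

    def test_zero_spike_ratio_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalized_fold_change(2.47, 0.0)

    def test_rounding_is_half_away_from_zero(self):
        assert round_fold(3.125) == 3.13
        assert round_fold(2.364) == 2.36

    @given(scale=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_fold_invariant_under_common_intensity_scaling(self, scale):
        base = fold_change_from_apexes(2.4e6, 1.0e6, 0.8e6, 1.0e6)
        scaled = fold_change_from_apexes(
            2.4e6 * scale, 1.0e6 * scale, 0.8e6 * scale, 1.0e6 * scale
        )
        assert scaled.normalized_fold == pytest.approx(base.normalized_fold, rel=1e-9)

    def test_full_pipeline_fold_recovery_monte_carlo(self):
        # planted folds in [1, 5], noise at 2% of each amplitude: the mean
        # relative error over 100 seeds stays below 5%
        rng = np.random.default_rng(7)
        errors = []
        for i in range(100):
            true_fold = rng.uniform(1.0, 5.0)
            amplitudes = {
                "target_control": 5e5,
                "target_treated": 5e5 * true_fold,
                "spike_control": 8e5,
                "spike_treated": 8e5,
            }
            apex = {}
            for j, (key, amp) in enumerate(amplitudes.items()):
                trace = synthdata.gen_trace(
                    synthdata.TraceSpec(
                        apex_amplitude=amp, noise_sd=0.02 * amp, seed=10_000 + 4 * i + j
                    )
                )
                apex[key] = extract_apex(trace)
            fold = normalized_fold_change(
                abundance_ratio(apex["target_treated"], apex["target_control"]),
                abundance_ratio(apex["spike_treated"], apex["spike_control"]),
            )
            errors.append(abs(fold - true_fold) / true_fold)
            assert fold == pytest.approx(true_fold, rel=0.15)
        assert np.mean(errors) < 0.05


class TestPeptideMz:
    def test_glycine_singly_charged(self):
        assert peptide_mz("G", 1) == pytest.approx(76.0393, abs=1e-3)

    @pytest.mark.parametrize(
        "peptide,charge",
        [("LLVSASQDGK", 2), ("TASTNNIAQAR", 2), ("G", 1), ("VATVSLPR", 2), ("MCHEW", 3)],
    )
    def test_monoisotopic_matches_residue_table_oracle(self, peptide, charge):
        assert peptide_mz(peptide, charge) == pytest.approx(
            oracle_mz(peptide, charge), abs=2e-3
        )

    def test_signature_peptide_in_average_mode_falls_in_instrument_window(self):
        mz = peptide_mz("LLVSASQDGK", 2, mass_mode="average")
        assert mz == pytest.approx(509.58, abs=0.02)
        trace = synthdata.gen_trace(synthdata.TraceSpec(noise_sd=0.0))
        assert trace.contains_mz(mz)
        # the monoisotopic value falls just below the same window
        assert not trace.contains_mz(peptide_mz("LLVSASQDGK", 2))

    def test_gamma12_signature_peptide(self):
        assert peptide_mz("TASTNNIAQAR", 2) == pytest.approx(573.80, abs=0.01)

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="Z"):
            peptide_mz("LLZPPG", 2)

    def test_invalid_charge_rejected(self):
        with pytest.raises(ValueError):
            peptide_mz("LLVSASQDGK", 0)


class TestPsmRecordValidation:
    def test_disallowed_modification_delta_rejected(self):
        with pytest.raises(ValueError, match="allowed set"):
            PsmRecord(**BASE, ion_score=40.0, product_ion_count=16,
                      modifications=((0, 79.97),))

    def test_allowed_modifications_accepted(self):
        rec = PsmRecord(**BASE, ion_score=40.0, product_ion_count=16,
                        modifications=((0, 16.0), (3, 57.021464)))
        assert len(rec.modifications) == 2
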
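"""Reference-index classification and conversion QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandmeth.genome import SENSE, ANTISENSE, MethylationState
from strandmeth.simulate import make_reconstituted_standard, simulate_trace
from strandmeth.traces import (CalibrationIndex, Category, PeakTable,
                               call_sample, category_to_band, classify_site,
                               conversion_efficiency, read_peak_tables,
                               write_peak_tables, read_call_vectors,
                               write_call_vectors)

CAL = CalibrationIndex(noise_floor_abs=5.0)


class TestClassifySite:
    @pytest.mark.parametrize("hc,ht,expected", [
        (0, 100, Category.T_ONLY),
        (100, 0, Category.C_ONLY),
        (50, 50, Category.C_LE_T),   # tie grouped with C <= T
        (40, 60, Category.C_LE_T),
        (60, 40, Category.C_GT_T),
        (0, 0, Category.MISSING),
        (3, 4, Category.MISSING),    # both under the absolute floor
    ])
    def test_peak_comparison_rules(self, hc, ht, expected):
        assert classify_site(hc, ht, CAL) == expected

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            classify_site(-1, 10, CAL)

    def test_relative_noise_floor(self):
        # minor C peak at 4% of the T peak is below the 5% floor
        cal = CalibrationIndex(noise_floor_frac=0.05)
        assert classify_site(4, 100, cal) == Category.T_ONLY
        assert classify_site(6, 100, cal) == Category.C_LE_T

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(hc=st.floats(0, 1000), ht=st.floats(1, 1000),
           delta=st.floats(0, 1000))
    def test_monotone_in_c_height(self, hc, ht, delta):
        """More C signal never moves the call to a lower-density band."""
        order = {Category.T_ONLY: 0, Category.C_LE_T: 1,
                 Category.C_GT_T: 2, Category.C_ONLY: 3}
        a = classify_site(hc, ht, CAL)
        b = classify_site(hc + delta, ht, CAL)
        if a != Category.MISSING and b != Category.MISSING:
            assert order[b] >= order[a]


class TestCategoryBands:
    @pytest.mark.parametrize("cat,band", [
        (Category.T_ONLY, (0.0, 0.0)),
        (Category.C_LE_T, (0.0, 0.10)),
        (Category.C_GT_T, (0.10, 0.25)),
        (Category.C_ONLY, (0.25, 1.0)),
    ])
    def test_band_mapping(self, cat, band):
        assert category_to_band(cat) == band

    def test_missing_has_no_band(self):
        with pytest.raises(ValueError):
            category_to_band(Category.MISSING)


def _peak_table(n_converted, n_failed, cpg_rows=(), sample_id="s1"):
    rows = []
    pos = 1
    for _ in range(n_converted):
        rows.append((pos, "C", 0.0, 1.0, False, np.nan)); pos += 1
    for _ in range(n_failed):
        rows.append((pos, "C", 1.0, 0.0, False, np.nan)); pos += 1
    for i, (hc, ht) in enumerate(cpg_rows, start=1):
        rows.append((pos, "C", hc, ht, True, i)); pos += 1
    df = pd.DataFrame(rows, columns=["template_pos", "ref_base", "height_C",
                                     "height_T", "is_cpg", "site_index"])
    return PeakTable(sample_id, SENSE, df)


class TestConversionEfficiency:
    def test_fully_converted(self):
        assert conversion_efficiency(_peak_table(20, 0)) == 1.0

    def test_19_of_20_fails_strict_gate(self):
        rate = conversion_efficiency(_peak_table(19, 1))
        assert rate == pytest.approx(0.95)
        v = call_sample(_peak_table(19, 1, [(0, 1)]),
                        site_map=None, analyzed_range=[1])
        assert not v.qc_pass  # the gate is strictly greater than 0.95

    def test_no_qc_positions_is_an_error(self):
        with pytest.raises(ValueError, match="conversion QC"):
            conversion_efficiency(_peak_table(0, 0, [(1.0, 0.0)]))

    def test_simulated_high_failure_rate_fails_gate(self, synth_region,
                                                    synth_site_map, rng):
        state = make_reconstituted_standard(0.0, synth_site_map)
        t = simulate_trace(state, SENSE, synth_region, synth_site_map,
                           noise_sd=0.02, rng=rng, conversion_failure_rate=0.10)
        assert conversion_efficiency(t) < 0.95


class TestCallSample:
    def test_all_t_only(self):
        v = call_sample(_peak_table(10, 0, [(0, 1)] * 5), site_map=None,
                        analyzed_range=range(1, 6))
        assert list(v.calls.values()) == [Category.T_ONLY] * 5
        assert v.qc_pass and v.conversion_rate == 1.0

    def test_absent_cpg_rows_become_missing(self):
        v = call_sample(_peak_table(10, 0, [(0, 1)]), site_map=None,
                        analyzed_range=range(1, 4))
        assert v.calls[1] == Category.T_ONLY
        assert v.calls[2] == v.calls[3] == Category.MISSING

    def test_unreadable_antisense_sites_called_missing(self, synth_region,
                                                       synth_site_map):
        state = make_reconstituted_standard(1.0, synth_site_map)
        t = simulate_trace(state, ANTISENSE, synth_region, synth_site_map)
        v = call_sample(t, synth_site_map, analyzed_range=range(1, 31))
        assert all(v.calls[i] == Category.MISSING for i in range(21, 31))
        assert all(v.calls[i] == Category.C_ONLY for i in range(1, 21))

    def test_half_methylated_sample_reads_c_only(self, synth_region,
                                                 synth_site_map):
        # 50% methylated molecules sit in the >= 25% band of the index
        state = make_reconstituted_standard(0.5, synth_site_map)
        t = simulate_trace(state, SENSE, synth_region, synth_site_map)
        v = call_sample(t, synth_site_map, analyzed_range=range(1, 21))
        assert set(v.calls.values()) == {Category.C_ONLY}


class TestCalibrationRecovery:
    """Zero-noise reconstituted standards reproduce the reference index."""

    @pytest.mark.parametrize("fraction,expected", [
        (0.0, Category.T_ONLY),
        (0.10, Category.C_GT_T),
        (0.25, Category.C_ONLY),
        (0.50, Category.C_ONLY),
        (1.0, Category.C_ONLY),
    ])
    def test_standard_categories(self, synth_region, synth_site_map,
                                 fraction, expected):
        state = make_reconstituted_standard(fraction, synth_site_map)
        t = simulate_trace(state, SENSE, synth_region, synth_site_map)
        v = call_sample(t, synth_site_map, analyzed_range=range(1, 21))
        assert set(v.calls.values()) == {expected}


class TestQcGateStochastic:
    def test_gate_excludes_incomplete_conversion(self, synth_region,
                                                 synth_site_map):
        """Samples with >= 5% true conversion failure are nearly always dropped."""
        state = make_reconstituted_standard(0.0, synth_site_map)
        excluded = 0
        reps = 40
        for k in range(reps):
            rng = np.random.default_rng(500 + k)
            t = simulate_trace(state, SENSE, synth_region, synth_site_map,
                               noise_sd=0.02, rng=rng,
                               conversion_failure_rate=0.05)
            v = call_sample(t, synth_site_map, analyzed_range=range(1, 21))
            excluded += not v.qc_pass
        assert excluded >= 0.95 * reps

    def test_gate_passes_good_conversion(self, synth_region, synth_site_map):
        state = make_reconstituted_standard(0.0, synth_site_map)
        passed = 0
        reps = 40
        for k in range(reps):
            rng = np.random.default_rng(900 + k)
            t = simulate_trace(state, SENSE, synth_region, synth_site_map,
                               noise_sd=0.02, rng=rng,
                               conversion_failure_rate=0.002)
            v = call_sample(t, synth_site_map, analyzed_range=range(1, 21))
            passed += v.qc_pass
        assert passed >= 0.9 * reps


class TestIO:
    def test_peak_table_round_trip(self, synth_region, synth_site_map, tmp_path):
        state = make_reconstituted_standard(0.3, synth_site_map)
        tables = [simulate_trace(state, s, synth_region, synth_site_map,
                                 noise_sd=0.01, rng=np.random.default_rng(1),
                                 sample_id="a") for s in (SENSE, ANTISENSE)]
        path = tmp_path / "peaks.tsv"
        write_peak_tables(tables, path)
        back = read_peak_tables(path)
        assert [(t.sample_id, t.strand) for t in back] == [("a", SENSE),
                                                           ("a", ANTISENSE)]
        assert len(back[0].rows) == len(tables[0].rows)

    def test_call_vector_round_trip(self, tmp_path):
        v = call_sample(_peak_table(10, 0, [(0, 1), (1, 0)]), site_map=None,
                        analyzed_range=range(1, 4))
        path = tmp_path / "calls.tsv"
        write_call_vectors([v], path)
        back = read_call_vectors(path)[0]
        assert back.calls == v.calls
        assert back.qc_pass == v.qc_pass
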
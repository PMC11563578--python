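"""Reporter extraction, impurity correction, aggregation, interference scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xlquant.ident import SiteKey
from xlquant.quant import (
    DEFAULT_PURITY,
    IDENTITY_PURITY,
    PurityMatrix,
    QuantRecord,
    ReporterIntensities,
    aggregate_sites,
    closed_form_correction,
    correct_impurity,
    extract_reporters,
    interference_percent,
    interference_scan,
    log2_ratio,
    quantify,
    recenter,
)
from xlquant.spectra import SpectraRun, Spectrum
from xlquant.synthetic import simulate_background_run

MZ126 = 126.127726
MZ127 = 127.131081


def _spec(mzs, ints, scan=1):
    return Spectrum("r", scan, mz=mzs, intensity=ints)


class TestExtraction:
    def test_peakless_spectrum(self):
        r = extract_reporters(_spec([], []))
        assert (r.i126, r.i127, r.status) == (0.0, 0.0, "both_missing")

    def test_single_channel(self):
        r = extract_reporters(_spec([126.1277], [5000.0]))
        assert r.i126 == 5000.0 and r.i127 == 0.0
        assert r.status == "missing127"

    def test_split_centroid_is_summed(self):
        r = extract_reporters(_spec([126.126, 126.129], [2000.0, 1000.0]))
        assert r.i126 == 3000.0

    def test_max_mode(self):
        r = extract_reporters(_spec([126.126, 126.129], [2000.0, 1000.0]), mode="max")
        assert r.i126 == 2000.0

    def test_outside_tolerance_ignored(self):
        r = extract_reporters(_spec([126.1330], [999.0]))  # 0.00527 Da off
        assert r.i126 == 0.0


class TestCorrection:
    def test_identity_matrix_is_noop(self):
        c = correct_impurity((1234.0, 567.0), IDENTITY_PURITY)
        assert (c.a126, c.a127) == (1234.0, 567.0)

    def test_closed_form_coefficients_from_default_matrix(self):
        """Eliminating one channel reproduces the documented coefficients."""
        (m11, m12), (m21, m22) = DEFAULT_PURITY.values
        assert round(m12 / m22, 5) == 0.01102
        assert round(m11 - m12 * m21 / m22, 6) == 0.906521
        assert round(m21 / m11, 5) == 0.10188
        assert round(m22 - m12 * m21 / m11, 6) == 0.906221

    def test_equal_raw_intensities(self):
        # 2x2 elimination by hand: (1000 - 1000*0.011023)/0.906521 etc.
        c = correct_impurity((1000.0, 1000.0))
        assert c.a126 == pytest.approx(1090.96, abs=0.01)
        assert c.a127 == pytest.approx(991.06, abs=0.01)

    @given(st.floats(1.0, 1e7), st.floats(1.0, 1e7))
    @settings(max_examples=60, derandomize=True)
    def test_closed_form_agrees_with_linear_solve(self, i126, i127):
        c = correct_impurity((i126, i127))
        cf126, cf127 = closed_form_correction(i126, i127)
        assert c.a126 == pytest.approx(cf126, rel=1e-4)
        assert c.a127 == pytest.approx(cf127, rel=1e-4)

    @given(st.floats(0.1, 1e6), st.floats(0.1, 1e6))
    @settings(max_examples=60, derandomize=True)
    def test_forward_mix_round_trip(self, a126, a127):
        i = DEFAULT_PURITY.matrix @ np.array([a126, a127])
        c = correct_impurity((float(i[0]), float(i[1])))
        assert c.a126 == pytest.approx(a126, rel=1e-6)
        assert c.a127 == pytest.approx(a127, rel=1e-6)

    def test_negative_after_correction_flagged_not_clamped(self):
        # large 127 bleed makes the corrected 126 negative
        c = correct_impurity((10.0, 10000.0))
        assert c.status == "nonpositive_after_correction"
        assert c.a126 < 0  # preserved, not clamped

    def test_negative_raw_rejected(self):
        with pytest.raises(ValueError):
            correct_impurity((-1.0, 5.0))

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            PurityMatrix(((0.5, 0.5), (0.5, 0.5)))


class TestLog2Ratio:
    def test_balanced(self):
        c = ReporterIntensities(1, 1, 1000.0, 1000.0)
        assert log2_ratio(c) == 0.0

    def test_orientation(self):
        c = ReporterIntensities(1, 1, 200.0, 800.0)
        assert log2_ratio(c, "127/126") == 2.0
        assert log2_ratio(c, "126/127") == -2.0

    def test_zero_channel_gives_missing_not_inf(self):
        c = ReporterIntensities(1, 1, 0.0, 800.0)
        assert log2_ratio(c) is None

    @given(st.floats(1.0, 1e6), st.floats(1.0, 1e6))
    @settings(max_examples=40, derandomize=True)
    def test_swap_symmetry(self, a, b):
        c = ReporterIntensities(1, 1, a, b)
        swapped = ReporterIntensities(1, 1, b, a)
        r1 = log2_ratio(c, "127/126")
        r2 = log2_ratio(swapped, "126/127")
        assert abs(r1) == pytest.approx(abs(r2), abs=1e-12)


def _record(key, ratio, scan=1):
    return QuantRecord("r", scan, key, "monolink" if not key.is_crosslink else "interlink",
                       ReporterIntensities(1, 1, 1.0, 1.0), ratio, "127/126")


class TestAggregation:
    def test_single_record(self):
        key = SiteKey((("MBP", 313),))
        sq = aggregate_sites([_record(key, 0.7)])
        assert len(sq) == 1
        assert sq[0].mean_ratio == 0.7 and sq[0].n_spectra == 1
        assert sq[0].sd_ratio == 0.0

    def test_mean_of_two(self):
        key = SiteKey((("MBP", 313),))
        sq = aggregate_sites([_record(key, 1.0, 1), _record(key, 3.0, 2)])
        assert sq[0].mean_ratio == 2.0 and sq[0].n_spectra == 2

    def test_canonical_key_merges_swapped_pairs(self):
        a = _record(SiteKey((("A", 10), ("B", 5))), 1.0, 1)
        b = _record(SiteKey((("B", 5), ("A", 10))), 2.0, 2)
        sq = aggregate_sites([a, b])
        assert len(sq) == 1 and sq[0].n_spectra == 2

    def test_missing_ratios_excluded(self):
        key = SiteKey((("MBP", 313),))
        sq = aggregate_sites([_record(key, 1.0, 1), _record(key, None, 2)])
        assert sq[0].n_spectra == 1

    @given(st.permutations(list(range(6))))
    @settings(max_examples=20, derandomize=True)
    def test_mean_permutation_invariant_and_bounded(self, order):
        key = SiteKey((("X", 1),))
        ratios = [-2.0, -0.5, 0.0, 0.3, 1.2, 2.5]
        recs = [_record(key, ratios[i], scan=n) for n, i in enumerate(order)]
        sq = aggregate_sites(recs)
        assert sq[0].mean_ratio == pytest.approx(np.mean(ratios), abs=1e-12)
        assert min(ratios) <= sq[0].mean_ratio <= max(ratios)


class TestRecenter:
    def _sites(self):
        keys = [SiteKey((("TBP", i), ("TBP", i + 10))) for i in (1, 2, 3)]
        keys += [SiteKey((("TOA1", 5), ("TOA1", 20)))]
        recs = [_record(k, v, scan=i) for i, (k, v) in
                enumerate(zip(keys, [-0.4, -0.5, -0.9, 0.2]))]
        return aggregate_sites(recs)

    def test_median_to_target(self):
        sites = self._sites()
        moved, shift = recenter(
            sites, lambda s: s.key.sites[0][0] == "TBP", target=-0.5
        )
        tbp = [s.mean_ratio for s in moved if s.key.sites[0][0] == "TBP"]
        assert np.median(tbp) == pytest.approx(-0.5)
        assert shift == pytest.approx(0.0)  # median already at -0.5

    def test_only_selected_group_moves(self):
        sites = self._sites()
        moved, _ = recenter(sites, lambda s: s.key.sites[0][0] == "TBP", target=0.0)
        other = [s for s in moved if s.key.sites[0][0] == "TOA1"]
        assert other[0].mean_ratio == pytest.approx(0.2)

    def test_fixed_offset(self):
        sites = self._sites()
        moved, shift = recenter(sites, lambda s: True, target=-0.5, mode="offset")
        assert shift == -0.5
        assert moved[-1].mean_ratio == pytest.approx(0.2 - 0.5)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            recenter(self._sites(), lambda s: False, target=0.0)


class TestInterference:
    def test_percent_formatting_worked_example(self):
        assert interference_percent(141, 83242) == 0.17
        assert interference_percent(18, 83242) == 0.02

    def test_no_peaks_near_targets(self):
        run = SpectraRun("r", [_spec([500.0], [1.0], scan=i) for i in range(1, 4)])
        df = interference_scan(run, [MZ126])
        assert df["count"].iloc[0] == 0 and df["percent"].iloc[0] == 0.0

    def test_planted_counts_recovered(self):
        run = simulate_background_run(400, {MZ126: 17, MZ127: 3}, seed=9)
        df = interference_scan(run, [MZ126, MZ127], tol=40, unit="ppm")
        assert df["count"].tolist() == [17, 3]
        assert df["percent"].tolist() == [round(1700 / 400, 2), 0.75]

    def test_spectrum_counts_once_per_target(self):
        s = _spec([MZ126 - 0.001, MZ126 + 0.001], [1.0, 1.0])
        df = interference_scan(SpectraRun("r", [s]), [MZ126])
        assert df["count"].iloc[0] == 1

    def test_empty_run_flagged(self):
        df = interference_scan(SpectraRun("r", []), [MZ126])
        assert df["total"].iloc[0] == 0 and math.isnan(df["percent"].iloc[0])


class TestPipeline:
    def test_quantify_matches_and_warns_on_missing_scans(self, clean_dataset):
        run, ids, truth = clean_dataset
        from dataclasses import replace

        ids_plus = list(ids) + [replace(ids[0], scan=99999)]
        with pytest.warns(UserWarning, match="no matching scan"):
            recs = quantify(run, ids_plus)
        assert len(recs) == len(ids)

    def test_exact_recovery_without_noise(self, clean_dataset):
        run, ids, truth = clean_dataset
        sites = aggregate_sites(quantify(run, ids))
        for s in sites:
            assert s.mean_ratio == pytest.approx(truth.site_ratio[s.key], abs=1e-9)
            assert s.sd_ratio == pytest.approx(0.0, abs=1e-9)
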
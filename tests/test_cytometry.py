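"""Profile thresholding, domain detection, centromere extent and overlap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from censkim.cytometry import (
    IntensityProfile,
    MeasureParams,
    UndefinedOverlapError,
    centromere_measurement,
    detect_domains,
    overlap_fraction,
    summarize_measurements,
    threshold_profile,
)
from censkim.simulate import IntensityProfileSpec, simulate_profile

FIXED0 = MeasureParams(threshold_method="fixed", fixed_threshold=0.0)


def _profile(**channels):
    n = len(next(iter(channels.values())))
    return IntensityProfile(np.arange(n, dtype=float), {k: np.asarray(v, float) for k, v in channels.items()})


class TestThreshold:
    def test_constant_zero_channel_all_absent(self):
        p = _profile(c=np.zeros(100))
        presence, _ = threshold_profile(p, "c", "isodata")
        assert not presence.any()

    def test_isodata_separates_bimodal_signal(self):
        rng = np.random.default_rng(1)
        truth = np.zeros(2000, dtype=bool)
        truth[500:900] = True
        values = np.where(truth, rng.normal(100, 1, 2000), rng.normal(10, 1, 2000))
        p = _profile(c=values)
        presence, thr = threshold_profile(p, "c", "isodata")
        assert 10 < thr < 100
        assert (presence != truth).mean() <= 0.01

    def test_fixed_zero_threshold_strict_positivity(self):
        p = _profile(c=[0.0, 0.5, 0.0, 2.0])
        presence, _ = threshold_profile(p, "c", "fixed", 0.0)
        assert presence.tolist() == [False, True, False, True]

    def test_unknown_channel_rejected(self):
        with pytest.raises(KeyError):
            threshold_profile(_profile(c=[1.0]), "missing")


class TestDomains:
    def test_four_planted_blocks_detected(self):
        p = simulate_profile(IntensityProfileSpec(1000, 0.435, 4))
        domains = detect_domains(p.channels["cen"] > 0, p.positions, min_gap=5, min_domain=3)
        assert len(domains) == 4

    def test_all_absent_empty(self):
        assert detect_domains(np.zeros(50, bool), np.arange(50.0)) == []

    def test_small_gaps_merged_and_short_domains_dropped(self):
        presence = np.zeros(100, bool)
        presence[10:20] = True
        presence[22:30] = True  # gap of 2 -> merged at min_gap 3
        presence[60:61] = True  # extent 1 -> dropped at min_domain 5
        domains = detect_domains(presence, np.arange(100.0), min_gap=3, min_domain=5)
        assert domains == [(10.0, 29.0)]

    def test_invariant_to_padding_absent_positions(self):
        presence = np.zeros(60, bool)
        presence[20:40] = True
        base = detect_domains(presence, np.arange(60.0), 2, 2)
        padded = np.concatenate([np.zeros(10, bool), presence, np.zeros(10, bool)])
        positions = np.arange(-10.0, 70.0)
        assert detect_domains(padded, positions, 2, 2) == base


class TestCentromereMeasurement:
    def test_planted_fraction_recovered(self):
        p = simulate_profile(IntensityProfileSpec(1000, 0.435, 4))
        m = centromere_measurement(p, "dna", "cen", FIXED0)
        assert m.ratio == pytest.approx(0.435, abs=0.005)
        assert m.n_domains == 4

    def test_full_coverage_ratio_one(self):
        p = _profile(dna=np.full(200, 50.0), cen=np.full(200, 50.0))
        m = centromere_measurement(p, "dna", "cen", FIXED0)
        assert m.ratio == 1.0 and m.n_domains == 1

    def test_ratio_invariant_under_position_rescaling(self):
        spec = IntensityProfileSpec(800, 0.4, 3)
        p = simulate_profile(spec)
        scaled = IntensityProfile(p.positions * 7.3, dict(p.channels))
        m1 = centromere_measurement(p, "dna", "cen", FIXED0)
        m2 = centromere_measurement(scaled, "dna", "cen", FIXED0)
        assert m1.ratio == pytest.approx(m2.ratio, rel=1e-9)

    def test_no_domain_recorded_as_failed_not_fatal(self):
        p = _profile(dna=np.full(100, 50.0), cen=np.zeros(100))
        m = centromere_measurement(p, "dna", "cen", FIXED0)
        assert m.failed and np.isnan(m.ratio)

    def test_batch_mean_recovery(self):
        rng = np.random.default_rng(42)
        planted, measured = [], []
        for i in range(240):
            f = float(np.clip(rng.normal(0.435, 0.05), 0.2, 0.7))
            p = simulate_profile(
                IntensityProfileSpec(1000, f, int(rng.integers(1, 6)), noise_sd=5.0, seed=i)
            )
            m = centromere_measurement(p, "dna", "cen", MeasureParams())
            planted.append(round(f * 1000) / 1000)
            measured.append(m.ratio)
        assert np.mean(measured) == pytest.approx(np.mean(planted), abs=0.01)


class TestOverlap:
    def test_identical_channels_full_overlap(self):
        v = np.concatenate([np.zeros(20), np.full(60, 80.0), np.zeros(20)])
        r = overlap_fraction(_profile(a=v, b=v.copy()), "a", "b", FIXED0)
        assert r.overlap_fraction == 1.0

    def test_planted_overlap_exact_at_zero_noise(self):
        p = simulate_profile(
            IntensityProfileSpec(1000, 0.4, 1, channel_overlap=0.75, mode="fiber")
        )
        r = overlap_fraction(p, "a", "b", FIXED0)
        assert r.overlap_fraction == 0.75
        assert r.overlap_fraction <= min(r.fraction_a, r.fraction_b)

    def test_disjoint_channels_zero(self):
        a = np.concatenate([np.full(50, 9.0), np.zeros(50)])
        b = np.concatenate([np.zeros(50), np.full(50, 9.0)])
        r = overlap_fraction(_profile(a=a, b=b), "a", "b", FIXED0)
        assert r.overlap_fraction == 0.0

    def test_symmetric_in_channels(self):
        p = simulate_profile(
            IntensityProfileSpec(600, 0.4, 1, channel_overlap=0.62, mode="fiber", seed=3)
        )
        r1 = overlap_fraction(p, "a", "b", FIXED0)
        r2 = overlap_fraction(p, "b", "a", FIXED0)
        assert r1.overlap_fraction == r2.overlap_fraction

    def test_no_signal_undefined(self):
        with pytest.raises(UndefinedOverlapError):
            overlap_fraction(_profile(a=np.zeros(10), b=np.zeros(10)), "a", "b", FIXED0)


class TestSummaries:
    def _m(self, ratio, label=None):
        from censkim.cytometry import ChromosomeMeasurement

        return ChromosomeMeasurement(100.0, ratio * 100, ratio, 4, label)

    def test_hand_arithmetic(self):
        mean, sd, _ = summarize_measurements([self._m(0.4), self._m(0.5)])
        assert mean == pytest.approx(0.45)
        assert sd == pytest.approx(0.0707, abs=1e-4)

    def test_single_measurement_sd_zero_with_warning(self):
        with pytest.warns(UserWarning):
            mean, sd, _ = summarize_measurements([self._m(0.4)])
        assert (mean, sd) == (0.4, 0.0)

    def test_mean_matches_direct_summation(self):
        rng = np.random.default_rng(8)
        ratios = rng.uniform(0.2, 0.7, 240)
        mean, _, _ = summarize_measurements([self._m(r) for r in ratios])
        assert mean == pytest.approx(ratios.sum() / len(ratios), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_measurements([])


@settings(derandomize=True, max_examples=30)
@given(
    n=st.integers(50, 400),
    frac=st.floats(0.1, 0.9),
    k=st.integers(1, 5),
    seed=st.integers(0, 1000),
)
def test_profile_measurement_roundtrip_property(n, frac, k, seed):
    """At zero noise the planted centromere fraction is recovered to within
    one pixel for any admissible profile geometry."""
    if n < 10 * k:
        return
    p = simulate_profile(IntensityProfileSpec(n, frac, k, seed=seed))
    m = centromere_measurement(p, "dna", "cen", FIXED0)
    planted_span = max(round(frac * n), 2 * k - 1)
    assert m.centromere_length == pytest.approx(planted_span, abs=1.0)
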
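import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoconj import (
    BindingModelSpec,
    ProteinSpec,
    ScatchardResult,
    SyntheticExperiment,
    build_isotherm,
    capacity_vs_inverse_mw,
    cooperativity_diagnostic,
    fit_calibration,
    generate_experiment,
    scatchard_transform,
    select_analysis_window,
    two_regime_fit,
)
from nanoconj.binding import BindingPoint
from nanoconj.exceptions import (
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
)


def point(l0, rl, l_free_nM, censored=False):
    return BindingPoint(
        added_ug_ml=l0, added_nM=l0, f0=1.0, f=1.0,
        unbound_ug_ml=0.0, unbound_nM=l_free_nM,
        bound_ug_ml=0.0, bound_nM=0.0, rl=rl, censored=censored,
    )


def langmuir_cloud(kd=10.0, n=100.0, l_free=None):
    """Noise-free Scatchard coordinates straight from the site model."""
    l_free = np.array([2.0, 5.0, 10.0, 20.0, 50.0, 100.0] if l_free is None else l_free)
    rl = n * l_free / (kd + l_free)
    return rl, rl / l_free


class TestTransformAndWindow:
    def test_langmuir_identity_at_half_saturation(self):
        pts = [point(50.0, 50.0, 10.0)]
        x, y = scatchard_transform(pts)
        assert x[0] == 50.0
        assert y[0] == pytest.approx((100.0 - 50.0) / 10.0)  # (N-RL)/Kd

    def test_zero_occupancy_maps_to_origin(self):
        x, y = scatchard_transform([point(1.0, 0.0, 5.0)])
        assert (x[0], y[0]) == (0.0, 0.0)

    def test_censored_points_excluded(self):
        pts = [point(8.0, 40.0, 0.0, censored=True), point(16.0, 70.0, 20.0)]
        x, _ = scatchard_transform(pts)
        assert len(x) == 1

    def test_all_censored_rejected(self):
        with pytest.raises(InsufficientDataError):
            scatchard_transform([point(8.0, 40.0, 0.0, censored=True)])

    def test_default_window_on_dilution_grid(self):
        grid = [8.0, 16.0, 31.0, 62.5, 125.0, 250.0]
        pts = [point(c, 1.0, 1.0) for c in grid]
        kept = select_analysis_window(pts)
        assert [p.added_ug_ml for p in kept] == [16.0, 31.0, 62.5]

    def test_unbounded_window_is_identity(self):
        pts = [point(c, 1.0, 1.0) for c in (8.0, 1000.0)]
        assert len(select_analysis_window(pts, 0.0, np.inf)) == 2

    def test_inverted_bounds_rejected(self):
        with pytest.raises(DomainError):
            select_analysis_window([point(8.0, 1.0, 1.0)], 200.0, 100.0)


class TestTwoRegimeFit:
    @given(
        kd=st.floats(min_value=0.5, max_value=200.0),
        n=st.floats(min_value=10.0, max_value=1000.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_single_class_oracle_any_parameters(self, kd, n):
        # a one-class site model IS a single Scatchard line: both regimes
        # must return the true Kd and the x-intercept the true N
        x, y = langmuir_cloud(kd, n)
        res = two_regime_fit(x, y)
        assert res.kd1_nM == pytest.approx(kd, rel=1e-6)
        assert res.kd2_nM == pytest.approx(kd, rel=1e-6)
        assert res.n_sites == pytest.approx(n, rel=1e-6)

    def test_overlapping_halves_on_three_points(self):
        x, y = langmuir_cloud(10.0, 100.0, l_free=[5.0, 10.0, 20.0])
        res = two_regime_fit(x, y)
        assert res.regime_split == (2, 2)
        assert res.kd1_nM == pytest.approx(10.0, rel=1e-9)

    def test_positive_slope_is_degenerate(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(DegenerateFitError):
            two_regime_fit(x, y)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            two_regime_fit(np.array([1.0, 2.0]), np.array([2.0, 1.0]))

    def test_anti_cooperative_regimes_ordered(self, igg_two_class, igg, gold_batch):
        from dataclasses import replace

        calib, sup, _ = generate_experiment(replace(igg_two_class, noise_cv=0.0))
        iso = build_isotherm(fit_calibration(calib), sup, igg, gold_batch)
        x, y = scatchard_transform(select_analysis_window(iso))
        res = two_regime_fit(x, y)
        assert res.kd1_nM < res.kd2_nM


class TestCooperativityDiagnostic:
    def test_pure_langmuir_is_linear(self):
        x, y = langmuir_cloud()
        assert cooperativity_diagnostic(x, y) == "linear"

    def test_two_class_mixture_is_convex(self):
        # mixed affinities: y = sum of two hyperbolae, convex in RL
        l_free = np.array([1.0, 3.0, 10.0, 30.0, 100.0, 300.0])
        rl = 50 * l_free / (4 + l_free) + 50 * l_free / (100 + l_free)
        assert cooperativity_diagnostic(rl, rl / l_free) == "anti-cooperative"

    def test_positive_hill_is_concave(self, gold_batch, bsa):
        exp = SyntheticExperiment(
            BindingModelSpec.hill(60.0, 90.0, 2.5), gold_batch, bsa,
            noise_cv=0.0, seed=1,
        )
        calib, sup, _ = generate_experiment(exp)
        iso = build_isotherm(fit_calibration(calib), sup, bsa, gold_batch)
        x, y = scatchard_transform(iso)
        assert cooperativity_diagnostic(x, y) == "cooperative"

    def test_needs_four_points(self):
        with pytest.raises(InsufficientDataError):
            cooperativity_diagnostic(np.arange(3.0), np.arange(3.0))


class TestCapacityVsInverseMw:
    measured = [
        (ProteinSpec("IgG", 150.0), 52.0),
        (ProteinSpec("BSA", 66.0), 90.0),
        (ProteinSpec("protein G", 26.0), 500.0),
        (ProteinSpec("STI", 20.0), 550.0),
    ]

    def _results(self):
        return [
            (p, ScatchardResult(1.0, 1.0, n, (2, 2), 1.0, 1.0, "linear"))
            for p, n in self.measured
        ]

    def test_site_count_tracks_inverse_mw(self):
        slope, _, r = capacity_vs_inverse_mw(self._results())
        assert r == pytest.approx(0.9805, abs=0.001)
        assert slope == pytest.approx(1.284e4, rel=0.001)

    def test_perfect_line_gives_unit_correlation(self):
        results = [
            (ProteinSpec(f"p{i}", mw), ScatchardResult(1, 1, 1000.0 / mw, (2, 2), 1, 1, "linear"))
            for i, mw in enumerate((20.0, 50.0, 100.0))
        ]
        _, intercept, r = capacity_vs_inverse_mw(results)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_needs_three_proteins(self):
        with pytest.raises(InsufficientDataError):
            capacity_vs_inverse_mw(self._results()[:2])
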
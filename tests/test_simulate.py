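from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoconj import (
    BindingModelSpec,
    ParticleBatch,
    ProteinSpec,
    SyntheticExperiment,
    analyze_experiment,
    equilibrium_bound,
    generate_experiment,
    recovery_study,
    recovery_summary,
)
from nanoconj.exceptions import DomainError
from nanoconj.simulate import DEFAULT_DESIGN_UG_ML, generate_matrix_series


class TestEquilibriumBound:
    def test_langmuir_quadratic_root(self):
        model = BindingModelSpec.langmuir(10.0, 100.0)
        b = equilibrium_bound(model, 100.0, 3.0)  # S = 300 nM
        assert b == pytest.approx(95.3414, abs=1e-3)
        # substitution check of the defining quadratic
        assert b**2 - b * (100 + 300 + 10) + 100 * 300 == pytest.approx(0, abs=1e-6)

    def test_no_ligand_no_binding(self):
        assert equilibrium_bound(BindingModelSpec.langmuir(10, 100), 0.0, 3.0) == 0.0

    def test_weak_binding_limit(self):
        b = equilibrium_bound(BindingModelSpec.langmuir(1e9, 100), 100.0, 3.0)
        assert b == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize(
        "model",
        [
            BindingModelSpec.langmuir(6.0, 90.0),
            BindingModelSpec.two_class(4.0, 26.0, 30.0, 26.0),
            BindingModelSpec.hill(10.0, 100.0, 0.7),
            BindingModelSpec.hill(60.0, 90.0, 2.5),
        ],
        ids=["langmuir", "two_class", "hill_negative", "hill_positive"],
    )
    @pytest.mark.parametrize("l_total", [0.5, 10.0, 250.0, 5000.0])
    def test_bounds_and_self_consistency(self, model, l_total):
        r0 = 2.99
        b = equilibrium_bound(model, l_total, r0)
        s = model.total_sites * r0
        assert 0.0 <= b <= min(l_total, s) + 1e-12
        # the solved free ligand satisfies the mass balance to <=1e-9 rel.
        l_free = l_total - b
        b_check = equilibrium_bound(model, l_free + b, r0)
        assert b_check == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_two_class_sums_class_occupancies(self):
        # at equal affinities a two-class model is one Langmuir class
        two = BindingModelSpec.two_class(10.0, 50.0, 10.0, 50.0)
        one = BindingModelSpec.langmuir(10.0, 100.0)
        for l_total in (5.0, 50.0, 500.0):
            assert equilibrium_bound(two, l_total, 3.0) == pytest.approx(
                equilibrium_bound(one, l_total, 3.0), rel=1e-9
            )

    def test_invalid_inputs_rejected(self):
        model = BindingModelSpec.langmuir(10.0, 100.0)
        with pytest.raises(DomainError):
            equilibrium_bound(model, -1.0, 3.0)
        with pytest.raises(DomainError):
            equilibrium_bound(model, 10.0, 0.0)


class TestGenerateExperiment:
    def test_seeded_determinism(self, bsa_experiment):
        a = generate_experiment(bsa_experiment)
        b = generate_experiment(bsa_experiment)
        assert np.array_equal(a[0].intensities, b[0].intensities)
        assert np.array_equal(a[1].intensities, b[1].intensities)
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_different_seeds_differ(self, bsa_experiment):
        a = generate_experiment(bsa_experiment)
        b = generate_experiment(replace(bsa_experiment, seed=2))
        assert not np.array_equal(a[0].intensities, b[0].intensities)

    def test_supernatant_below_calibration_everywhere(self, bsa_experiment):
        calib, sup, _ = generate_experiment(bsa_experiment)
        c0, f0 = calib.replicate_means()
        _, f = sup.replicate_means()
        assert np.all(f < f0)

    def test_design_follows_dilution_series(self, noise_free_bsa):
        calib, _, truth = generate_experiment(noise_free_bsa)
        assert tuple(truth["L0_ug_ml"]) == DEFAULT_DESIGN_UG_ML
        # two-fold series from 1000 down to 8 (31 rounded in the design)
        assert truth["L0_ug_ml"].iloc[-1] == 1000.0

    def test_true_occupancy_saturates_near_n(self, noise_free_bsa):
        _, _, truth = generate_experiment(noise_free_bsa)
        assert truth["rl_true"].max() <= 90.0
        assert truth["rl_true"].max() == pytest.approx(90.0, rel=0.01)

    def test_noise_free_pipeline_recovers_truth(
        self, noise_free_bsa, bsa, gold_batch
    ):
        calib, sup, _ = generate_experiment(noise_free_bsa)
        res = analyze_experiment(calib, sup, bsa, gold_batch)
        assert res.kd1_nM == pytest.approx(6.0, rel=1e-4)
        assert res.kd2_nM == pytest.approx(6.0, rel=1e-4)
        assert res.n_sites == pytest.approx(90.0, rel=1e-4)

    def test_matrix_series_reproduce_effect_sizes(self, noise_free_bsa):
        from nanoconj import compare_matrix_slopes

        table = compare_matrix_slopes(generate_matrix_series(noise_free_bsa))
        dev = table.set_index("matrix")["relative_deviation_pct"]
        assert dev["water"] == pytest.approx(-7.07, abs=0.05)
        assert dev["citrate"] == pytest.approx(3.03, abs=0.05)

    def test_unsorted_design_rejected(self, gold_batch, bsa):
        with pytest.raises(DomainError):
            SyntheticExperiment(
                BindingModelSpec.langmuir(6, 90), gold_batch, bsa,
                design_ug_ml=(16.0, 8.0),
            )


class TestRecoveryStudy:
    def test_noise_free_zero_bias(self, noise_free_bsa):
        table = recovery_study(noise_free_bsa, 3)
        summary = recovery_summary(table).set_index("parameter")
        assert summary.loc["n_sites", "bias"] == pytest.approx(0.0, abs=1e-3)
        assert summary.loc["kd1_nM", "bias"] == pytest.approx(0.0, abs=1e-3)

    def test_dispersion_grows_with_noise(self, bsa_experiment):
        quiet = recovery_study(bsa_experiment, 15)
        loud = recovery_study(replace(bsa_experiment, noise_cv=0.05), 15)
        assert loud["est_n_sites"].std() > quiet["est_n_sites"].std()

    def test_failed_replicates_recorded_not_raised(self, bsa_experiment):
        table = recovery_study(replace(bsa_experiment, noise_cv=0.2), 10)
        assert len(table) == 10
        failed = table["error"] != ""
        assert table.loc[failed, "est_n_sites"].isna().all()
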
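"""Estimation: zero-noise identifiability, noisy recovery, nested-model
comparison and replicate aggregation."""

import math

import numpy as np
import pytest

from atcmfit import (
    ATCMParams,
    FitError,
    SimulationSpec,
    Titration,
    aggregate_replicates,
    cheng_prusoff_ki,
    compare_models,
    fit_atcm,
    fit_competitive,
    fit_experiments,
    fit_extended_atcm,
    fit_hill,
    fit_saturation,
    simulate,
)

PKA = 10.45


def one_experiment(spec):
    return next(simulate(spec).experiments())[1]


class TestSaturationFit:
    def test_zero_noise_exact_recovery(self, sat_wt):
        ds = one_experiment(
            SimulationSpec(design="saturation", params=sat_wt, seed=1, noise_cv=0.0)
        )
        fit = fit_saturation(ds)
        assert fit.converged
        assert fit.estimates["pKd"] == pytest.approx(sat_wt.pKd, rel=1e-6)
        assert fit.estimates["Bmax"] == pytest.approx(sat_wt.Bmax, rel=1e-6)
        assert fit.estimates["ns_slope"] == pytest.approx(sat_wt.ns_slope, rel=1e-4)

    def test_noisy_recovery_across_replicates(self, sat_wt):
        spec = SimulationSpec(design="saturation", params=sat_wt, seed=42, noise_cv=0.05)
        fits = fit_experiments(simulate(spec), fit_saturation)
        agg = aggregate_replicates(fits, "pKd")
        assert agg.n == 3
        assert abs(agg.mean - 10.45) < 0.1

    def test_missing_nonspecific_arm_rejected(self, sat_wt):
        ds = one_experiment(
            SimulationSpec(design="saturation", params=sat_wt, seed=1)
        )
        from atcmfit import BindingDataset

        stripped = BindingDataset(ds.df[ds.df["is_nonspecific"] == 0])
        with pytest.raises(FitError, match="nonspecific"):
            fit_saturation(stripped)


class TestHillFit:
    def test_zero_noise_competitive_curve_recovered_exactly(self, mips1071_wt):
        ds = one_experiment(
            SimulationSpec(design="competition", params=mips1071_wt, seed=1, noise_cv=0.0)
        )
        fit = fit_hill(ds)
        # classical competition is exactly a unit-slope logistic with
        # IC50 = KB * (1 + A/KA)
        a = 0.15e-9 / mips1071_wt.KA
        expected = math.log10(mips1071_wt.KB * (1 + a))
        assert fit.estimates["logIC50"] == pytest.approx(expected, abs=1e-6)
        assert fit.estimates["nH"] == pytest.approx(1.0, abs=1e-6)
        assert fit.estimates["top"] == pytest.approx(100.0, abs=1e-6)
        assert fit.estimates["bottom"] == pytest.approx(0.0, abs=1e-4)

    def test_noisy_pki_recovery_via_cheng_prusoff(self, mips1071_wt):
        spec = SimulationSpec(
            design="competition", params=mips1071_wt, seed=8, noise_cv=0.05
        )
        # complete displacement is assumed (bottom fixed at 0), as is
        # standard when the titration does not reach the curve floor
        pkis = []
        for fit in fit_experiments(
            simulate(spec), fit_hill, constraints={"bottom": 0.0}
        ):
            ki = cheng_prusoff_ki(10 ** fit.estimates["logIC50"], 0.15e-9, PKA)
            pkis.append(-math.log10(ki))
        assert abs(np.mean(pkis) - 5.90) < 0.1

    def test_fixed_bottom_raises_ic50_on_partial_displacement(self, mips1726_wt):
        ds = one_experiment(
            SimulationSpec(
                design="interaction_modulator", params=mips1726_wt, seed=3,
                noise_cv=0.0, radioligand_conc=0.5e-9,
            )
        )
        free = fit_hill(ds)
        forced = fit_hill(ds, constraints={"bottom": 0.0})
        assert forced.estimates["logIC50"] > free.estimates["logIC50"]

    def test_flat_responses_rejected(self, mips1071_wt):
        ds = one_experiment(
            SimulationSpec(design="competition", params=mips1071_wt, seed=1, noise_cv=0.0)
        )
        flat = ds.df.copy()
        flat["response"] = 100.0
        from atcmfit import BindingDataset

        with pytest.raises(FitError, match="identical"):
            fit_hill(BindingDataset(flat))


class TestAtcmFit:
    def test_zero_noise_exact_recovery(self, mips1726_wt):
        ds = one_experiment(
            SimulationSpec(
                design="interaction_modulator", params=mips1726_wt, seed=1,
                noise_cv=0.0, radioligand_conc=0.5e-9,
            )
        )
        fit = fit_atcm(ds, fixed={"pKA": PKA})
        assert fit.estimates["pKB"] == pytest.approx(7.52, abs=1e-4)
        assert fit.estimates["log_alpha_rad"] == pytest.approx(-1.90, abs=1e-4)
        assert fit.flags["plateau_identifiable"] is True

    def test_requires_fixed_radioligand_affinity(self, mips1726_wt):
        ds = one_experiment(
            SimulationSpec(design="interaction_modulator", params=mips1726_wt, seed=1)
        )
        with pytest.raises(FitError, match="pKA"):
            fit_atcm(ds, fixed={})

    def test_noisy_recovery_across_replicates(self, mips1726_wt):
        spec = SimulationSpec(
            design="interaction_modulator", params=mips1726_wt, seed=77,
            noise_cv=0.05, radioligand_conc=0.5e-9,
        )
        fits = fit_experiments(simulate(spec), fit_atcm, fixed={"pKA": PKA})
        assert abs(aggregate_replicates(fits, "pKB").mean - 7.52) < 0.15
        assert abs(aggregate_replicates(fits, "log_alpha_rad").mean + 1.90) < 0.15

    def test_neutral_modulator_cooperativity_consistent_with_zero(self):
        # flat (neutral) curves leave pKB on a ridge, so single-fit Hessian
        # errors are meaningless; the replicate aggregate must centre on 0
        neutral = ATCMParams(pKA=PKA, pKB=7.0, Bmax=237.0, log_alpha_rad=0.0)
        spec = SimulationSpec(
            design="interaction_modulator", params=neutral, seed=5,
            noise_cv=0.05, n_experiments=6,
        )
        fits = fit_experiments(simulate(spec), fit_atcm, fixed={"pKA": PKA})
        agg = aggregate_replicates(fits, "log_alpha_rad")
        assert abs(agg.mean) < 0.2

    def test_poorly_sampled_plateau_is_flagged(self):
        weak = ATCMParams(pKA=PKA, pKB=5.0, Bmax=237.0, log_alpha_rad=-1.5)
        ds = one_experiment(
            SimulationSpec(
                design="interaction_modulator", params=weak, seed=5, noise_cv=0.0
            )
        )
        fit = fit_atcm(ds, fixed={"pKA": PKA})
        assert fit.flags["plateau_identifiable"] is False

    def test_multistart_is_deterministic(self, mips1726_wt):
        ds = one_experiment(
            SimulationSpec(
                design="interaction_modulator", params=mips1726_wt, seed=9,
                noise_cv=0.05, radioligand_conc=0.5e-9,
            )
        )
        f1 = fit_atcm(ds, fixed={"pKA": PKA})
        f2 = fit_atcm(ds, fixed={"pKA": PKA})
        assert f1.estimates == f2.estimates
        assert f1.ssr == f2.ssr

    def test_concentration_rescaling_shifts_estimates_exactly(self):
        base = ATCMParams(pKA=PKA, pKB=7.5, Bmax=237.0, log_alpha_rad=-1.5)
        shifted = ATCMParams(pKA=PKA, pKB=6.5, Bmax=237.0, log_alpha_rad=-1.5)
        kw = dict(design="interaction_modulator", seed=1, noise_cv=0.0)
        ds_base = one_experiment(
            SimulationSpec(params=base, titration=Titration(top=3e-6), **kw)
        )
        ds_shift = one_experiment(
            SimulationSpec(params=shifted, titration=Titration(top=3e-5), **kw)
        )
        f_base = fit_atcm(ds_base, fixed={"pKA": PKA})
        f_shift = fit_atcm(ds_shift, fixed={"pKA": PKA})
        assert f_shift.estimates["pKB"] == pytest.approx(
            f_base.estimates["pKB"] - 1.0, abs=1e-6
        )
        assert f_shift.estimates["log_alpha_rad"] == pytest.approx(
            f_base.estimates["log_alpha_rad"], abs=1e-6
        )

    @pytest.mark.parametrize("cv,tol", [(0.02, 0.06), (0.05, 0.12), (0.10, 0.25)])
    def test_bias_scales_with_noise(self, mips1868_wt, cv, tol):
        spec = SimulationSpec(
            design="interaction_modulator", params=mips1868_wt, seed=55,
            noise_cv=cv, n_experiments=4,
        )
        fits = fit_experiments(simulate(spec), fit_atcm, fixed={"pKA": PKA})
        assert abs(aggregate_replicates(fits, "pKB").mean - 7.00) < tol
        assert abs(aggregate_replicates(fits, "log_alpha_rad").mean + 1.45) < tol


class TestExtendedAtcmFit:
    def test_zero_noise_exact_recovery(self, sb269652_wt):
        ds = one_experiment(
            SimulationSpec(
                design="interaction_dopamine_matrix", params=sb269652_wt,
                seed=1, noise_cv=0.0,
            )
        )
        fit = fit_extended_atcm(ds, fixed={"pKA": PKA})
        assert fit.estimates["pKB"] == pytest.approx(6.45, abs=1e-4)
        assert fit.estimates["pKI"] == pytest.approx(5.59, abs=1e-4)
        assert fit.estimates["log_alpha_rad"] == pytest.approx(-0.45, abs=1e-4)
        assert fit.estimates["log_alpha_comp"] == pytest.approx(-0.54, abs=1e-4)
        assert fit.estimates["Bmax"] == pytest.approx(237.0, rel=1e-4)

    def test_single_modulator_level_rejected(self, sb269652_wt):
        ds = one_experiment(
            SimulationSpec(
                design="interaction_dopamine_matrix", params=sb269652_wt,
                seed=1, noise_cv=0.0,
            )
        )
        from atcmfit import BindingDataset

        vehicle_only = BindingDataset(ds.df[ds.df["conc_modulator_M"] == 0])
        with pytest.raises(FitError, match="unidentifiable"):
            fit_extended_atcm(vehicle_only, fixed={"pKA": PKA})

    def test_noisy_competitor_cooperativity_recovery(self, sb269652_wt):
        spec = SimulationSpec(
            design="interaction_dopamine_matrix", params=sb269652_wt,
            seed=88, noise_cv=0.05,
        )
        fits = fit_experiments(simulate(spec), fit_extended_atcm, fixed={"pKA": PKA})
        assert abs(aggregate_replicates(fits, "log_alpha_comp").mean + 0.54) < 0.15


class TestModelComparison:
    def test_identical_fits_give_null_result(self, mips1726_wt):
        ds = one_experiment(
            SimulationSpec(
                design="interaction_modulator", params=mips1726_wt, seed=2,
                noise_cv=0.05, radioligand_conc=0.5e-9,
            )
        )
        full = fit_atcm(ds, fixed={"pKA": PKA})
        shrunk = fit_atcm(ds, fixed={"pKA": PKA, "log_alpha_rad": full.estimates["log_alpha_rad"]})
        cmp_res = compare_models(shrunk, full)
        assert cmp_res.f_stat == pytest.approx(0.0, abs=1e-6)
        assert cmp_res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_strong_cooperativity_prefers_full_model(self, mips1726_wt):
        ds = one_experiment(
            SimulationSpec(
                design="interaction_modulator", params=mips1726_wt, seed=2,
                noise_cv=0.05, radioligand_conc=0.5e-9,
            )
        )
        full = fit_atcm(ds, fixed={"pKA": PKA})
        restricted = fit_competitive(ds, fixed={"pKA": PKA})
        assert compare_models(restricted, full).prefer_full

    def test_mismatched_data_rejected(self, mips1726_wt):
        kw = dict(
            design="interaction_modulator", params=mips1726_wt,
            radioligand_conc=0.5e-9, noise_cv=0.05,
        )
        full = fit_atcm(
            one_experiment(SimulationSpec(seed=1, titration=Titration(top=3e-5, n_points=12), **kw)),
            fixed={"pKA": PKA},
        )
        restricted = fit_competitive(
            one_experiment(SimulationSpec(seed=1, titration=Titration(top=3e-5, n_points=8), **kw)),
            fixed={"pKA": PKA},
        )
        with pytest.raises(FitError, match="same data"):
            compare_models(restricted, full)

    def test_non_nested_models_rejected(self, mips1726_wt):
        ds = one_experiment(
            SimulationSpec(
                design="interaction_modulator", params=mips1726_wt, seed=2,
                noise_cv=0.05, radioligand_conc=0.5e-9,
            )
        )
        full = fit_atcm(ds, fixed={"pKA": PKA})
        hill = fit_hill(ds, constraints={"nH": 1.0})
        with pytest.raises(FitError):
            compare_models(full, hill)


class TestAggregation:
    def test_mean_and_sem_arithmetic(self, mips1726_wt):
        fits = []
        for value in (7.4, 7.5, 7.6):
            fits.append(
                _make_fit({"pKB": value})
            )
        agg = aggregate_replicates(fits, "pKB")
        assert agg.mean == pytest.approx(7.5)
        assert agg.sem == pytest.approx(0.1 / math.sqrt(3), abs=1e-10)

    def test_identical_estimates_have_zero_sem(self):
        fits = [_make_fit({"pKB": 7.0}) for _ in range(3)]
        assert aggregate_replicates(fits, "pKB").sem == 0.0

    def test_single_fit_rejected(self):
        with pytest.raises(FitError, match=">= 2"):
            aggregate_replicates([_make_fit({"pKB": 7.0})], "pKB")

    def test_unconverged_fits_excluded(self):
        fits = [_make_fit({"pKB": 7.0}), _make_fit({"pKB": 7.2}),
                _make_fit({"pKB": 99.0}, converged=False)]
        agg = aggregate_replicates(fits, "pKB")
        assert agg.n == 2
        assert agg.mean == pytest.approx(7.1)


def _make_fit(estimates, converged=True):
    from atcmfit import FitResult

    return FitResult(
        model="atcm", estimates=estimates,
        standard_errors={k: 0.05 for k in estimates}, ssr=1.0, n_obs=13,
        converged=converged, n_starts_used=9,
    )
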
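"""Global shared-parameter fitting: strategy construction, recovery,
identifiability failure and model comparison."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from sabrefit import (ConfigurationError, ECDataset, OperationalParams,
                      SabreParams, StudyDesign, ValidationError,
                      build_strategy, compare_models, fit_global,
                      fit_operational_pair, generate_study,
                      operational_fraction, sabre_fraction)
from sabrefit.fitting import (FitSpec, ParameterSpec, build_single_curve_spec)

CONC = np.logspace(-9, -4, 10)


def sabre_dataset(agonist, pre, **kw):
    p = SabreParams(**kw)
    return ECDataset(agonist, pre, CONC,
                     100 * np.atleast_1d(sabre_fraction(CONC, p)))


class TestBuildStrategy:
    def test_free_parameter_counts_per_strategy(self, shared_study_noisefree):
        study = shared_study_noisefree
        logkd = {"NECA": -5.88, "CPA": -5.93, "CHA": -5.50}
        # final stages: strategy 1 frees gamma + q + 6 logKd = 8
        assert len(build_strategy(study, 1).free_keys) == 8
        naive = [d for d in study if d.pretreatment == "N"]
        # strategy 2: gamma + 3 logKd = 4
        assert len(build_strategy(naive, 2).free_keys) == 4
        # strategy 3 per pair: gamma, shared logKd, q = 3
        specs3 = build_strategy(study, 3)
        assert len(specs3) == 3
        assert all(len(s.free_keys) == 3 for s in specs3)
        # strategy 4: gamma + q = 2
        assert len(build_strategy(study, 4, logkd_values=logkd).free_keys) == 2

    def test_initial_stage_frees_epsilon_and_n(self, shared_study_noisefree):
        spec = build_strategy(shared_study_noisefree, 1, stage="initial")
        assert "epsilon" in spec.free_keys and "n" in spec.free_keys

    def test_strategy2_rejects_inactivated_datasets(self, shared_study_noisefree):
        with pytest.raises(ConfigurationError):
            build_strategy(shared_study_noisefree, 2)

    def test_strategy4_requires_logkd_values(self, shared_study_noisefree):
        with pytest.raises(ConfigurationError):
            build_strategy(shared_study_noisefree, 4)

    def test_free_q_on_naive_dataset_rejected(self):
        ds = sabre_dataset("NECA", "N", gamma=50, logKd=-6)
        specs = {
            "epsilon": ParameterSpec("epsilon", "epsilon", fixed=1.0),
            "n": ParameterSpec("n", "n", fixed=1.0),
            "gamma": ParameterSpec("gamma", "gamma", bounds=(1e-3, 1e6),
                                   initials=(1.0,), log10=True),
            "logKd": ParameterSpec("logKd", "logKd", bounds=(-9, -3),
                                   initials=(-6.0,)),
            "q": ParameterSpec("q", "q", bounds=(1e-6, 1.0), initials=(0.5,)),
        }
        pmap = [{k: k for k in ("epsilon", "gamma", "n", "logKd", "q")}]
        with pytest.raises(ValidationError):
            FitSpec([ds], ["sabre"], pmap, specs)

    def test_empty_dataset_list_rejected(self):
        with pytest.raises(ValidationError):
            FitSpec([], [], [], {})


class TestFitGlobal:
    def test_single_curve_equals_independent_fit(self):
        """With no sharing, the global engine matches scipy.curve_fit."""
        rng = np.random.default_rng(7)
        y = np.atleast_1d(sabre_fraction(
            CONC, SabreParams(gamma=80, logKd=-5.9))) + rng.normal(0, 0.02, CONC.size)
        ds = ECDataset("NECA", "N", CONC, 100 * np.maximum(y, 0))
        fit = fit_global(build_single_curve_spec(ds, free=("gamma", "logKd")))

        def f(c, log_gamma, logkd):
            return np.atleast_1d(sabre_fraction(
                c, SabreParams(gamma=10 ** log_gamma, logKd=logkd)))

        popt, _ = curve_fit(f, CONC, ds.fractions, p0=[1.0, -6.0],
                            bounds=([-3, -12], [6, -1]), xtol=1e-15, ftol=1e-15)
        ss_ref = float(np.sum((f(CONC, *popt) - ds.fractions) ** 2))
        assert fit.ss == pytest.approx(ss_ref, abs=1e-8)

    def test_strategy3_noise_free_recovery(self, neca_pair_noisefree):
        fit = fit_global(build_strategy(neca_pair_noisefree, 3)[0])
        assert fit["gamma"] == pytest.approx(66.86, rel=1e-3)
        assert fit["q_NECA"] == pytest.approx(0.31, rel=1e-3)
        assert fit["logKd_NECA"] == pytest.approx(-5.88, rel=1e-3)
        assert not fit.ambiguous

    def test_strategy4_noise_free_recovery(self, shared_study_noisefree):
        logkd = {"NECA": -5.88, "CPA": -5.93, "CHA": -5.50}
        fit = fit_global(build_strategy(shared_study_noisefree, 4,
                                        logkd_values=logkd))
        assert fit["gamma"] == pytest.approx(86.84, rel=1e-3)
        assert fit["q"] == pytest.approx(0.22, rel=1e-3)

    def test_estimates_sharpen_as_noise_shrinks(self):
        """Median |gamma error| falls monotonically along a noise ladder."""
        medians = []
        for sd in (0.04, 0.01, 0.0025):
            errs = []
            for rep in range(9):
                design = StudyDesign(logKd={"NECA": -5.88}, gamma=66.86,
                                     q=0.31, concentrations=CONC,
                                     noise_sd=sd, seed=500 + rep)
                fit = fit_global(build_strategy(generate_study(design), 3)[0])
                errs.append(abs(fit["gamma"] - 66.86))
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]

    def test_single_curve_ridge_is_ambiguous(self):
        """eps, gamma, logKd free on one high-gain curve: the eps*gamma
        ridge makes every free parameter redundant."""
        ds = sabre_dataset("NECA", "N", epsilon=1, gamma=86.84, logKd=-5.88)
        fit = fit_global(build_single_curve_spec(ds))
        assert fit.ambiguous
        deps = fit.dependency_report.values
        assert deps["gamma"] >= 0.9999
        assert deps["logKd"] >= 0.9999

    def test_fixing_at_best_fit_preserves_ss(self, neca_pair_noisefree):
        fit = fit_global(build_strategy(neca_pair_noisefree, 3)[0])
        problem = fit._problem
        idx = fit.free_keys.index("gamma")
        _, ss = problem.solve_fixed({"gamma": fit._x[idx]}, warm=fit._x)
        assert ss == pytest.approx(fit.ss, abs=1e-10 + 1e-10 * fit.ss)


class TestOperationalPair:
    def make_pair(self, tau_n, tau_x, logkd):
        out = []
        for pre, tau in (("N", tau_n), ("X", tau_x)):
            p = OperationalParams(tau=tau, n=1, logKd=logkd)
            out.append(ECDataset("NECA", pre, CONC,
                                 100 * np.atleast_1d(operational_fraction(CONC, p))))
        return out

    def test_noise_free_recovery(self):
        fit = fit_operational_pair(self.make_pair(100.0, 10.0, -5.9))
        assert fit["tau_N"] == pytest.approx(100.0, rel=1e-4)
        assert fit["tau_X"] == pytest.approx(10.0, rel=1e-4)
        assert fit["logKd_NECA"] == pytest.approx(-5.9, rel=1e-4)

    def test_tau_ratio_recovers_operable_fraction(self):
        """Receptor depletion with linear stimulus scaling multiplies tau
        by the operable fraction, so tau_X/tau_N estimates q."""
        q = 0.22
        fit = fit_operational_pair(self.make_pair(120.0, 120.0 * q, -5.9))
        assert fit["tau_X"] / fit["tau_N"] == pytest.approx(q, rel=1e-4)

    def test_mismatched_pair_rejected(self):
        pair = self.make_pair(100.0, 10.0, -5.9)
        pair[1].agonist = "CPA"
        with pytest.raises(ValidationError):
            fit_operational_pair(pair)
        both_naive = self.make_pair(100.0, 10.0, -5.9)
        both_naive[1].pretreatment = "N"
        with pytest.raises(ValidationError):
            fit_operational_pair(both_naive)


class TestCompareModels:
    def test_weights_from_fits_to_same_observations(self, neca_pair_noisefree):
        sab = fit_global(build_strategy(neca_pair_noisefree, 3)[0])
        # noise-free SABRE data: SABRE must dominate the comparison
        op = fit_operational_pair(neca_pair_noisefree)
        cmp_ = compare_models(sab, op)
        assert cmp_.weights["sabre"] + cmp_.weights["operational"] == pytest.approx(1.0)
        assert cmp_.weights["sabre"] > 0.99

    def test_differing_observation_counts_rejected(self, neca_pair_noisefree,
                                                   shared_study_noisefree):
        sab = fit_global(build_strategy(neca_pair_noisefree, 3)[0])
        other = fit_global(build_strategy(
            shared_study_noisefree, 4,
            logkd_values={"NECA": -5.88, "CPA": -5.93, "CHA": -5.50}))
        with pytest.raises(ValidationError):
            compare_models(sab, other)
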
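"""Candidate dynamics families, RSE selection, group LRT, first-ring age."""

import numpy as np
import pytest

from heartwoodkit.dynamics import (
    FAMILIES,
    CandidateCurve,
    CandidateFit,
    first_ring_age,
    fit_family,
    group_lrt,
    select_model,
)


def _truth(family, x):
    if family == "linear":
        return 3.0 + 0.8 * x
    if family == "quadratic":
        return 1.0 + 0.5 * x + 0.07 * x**2
    if family == "power":
        return 2.0 * x**1.5
    return 100.0 + (5.0 - 100.0) * np.exp(-0.1 * x)  # asym_exp


class TestFitFamily:
    def test_noise_free_power_recovery(self):
        x = np.linspace(1, 20, 30)
        fit = fit_family("power", x, 2.0 * x**1.5)
        assert fit.params[0] == pytest.approx(2.0, abs=1e-6)
        assert fit.params[1] == pytest.approx(1.5, abs=1e-6)

    def test_asym_exp_parameter_meaning(self):
        x = np.linspace(0, 80, 60)
        est = CandidateCurve("asym_exp").fit(x, 100 + (5 - 100) * np.exp(-0.1 * x))
        a0, a1, a2 = est.params_
        assert est.predict([0.0])[0] == pytest.approx(5.0, abs=1e-6)
        assert est.predict([1e4])[0] == pytest.approx(100.0, abs=1e-6)
        assert a2 == pytest.approx(0.1, abs=1e-6)
        assert a2 > 0

    @pytest.mark.parametrize("family", FAMILIES)
    def test_noise_free_family_is_exact_and_selected(self, family):
        x = np.linspace(1, 25, 40)
        y = _truth(family, x)
        fits = [fit_family(f, x, y) for f in FAMILIES]
        own = next(f for f in fits if f.family == family)
        assert own.rss < 1e-12
        assert select_model(fits).chosen == family

    def test_power_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fit_family("power", [-1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])

    def test_rse_invariant_to_observation_order(self, rng):
        x = rng.uniform(1, 20, 50)
        y = 2 * x**1.2 + rng.normal(0, 1, 50)
        f1 = fit_family("power", x, y)
        perm = rng.permutation(50)
        f2 = fit_family("power", x[perm], y[perm])
        assert f1.rse == pytest.approx(f2.rse, rel=1e-8)

    def test_parameter_recovery_with_noise(self, rng):
        """Per-family truth recovered within 3 SE in >= 93% of replicates."""
        truths = {
            "linear": (3.0, 0.8),
            "power": (2.0, 1.5),
        }
        for family, truth in truths.items():
            hits = np.zeros(len(truth))
            reps = 60
            for _ in range(reps):
                x = rng.uniform(1, 20, 200)
                y = _truth(family, x) * np.exp(rng.normal(0, 0.02, 200)) \
                    if family == "power" else _truth(family, x) + rng.normal(0, 0.5, 200)
                f = fit_family(family, x, y)
                hits += (
                    np.abs(f.params[: len(truth)] - np.array(truth))
                    < 3 * f.param_ses[: len(truth)]
                )
            assert np.all(hits / reps >= 0.93), family


class TestSelection:
    def _mk(self, family, rse, n_params):
        return CandidateFit(
            family=family,
            params=np.zeros(n_params),
            param_ses=np.zeros(n_params),
            rse=rse,
            n=50,
            converged=True,
            loglik=0.0,
            rss=rse**2 * (50 - n_params),
        )

    def test_single_fit_chosen(self):
        sel = select_model([self._mk("power", 1.0, 2)])
        assert sel.chosen == "power"

    def test_tie_goes_to_fewer_parameters(self):
        sel = select_model(
            [self._mk("quadratic", 1.0, 3), self._mk("linear", 1.0, 2)]
        )
        assert sel.chosen == "linear"

    def test_nonconverged_excluded(self):
        bad = self._mk("power", 0.1, 2)
        bad.converged = False
        sel = select_model([bad, self._mk("linear", 1.0, 2)])
        assert sel.chosen == "linear"
        with pytest.raises(ValueError):
            select_model([bad])

    def test_quadratic_truth_usually_selected(self, rng):
        """Model selection by RSE identifies a quadratic truth under
        moderate noise in >= 90% of replicates."""
        wins = 0
        reps = 50
        for _ in range(reps):
            x = rng.uniform(1, 20, 120)
            y = _truth("quadratic", x) + rng.normal(0, 1.0, 120)
            fits = []
            for fam in FAMILIES:
                try:
                    fits.append(fit_family(fam, x, y))
                except (ValueError, RuntimeError):
                    pass
            wins += select_model(fits).chosen == "quadratic"
        assert wins / reps >= 0.90


class TestGroupLrt:
    def test_identical_groups_give_null(self, rng):
        x = rng.uniform(1, 20, 60)
        y = 2 * x**1.2 * np.exp(rng.normal(0, 0.05, 60))
        xx, yy = np.concatenate([x, x]), np.concatenate([y, y])
        g = np.array(["a"] * 60 + ["b"] * 60)
        shared, per_group = fit_family("power", xx, yy, groups=g)
        chi2, df, p = group_lrt(shared, per_group)
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert df == 2

    def test_statistic_nonnegative_and_detects_difference(self, rng):
        x = rng.uniform(1, 20, 200)
        g = np.array(["a"] * 100 + ["b"] * 100)
        b = np.where(g == "a", 1.0, 2.6)
        y = 2 * x**b * np.exp(rng.normal(0, 0.15, 200))
        shared, per_group = fit_family("power", x, y, groups=g)
        chi2, df, p = group_lrt(shared, per_group)
        assert chi2 >= 0
        assert p < 0.001

    def test_mismatched_families_rejected(self, rng):
        x = rng.uniform(1, 20, 40)
        y = x + rng.normal(0, 0.1, 40)
        lin = fit_family("linear", x, y)
        pw = {"a": fit_family("power", x[:20], y[:20]), "b": fit_family("power", x[20:], y[20:])}
        with pytest.raises(ValueError):
            group_lrt(lin, pw)


class TestFirstRingAge:
    def test_x_intercept_examples(self):
        f = fit_family("linear", np.array([20.0, 30, 40, 50.0]),
                       -15.0 + 1.0 * np.array([20.0, 30, 40, 50.0]))
        age, ci = first_ring_age(f)
        assert age == pytest.approx(15.0, abs=1e-8)
        x = np.array([20.0, 30, 40, 50.0])
        f2 = fit_family("linear", x, -8.64 + 0.96 * x)
        age2, _ = first_ring_age(f2)
        assert age2 == pytest.approx(9.0, abs=1e-8)

    def test_crossing_one_option(self):
        x = np.array([20.0, 30, 40, 50.0])
        f = fit_family("linear", x, -15.0 + 1.0 * x)
        age1, _ = first_ring_age(f, crossing=1.0)
        assert age1 == pytest.approx(16.0, abs=1e-6)

    def test_delta_and_bootstrap_cis_agree(self, rng):
        x = rng.uniform(15, 60, 300)
        y = -15 + 1.0 * x + rng.normal(0, 1.5, 300)
        f = fit_family("linear", x, y)
        _, ci_d = first_ring_age(f)
        _, ci_b = first_ring_age(f, ci_method="bootstrap", n_boot=4000)
        for d, b in zip(ci_d, ci_b):
            assert abs(d - b) / abs(d) < 0.10

    def test_nonpositive_rate_rejected(self):
        x = np.array([20.0, 30, 40, 50.0])
        f = fit_family("linear", x, 10.0 - 0.5 * x)
        with pytest.raises(ValueError):
            first_ring_age(f)
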
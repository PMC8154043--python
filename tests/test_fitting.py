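import numpy as np
import pandas as pd
import pytest
import scipy.optimize._numdiff

from leafflux.fitting import (
    ConstraintSet,
    FitProblem,
    Scenario,
    chi2_accept,
    eval_quantity,
    fit,
    scenario_compare,
)
from leafflux.network import compute_RL
from leafflux.synth import default_spec

from .conftest import MINI_FIT_KW, mini_dataset, noiseless_dataset


@pytest.fixture(scope="module")
def mini_ds():
    return mini_dataset(seed=1)


@pytest.fixture(scope="module")
def mini_problem(mini_ds):
    cons = ConstraintSet(boundary=mini_ds["boundary"])
    return FitProblem(mini_ds["model"], mini_ds["fragments"], mini_ds["mids"], cons)


class TestResiduals:
    def test_noiseless_data_zero_ssr_at_truth(self):
        spec = default_spec(seed=0)
        ds = noiseless_dataset(spec)
        cons = ConstraintSet(boundary=ds["boundary"], vo_vc_bounds=(0.2, 0.25))
        prob = FitProblem(spec.model, spec.fragments, ds["mids"], cons)
        d, pen = prob.residuals(prob.theta_from_flux(spec.truth))
        assert float(d @ d) < 1e-12
        assert float(pen @ pen) < 1e-12

    def test_datum_off_by_two_sd_contributes_four(self):
        """Shifting one datum by 2 sd makes its squared residual 4."""
        spec_sd = 0.02
        from leafflux import models
        from leafflux.emu import decompose
        from leafflux.measurement import MIDTimeSeries, predict_fragment
        from leafflux.simulate import TracerProgram, simulate

        model, truth, frags = (
            models.mini_model(), models.mini_truth(), models.mini_fragments()
        )
        times = (2.0, 5.0, 10.0, 20.0, 40.0)
        system = decompose(model, sorted({e for f in frags for e in f.emus()}))
        sim = simulate(system, truth, TracerProgram(purity=0.99), times)
        dil = truth.dilution_fraction.to_dict()
        mids = []
        for frag in frags:
            pred = predict_fragment(sim, frag, dil)
            values = pred.copy()
            # shift a fragment without a dilution pool so the profiled
            # dilution cannot absorb any of the deviation
            if frag.id == "a_frag":
                values[2, 1] += 2 * spec_sd
                values[2, 2] -= 2 * spec_sd  # keep the row on the simplex
            mids.append(MIDTimeSeries(frag.id, np.asarray(times), values,
                                      np.full(pred.shape, spec_sd)))
        cons = ConstraintSet(boundary={"flux:syn": (10.0, 0.3)})
        prob = FitProblem(model, frags, mids, cons)
        d, _pen = prob.residuals(prob.theta_from_flux(truth))
        assert float(d @ d) == pytest.approx(8.0, abs=1e-6)  # two entries moved 2 sd
        assert np.sort(np.abs(d))[-1] == pytest.approx(2.0, abs=1e-6)

    def test_unknown_fragment_rejected(self, mini_ds):
        cons = ConstraintSet(boundary=mini_ds["boundary"])
        bad = mini_ds["mids"][0]
        bad2 = type(bad)("nonexistent", bad.times_min, bad.values, bad.sd)
        with pytest.raises(KeyError):
            FitProblem(mini_ds["model"], mini_ds["fragments"], [bad2], cons)

    def test_gradient_consistency(self, mini_problem, mini_ds):
        """FD gradient of the SSR matches the Jacobian-based gradient."""
        theta = mini_problem.theta_from_flux(mini_ds["truth"])
        rng = np.random.default_rng(0)
        for _ in range(5):
            th = theta + rng.normal(0, 0.05, theta.size)
            J = scipy.optimize._numdiff.approx_derivative(
                mini_problem.full_residuals, th, method="3-point", rel_step=1e-6
            )
            r = mini_problem.full_residuals(th)
            grad_jac = 2 * J.T @ r

            def cost(x):
                rr = mini_problem.full_residuals(x)
                return float(rr @ rr)

            grad_fd = scipy.optimize._numdiff.approx_derivative(
                cost, th, method="3-point", rel_step=1e-6
            )
            denom = max(np.abs(grad_jac).max(), 1.0)
            assert np.abs(grad_fd - grad_jac).max() / denom < 1e-4


class TestChi2:
    def test_dof_1753_interval(self):
        interval, verdict = chi2_accept(810.0, 1753)
        # exact chi-square 2.5 / 97.5 % quantiles at 1,753 degrees of freedom
        assert interval[0] == pytest.approx(1638.85, abs=0.01)
        assert interval[1] == pytest.approx(1870.93, abs=0.01)
        # two-sided test: an SSR far below the interval is under-dispersed
        assert verdict is False

    def test_within_band_accepted(self):
        _, verdict = chi2_accept(1753.0, 1753)
        assert verdict is True

    @pytest.mark.parametrize("ssr", [0.0, 100.0])
    def test_dof10_extremes_rejected(self, ssr):
        _, verdict = chi2_accept(ssr, 10)
        assert verdict is False

    def test_bad_dof(self):
        with pytest.raises(ValueError):
            chi2_accept(1.0, 0)


class TestMiniFit:
    def test_multistart_recovery(self, mini_ds):
        cons = ConstraintSet(boundary=mini_ds["boundary"])
        res = fit(mini_ds["model"], mini_ds["mids"], cons,
                  fragments=mini_ds["fragments"], n_starts=8, seed=0,
                  **MINI_FIT_KW)
        truth = mini_ds["truth"]
        for rxn in ("syn", "ab", "rel"):
            assert res.flux.net_flux[rxn] == pytest.approx(
                truth.net_flux[rxn], rel=0.15
            ), rxn
        assert res.converged

    def test_ssr_at_truth_within_chi2_band(self):
        """Noise drawn at the stated sd puts the truth SSR in the 95% band."""
        hits = 0
        for seed in range(5):
            ds = mini_dataset(seed=seed)
            cons = ConstraintSet(boundary=ds["boundary"])
            prob = FitProblem(ds["model"], ds["fragments"], ds["mids"], cons)
            d, _ = prob.residuals(prob.theta_from_flux(ds["truth"]))
            ssr = float(d @ d)
            interval, ok = chi2_accept(ssr, prob.dof + prob.n_params)
            hits += ok
        assert hits >= 4

    def test_forced_scenario_never_beats_unconstrained(self, mini_ds):
        cons = ConstraintSet(boundary=mini_ds["boundary"])
        base = fit(mini_ds["model"], mini_ds["mids"], cons,
                   fragments=mini_ds["fragments"], n_starts=6, seed=1,
                   **MINI_FIT_KW)
        forced = fit(
            mini_ds["model"], mini_ds["mids"], cons,
            Scenario("forced_tca", target=6.0),  # truth rel flux is 3
            fragments=mini_ds["fragments"], n_starts=2, seed=1,
            start_from=base.flux, **MINI_FIT_KW,
        )
        assert forced.ssr > base.ssr
        assert forced.forced_value == pytest.approx(6.0, rel=0.01)
        table = scenario_compare([base, forced])
        assert table["scenario"].tolist() == ["unconstrained", "forced_tca"]
        assert table["dSSR"].iloc[0] == 0.0

    def test_scenario_compare_rejects_mixed_data(self, mini_ds):
        cons = ConstraintSet(boundary=mini_ds["boundary"])
        a = fit(mini_ds["model"], mini_ds["mids"], cons,
                fragments=mini_ds["fragments"], n_starts=2, seed=0,
                **MINI_FIT_KW)
        other = mini_dataset(seed=9)
        b = fit(other["model"], other["mids"],
                ConstraintSet(boundary=other["boundary"]),
                fragments=other["fragments"], n_starts=2, seed=0,
                **MINI_FIT_KW)
        with pytest.raises(ValueError, match="different datasets"):
            scenario_compare([a, b])
        with pytest.raises(ValueError):
            scenario_compare([a])


class TestCamelinaNoiselessRecovery:
    def test_truth_start_recovers_exactly(self):
        """Noiseless data, truth-initialized: fluxes back within 1e-3 relative."""
        spec = default_spec(seed=0)
        ds = noiseless_dataset(spec)
        cons = ConstraintSet(boundary=ds["boundary"], vo_vc_bounds=(0.2, 0.25))
        res = fit(spec.model, ds["mids"], cons, fragments=spec.fragments,
                  n_starts=1, start_from=spec.truth, n_polish=1, seed=0)
        assert res.ssr < 1e-6
        v_true = spec.truth.net_flux
        scale = np.abs(v_true).max()
        for rxn in v_true.index:
            assert abs(res.flux.net_flux[rxn] - v_true[rxn]) <= 1e-3 * max(
                abs(v_true[rxn]), 1e-3 * scale
            ), rxn
        rl = compute_RL(spec.model, res.flux)
        assert rl["RL_total"] == pytest.approx(
            ds_truth_rl := compute_RL(spec.model, spec.truth)["RL_total"], rel=1e-3
        )


class TestQuantities:
    def test_eval_quantity_names(self, camelina, camelina_truth):
        assert eval_quantity(camelina, camelina_truth, "flux:rbc_c") == pytest.approx(150.0)
        assert eval_quantity(camelina, camelina_truth, "ratio:rbc_o/rbc_c") == pytest.approx(0.2)
        assert eval_quantity(camelina, camelina_truth, "RL_total") == pytest.approx(
            compute_RL(camelina, camelina_truth)["RL_total"]
        )
        with pytest.raises(KeyError):
            eval_quantity(camelina, camelina_truth, "nope")

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            Scenario("forced_tca")
        with pytest.raises(ValueError):
            Scenario("bogus", target=1.0)
        with pytest.raises(ValueError):
            ConstraintSet(vo_vc_bounds=(0.3, 0.2))
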
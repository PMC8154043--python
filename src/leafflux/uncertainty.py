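"""Confidence intervals by parameter continuation and Monte-Carlo perturbation.

Two independent routes to 95 % intervals on any flux or derived quantity:

* **Parameter continuation** (profile likelihood): the quantity is stepped
  away from its optimum in both directions, re-optimizing all remaining
  parameters at each step; the interval ends where the profile SSR crosses
  SSR_min + 3.84 (the 95 % point of χ² with one degree of freedom), located
  by adaptive step halving.
* **Monte Carlo**: every measurement (MIDs and boundary rates) is resampled
  from a normal with its reported sd, the fit is repeated from the
  unperturbed optimum, and the 2.5/97.5 percentiles of the refit quantity
  form the interval.

Both are exposed generically over a residual function so linear toy
problems can validate them against closed forms, plus wrappers for
flux-fit problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .fitting import FitProblem, FitResult, eval_quantity
from .measurement import MIDTimeSeries

__all__ = [
    "ConfidenceInterval",
    "profile_ci",
    "continuation_ci",
    "monte_carlo_ci",
    "perturb_dataset",
]

CHI2_1_95 = 3.841458820694124  # χ²₁ 95 % quantile


@dataclass
class ConfidenceInterval:
    quantity: str
    estimate: float
    lower: float
    upper: float
    method: str  # "continuation" | "monte_carlo"
    level: float = 0.95
    open_lower: bool = False
    open_upper: bool = False

    def __post_init__(self):
        if not (self.lower <= self.estimate <= self.upper):
            raise ValueError("CI must bracket the point estimate")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def profile_ci(
    residual_fn,
    theta0: np.ndarray,
    quantity_fn,
    *,
    pin_residual,
    quantity_name: str = "quantity",
    bounds=None,
    threshold: float = CHI2_1_95,
    rel_step: float = 0.05,
    abs_step: float = 1e-3,
    max_steps: int = 40,
    n_halvings: int = 6,
) -> ConfidenceInterval:
    """Generic profile-likelihood interval over a residual function.

    ``residual_fn(theta)`` returns the weighted residual vector,
    ``quantity_fn(theta)`` the scalar of interest, and
    ``pin_residual(theta, target)`` an extra residual that is ~0 when the
    quantity equals ``target`` and climbs steeply otherwise (the pin used to
    re-optimize the remaining parameters at a fixed quantity value).
    A profile that stays below the threshold out to ``max_steps`` is flagged
    as an open (non-identifiable) interval side.
    """

    def full(theta, target):
        r = residual_fn(theta)
        return np.concatenate([r, np.atleast_1d(pin_residual(theta, target))])

    def reopt(theta_start, target):
        kw = {"method": "trf", "x_scale": "jac", "ftol": 1e-10, "xtol": 1e-12}
        if bounds is not None:
            kw["bounds"] = bounds
        res = scipy.optimize.least_squares(lambda th: full(th, target), theta_start, **kw)
        r = residual_fn(res.x)
        return res.x, float(r @ r)

    r0 = residual_fn(theta0)
    ssr_min = float(r0 @ r0)
    q0 = float(quantity_fn(theta0))
    limit = ssr_min + threshold
    step0 = max(abs(q0) * rel_step, abs_step)

    def walk(direction):
        theta, q, step = theta0, q0, step0
        prev_q, prev_ssr = q0, ssr_min
        for _ in range(max_steps):
            target = q + direction * step
            theta_new, ssr = reopt(theta, target)
            if ssr > limit:
                # bracket [prev_q, target]: adaptive halving to the crossing
                lo_q, hi_q, hi_ssr = prev_q, target, ssr
                lo_ssr = prev_ssr
                th = theta_new
                for _ in range(n_halvings):
                    mid = 0.5 * (lo_q + hi_q)
                    th, ssr_mid = reopt(th, mid)
                    if ssr_mid > limit:
                        hi_q, hi_ssr = mid, ssr_mid
                    else:
                        lo_q, lo_ssr = mid, ssr_mid
                # linear interpolation inside the final bracket
                if hi_ssr > lo_ssr:
                    frac = (limit - lo_ssr) / (hi_ssr - lo_ssr)
                else:
                    frac = 0.5
                return lo_q + frac * (hi_q - lo_q), False
            theta, prev_q, prev_ssr = theta_new, target, ssr
            q = target
            step *= 1.6
        return q, True  # profile flat to the search bound: open interval

    upper, open_up = walk(+1.0)
    lower, open_lo = walk(-1.0)
    return ConfidenceInterval(
        quantity=quantity_name,
        estimate=q0,
        lower=min(lower, q0),
        upper=max(upper, q0),
        method="continuation",
        open_lower=open_lo,
        open_upper=open_up,
    )


def continuation_ci(
    problem: FitProblem,
    fit_result: FitResult,
    quantity: str,
    *,
    rel_step: float = 0.05,
    max_steps: int = 40,
) -> ConfidenceInterval:
    """Parameter-continuation CI for a named quantity of a flux fit."""

    pin_sd = max(abs(eval_quantity(problem.model, fit_result.flux, quantity)) * 1e-3, 1e-5)

    def residual_fn(theta):
        return problem.full_residuals(theta)

    def quantity_fn(theta):
        return eval_quantity(problem.model, problem.flux_state(theta), quantity)

    def pin_residual(theta, target):
        return (quantity_fn(theta) - target) / pin_sd

    return profile_ci(
        residual_fn,
        fit_result.theta,
        quantity_fn,
        pin_residual=pin_residual,
        quantity_name=quantity,
        bounds=problem.bounds(),
        rel_step=rel_step,
        max_steps=max_steps,
    )


def perturb_dataset(data: list[MIDTimeSeries], boundary: dict, rng,
                    pool_obs: dict | None = None):
    """Resample every measurement from Normal(measured, sd).

    MID noise is drawn on the simplex (zero row sum) so rows stay
    normalized; boundary rates get additive noise and pool observations
    log-normal noise at their relative sd."""
    new_data = []
    for s in data:
        noise = rng.normal(0.0, 1.0, size=s.values.shape) * s.sd
        noise -= noise.mean(axis=1, keepdims=True)
        new_data.append(
            MIDTimeSeries(s.fragment_id, s.times_min.copy(), s.values + noise,
                          s.sd.copy(), s.n_replicates)
        )
    new_boundary = {
        name: (float(v + rng.normal(0.0, sd)), sd) for name, (v, sd) in boundary.items()
    }
    if pool_obs is None:
        return new_data, new_boundary
    new_pools = {
        met: (float(v * np.exp(rng.normal(0.0, rsd))), rsd)
        for met, (v, rsd) in pool_obs.items()
    }
    return new_data, new_boundary, new_pools


def monte_carlo_ci(
    draw_fn,
    estimates: dict[str, float],
    *,
    n_draws: int = 200,
    seed: int = 0,
    level: float = 0.95,
    max_failed_frac: float = 0.10,
) -> dict[str, ConfidenceInterval]:
    """Generic Monte-Carlo CIs: percentile intervals of refit quantities.

    ``draw_fn(rng)`` perturbs the data with the given substream, refits, and
    returns ``{quantity: value}``; each of ``n_draws`` draws receives an
    independent child stream of ``seed`` (reproducible and parallelizable by
    draw).  ``estimates`` are the unperturbed point estimates reported in
    the intervals.  Raising inside ``draw_fn`` counts as a failed draw; more
    than ``max_failed_frac`` failures is an error.
    """
    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(n_draws)]
    samples: dict[str, list[float]] = {}
    failed = 0
    for rng in streams:
        try:
            vals = draw_fn(rng)
        except Exception:
            failed += 1
            continue
        for q, v in vals.items():
            samples.setdefault(q, []).append(float(v))
    if failed > max_failed_frac * n_draws:
        raise RuntimeError(f"{failed}/{n_draws} Monte-Carlo draws failed to converge")

    alpha = (1.0 - level) / 2.0
    out = {}
    for q, vals in samples.items():
        arr = np.asarray(vals)
        lo_q, hi_q = np.percentile(arr, [100 * alpha, 100 * (1 - alpha)])
        est = estimates[q]
        out[q] = ConfidenceInterval(
            quantity=q,
            estimate=float(est),
            lower=float(min(lo_q, est)),
            upper=float(max(hi_q, est)),
            method="monte_carlo",
            level=level,
        )
    return out


def flux_monte_carlo_ci(
    problem: FitProblem,
    baseline_theta: np.ndarray,
    quantities: list[str],
    *,
    n_draws: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, ConfidenceInterval]:
    """Monte-Carlo CIs for a flux fit: perturb MIDs and boundary rates within
    their sd, refit warm-started from the unperturbed optimum."""
    from .fitting import ConstraintSet

    model, frags, tracer = problem.model, problem.fragments, problem.tracer
    cons = problem.constraints

    def draw(rng):
        data, boundary, pools = perturb_dataset(
            problem.data, cons.boundary, rng, cons.pool_obs
        )
        c2 = ConstraintSet(
            boundary=boundary, pool_obs=pools, vo_vc_bounds=cons.vo_vc_bounds,
            vo_rxn=cons.vo_rxn, vc_rxn=cons.vc_rxn,
        )
        p2 = FitProblem(model, frags, data, c2, problem.scenario, tracer,
                        n_grid=problem.n_grid)
        lo, hi = p2.bounds()
        res = scipy.optimize.least_squares(
            p2.full_residuals,
            np.clip(baseline_theta, lo + 1e-12, hi - 1e-12),
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            diff_step=1e-6,
            ftol=1e-8,
            xtol=1e-10,
            max_nfev=60,
        )
        fs = p2.flux_state(res.x)
        return {q: eval_quantity(model, fs, q) for q in quantities}

    fs0 = problem.flux_state(baseline_theta)
    estimates = {q: eval_quantity(model, fs0, q) for q in quantities}
    return monte_carlo_ci(draw, estimates, n_draws=n_draws, seed=seed, level=level)
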
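"""Parameter precision and between-condition significance.

Two routes quantify precision: parameter continuation (profile likelihood —
step one parameter away from its optimum re-optimizing all others until the
SSR rises by the chi-square quantile) and Monte Carlo resampling (perturb the
best-fit predictions with measurement noise and refit).  Between-condition
differences are called by comparing per-group confidence intervals: 83.4%
intervals under equal variances (non-overlap is then equivalent to P = 0.05),
or the normal-theory adjusted level

    [1 - 2 Phi(-1.96 sqrt(1 + rho^2) / (1 + rho))] x 100%

when the two groups' standard deviations differ by ratio rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from .fitting import FluxFitResults, scale_error

__all__ = [
    "MonteCarloEnsemble",
    "monte_carlo",
    "ci_from_ensemble",
    "adjusted_level",
    "compare_conditions",
    "continuation_ci",
    "profile_interval",
]


# -- Monte Carlo ----------------------------------------------------------

@dataclass
class MonteCarloEnsemble:
    """Refitted parameter vectors from Monte Carlo resampling.

    ``samples`` holds one converged refit per row in the model's structural
    parameter order; failed refits are kept in ``failures`` (round index and
    reason), never silently dropped.
    """

    samples: np.ndarray
    param_names: list
    condition: str = ""
    seed: object = None
    failures: list = field(default_factory=list)
    _model: object = None

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def theta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.param_names)

    def param_frame(self) -> pd.DataFrame:
        """Samples on natural scales: every net flux (free and dependent, by
        reaction id), exchange fluxes, pool sizes and mixing fractions."""
        m = self._model
        rows = []
        for row in self.samples:
            state, mixing = m.theta_to_state(row)
            rec = {rid: state.net[rid] for rid in m.param.reaction_ids}
            rec.update({f"exch:{r}": v for r, v in state.exchange.items()})
            rec.update({f"pool:{p}": v for p, v in state.pools.items()})
            for g, (w, u) in mixing.items():
                for i, wi in enumerate(np.atleast_1d(w)):
                    rec[f"mix:{g}:w{i}"] = wi
                rec[f"mix:{g}:unlabelled"] = u
            rows.append(rec)
        return pd.DataFrame(rows)

    def net_flux_frame(self, exclude_pseudo: bool = True) -> pd.DataFrame:
        m = self._model
        keep = [r.id for r in m.network.reactions
                if not (exclude_pseudo and r.pseudo)]
        return self.param_frame()[keep]

    def ci(self, param: str, level: float = 95.0):
        frame = self.param_frame() if ":" in param or param not in self.param_names \
            else self.theta_frame()
        if param in frame:
            return ci_from_ensemble(frame[param].to_numpy(), level)
        raise KeyError(f"unknown parameter {param!r}")


def monte_carlo(results: FluxFitResults, n: int = 1000, seed=None,
                max_nfev: int = 60, max_failure_rate: float = 0.10,
                condition: str = "") -> MonteCarloEnsemble:
    """Monte Carlo uncertainty: perturb best-fit predictions, refit, collect.

    Each round simulates data at the best-fit parameters, adds Gaussian noise
    with the per-measurement sigmas of the error model (clamped to [0, 1] and
    renormalized, matching the measurement process), perturbs the flux
    measurements by their sd, and refits from the best-fit vector.
    Deterministic given ``seed``; aborts if more than ``max_failure_rate`` of
    refits fail.
    """
    model = results.model
    base_obs = results.predict()
    rng = np.random.default_rng(seed)
    keep_meas = {g: model.meas[g] for g in model.groups}
    keep_sigma = {g: model.sigma[g] for g in model.groups}
    keep_flux = list(model.flux_measurements)
    samples, failures = [], []
    try:
        for round_i in range(n):
            for g in model.groups:
                P = base_obs[g][None, :, :].repeat(len(model.replicates), axis=0)
                sd = scale_error(100.0 * P, model.error_model) / 100.0
                noisy = np.clip(P + rng.normal(0.0, 1.0, P.shape) * sd, 0.0, 1.0)
                noisy /= noisy.sum(axis=2, keepdims=True)
                model.meas[g] = noisy
                model.sigma[g] = scale_error(100.0 * noisy,
                                             model.error_model) / 100.0
            model.flux_measurements = [
                (rid, results.params.net[rid] + rng.normal(0.0, sd), sd)
                for rid, _, sd in keep_flux]
            try:
                refit = model.fit(n_starts=0, start=results.theta,
                                  max_nfev=max_nfev)
                samples.append(refit.theta)
            except Exception as exc:
                failures.append((round_i, str(exc)))
            if len(failures) > max_failure_rate * n:
                raise RuntimeError(
                    f"Monte Carlo refit failure rate exceeded "
                    f"{max_failure_rate:.0%}: " +
                    "; ".join(msg for _, msg in failures[:5]))
    finally:
        model.meas = keep_meas
        model.sigma = keep_sigma
        model.flux_measurements = keep_flux
    return MonteCarloEnsemble(np.array(samples), list(model.param_names),
                              condition=condition, seed=seed,
                              failures=failures, _model=model)


def ci_from_ensemble(samples, level: float):
    """Ranked confidence interval: sort ascending, discard
    floor((1 - level/100)/2 * n) values from each end, return the range of
    the remainder (e.g. the top and bottom 8.3% for an 83.4% interval)."""
    if not (0.0 < level < 100.0):
        raise ValueError("confidence level must be in (0, 100)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    # guard the floor against float representation of the level (0.166/2 * 1000
    # must drop exactly 83)
    k = math.floor((1.0 - level / 100.0) / 2.0 * n + 1e-9)
    return float(x[k]), float(x[n - 1 - k])


def adjusted_level(rho: float) -> float:
    """Per-group confidence level whose interval non-overlap tests P = 0.05
    for groups with standard-deviation ratio ``rho``; 83.4% at rho = 1,
    approaching 95% as the variances diverge.  Symmetric in rho <-> 1/rho."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    return (1.0 - 2.0 * ndtr(-1.96 * math.sqrt(1.0 + rho ** 2) / (1.0 + rho))) * 100.0


def compare_conditions(ens_a: MonteCarloEnsemble, ens_b: MonteCarloEnsemble,
                       params=None, var_alpha: float = 0.05) -> pd.DataFrame:
    """Significance calls from CI overlap between two Monte Carlo ensembles.

    Per parameter: an F test on the ensemble variances decides between the
    83.4% equal-variance level and the rho-adjusted level; a parameter is
    significant when the two intervals at that level do not overlap.
    """
    fa = ens_a.param_frame() if ens_a._model is not None else ens_a.theta_frame()
    fb = ens_b.param_frame() if ens_b._model is not None else ens_b.theta_frame()
    if params is None:
        params = [c for c in fa.columns if c in fb.columns]
    missing = [p for p in params if p not in fa.columns or p not in fb.columns]
    if missing:
        raise KeyError(f"parameters absent from an ensemble: {missing}")
    rows = []
    for p in params:
        a, b = fa[p].to_numpy(), fb[p].to_numpy()
        sa, sb = np.std(a, ddof=1), np.std(b, ddof=1)
        if sa == 0 and sb == 0:
            rho, equal, level = 1.0, True, 83.4
        else:
            F = (sa ** 2) / (sb ** 2) if sb > 0 else np.inf
            dfa, dfb = len(a) - 1, len(b) - 1
            pval = 2 * min(stats.f.cdf(F, dfa, dfb), stats.f.sf(F, dfa, dfb))
            equal = pval >= var_alpha
            rho = sa / sb if sb > 0 else np.inf
            level = 83.4 if equal else adjusted_level(rho)
        ci_a = ci_from_ensemble(a, level)
        ci_b = ci_from_ensemble(b, level)
        significant = ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]
        rows.append({
            "param": p,
            "estimate_A": float(np.median(a)), "ci_A_lo": ci_a[0], "ci_A_hi": ci_a[1],
            "estimate_B": float(np.median(b)), "ci_B_lo": ci_b[0], "ci_B_hi": ci_b[1],
            "rho": rho, "equal_variance": equal, "level_used": level,
            "significant": significant,
        })
    return pd.DataFrame(rows)


# -- parameter continuation (profile likelihood) --------------------------

def profile_interval(profile_ssr, x_hat: float, ssr_min: float,
                     alpha: float = 0.05, step0: float = None,
                     lo: float = -np.inf, hi: float = np.inf,
                     max_steps: int = 40):
    """Confidence bounds where a profiled SSR crosses ssr_min + chi2_1(1-alpha).

    ``profile_ssr(value)`` returns the SSR minimized over all other
    parameters.  A flat profile (no crossing before ``lo``/``hi`` or step
    exhaustion) yields an unbounded side (+-inf), not an exception.
    """
    threshold = ssr_min + stats.chi2.ppf(1 - alpha, 1)
    if step0 is None:
        step0 = 0.05 * max(abs(x_hat), 0.1)

    def one_side(sign):
        step = step0
        x_prev, s_prev = x_hat, ssr_min
        for _ in range(max_steps):
            x = x_prev + sign * step
            bounded = False
            if x <= lo:
                x, bounded = lo, True
            if x >= hi:
                x, bounded = hi, True
            s = profile_ssr(x)
            if s >= threshold:
                f = lambda v: profile_ssr(v) - threshold
                try:
                    return optimize.brentq(f, min(x_prev, x), max(x_prev, x),
                                           xtol=1e-4 * max(abs(step0), 1e-6),
                                           maxiter=60)
                except ValueError:
                    return x
            if bounded:
                return sign * np.inf
            if s < s_prev + 0.1:
                step *= 2.0  # profile flat here: accelerate
            x_prev, s_prev = x, s
        return sign * np.inf

    return one_side(-1.0), one_side(+1.0)


def continuation_ci(results: FluxFitResults, param_name: str,
                    alpha: float = 0.05, max_nfev: int = 40,
                    max_improvements: int = 3, natural_scale: bool = True):
    """Profile-likelihood CI for one structural parameter of a fit.

    Steps the parameter away from its optimum re-optimizing all others; if a
    better global solution turns up during the scan the incumbent fit is
    replaced and the continuation restarted.  Returns ``(lower, upper)`` on
    the parameter's natural scale (pool sizes and exchange fluxes are profiled
    in log space and exponentiated; an unidentifiable direction gives an
    infinite bound, with exp(-inf) = 0 for log-scale parameters).
    """
    model = results.model
    if param_name not in model.param_names:
        raise KeyError(f"unknown parameter {param_name!r}")
    idx = model.param_names.index(param_name)
    log_scale = param_name.startswith(("pool:", "exch:"))

    theta_hat = results.theta.copy()
    ssr_min = results.ssr
    lb, ub = model.bounds
    improvements = 0

    while True:
        improved = {}
        warm = {"theta": theta_hat.copy()}

        def profile_ssr(value):
            start = warm["theta"].copy()
            start[idx] = value
            free = [j for j in range(len(start)) if j != idx]
            if not free:  # single-parameter model: nothing to re-optimize
                return model.ssr(start)

            def resid(sub):
                full = start.copy()
                full[np.array(free)] = sub
                return model.residuals(full)

            sol = optimize.least_squares(
                resid, np.clip(start[free], lb[free], ub[free]),
                bounds=(lb[free], ub[free]), method="trf", x_scale=1.0,
                diff_step=1e-5, ftol=1e-9, xtol=1e-10, max_nfev=max_nfev)
            ssr = float(2 * sol.cost)
            full = start.copy()
            full[np.array(free)] = sol.x
            warm["theta"] = full
            if ssr < ssr_min - 1e-6 and not improved:
                improved["theta"] = full.copy()
                improved["ssr"] = ssr
            return ssr

        interval = profile_interval(
            profile_ssr, theta_hat[idx], ssr_min, alpha=alpha,
            lo=lb[idx], hi=ub[idx])
        if improved and improvements < max_improvements:
            improvements += 1
            refit = model.fit(n_starts=0, start=improved["theta"])
            theta_hat, ssr_min = refit.theta.copy(), refit.ssr
            continue
        break

    if log_scale and natural_scale:
        return math.exp(interval[0]), math.exp(interval[1])
    return interval
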
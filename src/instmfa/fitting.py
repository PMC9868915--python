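"""Flux and pool-size estimation by variance-weighted nonlinear least squares.

`FluxModel` couples an atom-transition network to replicate MID time-course
tables and measured output (biomass) fluxes; `fit` minimizes the sum of
squared residuals weighted by per-measurement variances from the mol%-scaled
error model, restarting from random parameter sets to escape local minima.
A fit is accepted when the SSR falls inside the two-sided chi-square window
for its degrees of freedom, counting the closed-form MS normalisation factors
among the fitted parameters.

The free parameter vector stacks, in order: free net fluxes (raw, bounded
nonnegative for irreversible reactions), log exchange fluxes, log pool sizes,
and stick-breaking logits for measurement-mixing simplices (compartment
weights + unlabelled dilution fraction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .emu import CompiledSystem, decompose, simulate_timecourse
from .network import FluxParameterization, FluxState, NetworkModel

__all__ = [
    "ErrorModel",
    "scale_error",
    "weighted_ssr",
    "chi2_window",
    "parameter_breakdown",
    "degrees_of_freedom",
    "FluxModel",
    "FluxFitResults",
    "calibrate_error_model",
    "simplex_to_logits",
    "logits_to_simplex",
]


@dataclass(frozen=True)
class ErrorModel:
    """Mol%-dependent measurement error: sigma_min below ``x_low`` mol%,
    sigma_max above ``x_high`` mol%, linear in between.  Keeps small
    isotopologues from being assigned overly large errors."""

    sigma_min: float
    sigma_max: float
    x_low: float = 0.5
    x_high: float = 25.0

    def __post_init__(self):
        if not (0.0 < self.sigma_min <= self.sigma_max):
            raise ValueError("require 0 < sigma_min <= sigma_max")
        if not (self.x_low < self.x_high):
            raise ValueError("require x_low < x_high")


def scale_error(x, em: ErrorModel):
    """Sigma (mol%) assigned to an isotopologue abundance ``x`` (mol%)."""
    x = np.asarray(x, dtype=float)
    frac = np.clip((x - em.x_low) / (em.x_high - em.x_low), 0.0, 1.0)
    out = em.sigma_min + frac * (em.sigma_max - em.sigma_min)
    return out if out.ndim else float(out)


def weighted_ssr(simulated, measured, sigmas, normalisations=None) -> float:
    """Sum of squared residuals weighted by per-measurement variance."""
    sim = np.asarray(simulated, dtype=float)
    meas = np.asarray(measured, dtype=float)
    sig = np.asarray(sigmas, dtype=float)
    if np.any(sig <= 0):
        raise ValueError("sigma must be positive for every measurement")
    if normalisations is not None:
        sim = sim * np.asarray(normalisations, dtype=float)
    return float(np.sum(((sim - meas) / sig) ** 2))


def chi2_window(n_measurements: int, n_params: int, alpha: float = 0.05):
    """Two-sided chi-square acceptance window for the fit SSR.

    Returns ``(df, lower, upper)`` with the alpha/2 and 1-alpha/2 quantiles of
    the chi-square distribution at ``df = n - p`` degrees of freedom.
    """
    df = n_measurements - n_params
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    return df, float(stats.chi2.ppf(alpha / 2, df)), float(
        stats.chi2.ppf(1 - alpha / 2, df))


def parameter_breakdown(n_normalisations: int, n_free_fluxes: int,
                        n_pool_sizes: int) -> int:
    """Total free parameters of a measurement design (bookkeeping helper)."""
    return n_normalisations + n_free_fluxes + n_pool_sizes


def degrees_of_freedom(n_isotopologue: int, n_flux_measurements: int,
                       n_params: int) -> int:
    return n_isotopologue + n_flux_measurements - n_params


# -- simplex transforms ---------------------------------------------------

def logits_to_simplex(logits, m: int) -> np.ndarray:
    """Stick-breaking map from m-1 unconstrained logits to an m-simplex."""
    w = np.empty(m)
    rest = 1.0
    for i in range(m - 1):
        f = expit(logits[i])
        w[i] = rest * f
        rest *= 1.0 - f
    w[m - 1] = rest
    return w


def simplex_to_logits(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    m = len(w)
    out = np.empty(m - 1)
    rest = 1.0
    for i in range(m - 1):
        out[i] = logit(np.clip(w[i] / rest, 1e-12, 1 - 1e-12))
        rest -= w[i]
    return out


# -- the model ------------------------------------------------------------

class FluxModel:
    """Isotopically non-stationary MFA problem: network + data + error model.

    Parameters
    ----------
    network : NetworkModel
    data : tidy DataFrame (metabolite, n_carbons, time_min, replicate,
        isotopologue_index, value), fractions or mol%; all replicates are
        fitted simultaneously.  Metabolite names must match the network's
        measurement groups.
    flux_measurements : list of (reaction_id, value, sd) output-flux
        constraints (biomass composition measurements).
    error_model : ErrorModel used both to weight residuals and (by the
        generator and Monte Carlo machinery) to perturb data.
    normalise_ms : fit one multiplicative MS normalisation factor per
        (metabolite, time, replicate) MID, solved in closed form at each
        residual evaluation and counted among the free parameters.
    """

    def __init__(self, network: NetworkModel, data: pd.DataFrame,
                 flux_measurements=(), error_model=ErrorModel(1.20, 1.90),
                 substrates=None, normalise_ms=True,
                 rtol=1e-8, atol=1e-10, penalty=1e3):
        self.network = network
        self.error_model = error_model
        self.normalise_ms = normalise_ms
        self.substrates = substrates
        self.rtol, self.atol = rtol, atol
        self.penalty = penalty
        self.flux_measurements = list(flux_measurements)
        for rid, _, sd in self.flux_measurements:
            if rid not in network.reaction_index:
                raise ValueError(f"flux measurement for unknown reaction {rid}")
            if sd <= 0:
                raise ValueError(f"flux measurement {rid}: sd must be positive")

        self.groups = [g for g in network.measurements
                       if g in set(data["metabolite"])]
        extra = set(data["metabolite"]) - set(network.measurements)
        if extra:
            raise ValueError(f"data contains unmeasured metabolites {sorted(extra)}")
        self.emunet = decompose(network, self.groups)
        self.param = FluxParameterization(network)
        self.exchange_ids = [r.id for r in network.reactions if r.reversible]
        self.pool_ids = sorted({e.pool for e in self.emunet.emus})
        self.mix_groups = [g for g in self.groups
                           if network.measurements[g].n_mix_params > 0]

        self._ingest(data)
        self._build_names()

    # -- data layout -----------------------------------------------------

    def _ingest(self, data):
        self.times = np.array(sorted(data["time_min"].unique()), dtype=float)
        self.replicates = sorted(data["replicate"].unique())
        t_index = {t: i for i, t in enumerate(self.times)}
        r_index = {r: i for i, r in enumerate(self.replicates)}
        self.meas, self.sigma = {}, {}
        for g in self.groups:
            sub = data[data["metabolite"] == g]
            n = self.network.pools[self.network.measurements[g].pools[0]].n_carbons
            M = np.full((len(self.replicates), len(self.times), n + 1), np.nan)
            for (rep, t), gg in sub.groupby(["replicate", "time_min"]):
                vals = gg.sort_values("isotopologue_index")["value"].to_numpy()
                if len(vals) != n + 1:
                    raise ValueError(f"{g}: incomplete MID at t={t} rep={rep}")
                vals = vals / vals.sum()
                M[r_index[rep], t_index[t]] = vals
            if np.isnan(M).any():
                raise ValueError(f"{g}: missing time points in some replicate")
            self.meas[g] = M
            self.sigma[g] = scale_error(100.0 * M, self.error_model) / 100.0
        self.n_isotopologue = int(sum(m.size for m in self.meas.values()))
        self.n_normalisations = (
            sum(len(self.replicates) * len(self.times) for _ in self.groups)
            if self.normalise_ms else 0)

    def _build_names(self):
        names = [f"net:{r}" for r in self.param.free_ids]
        names += [f"exch:{r}" for r in self.exchange_ids]
        names += [f"pool:{p}" for p in self.pool_ids]
        for g in self.mix_groups:
            for i in range(self.network.measurements[g].n_mix_params):
                names.append(f"mix:{g}:{i}")
        self.param_names = names
        self.n_params_theta = len(names)
        self._n_free = self.param.n_free
        self._n_exch = len(self.exchange_ids)
        self._n_pool = len(self.pool_ids)
        lb = np.full(self.n_params_theta, -np.inf)
        ub = np.full(self.n_params_theta, np.inf)
        for i, rid in enumerate(self.param.free_ids):
            if not self.network.reaction_index[rid].reversible:
                lb[i] = 0.0
        o = self._n_free
        lb[o:o + self._n_exch] = math.log(1e-9)
        ub[o:o + self._n_exch] = math.log(1e3)
        o += self._n_exch
        lb[o:o + self._n_pool] = math.log(1e-6)
        ub[o:o + self._n_pool] = math.log(1e6)
        o += self._n_pool
        lb[o:] = -12.0
        ub[o:] = 12.0
        self.bounds = (lb, ub)

    @property
    def n_measurements(self) -> int:
        return self.n_isotopologue + len(self.flux_measurements)

    @property
    def n_parameters(self) -> int:
        return self.n_params_theta + self.n_normalisations

    # -- parameter packing -----------------------------------------------

    def theta_to_state(self, theta):
        theta = np.asarray(theta, dtype=float)
        o = self._n_free
        net = self.param.full_net(theta[:o])
        exch = {r: math.exp(theta[o + i]) for i, r in enumerate(self.exchange_ids)}
        o += self._n_exch
        pools = {p: math.exp(theta[o + i]) for i, p in enumerate(self.pool_ids)}
        o += self._n_pool
        mixing = {}
        for g in self.mix_groups:
            grp = self.network.measurements[g]
            m = grp.n_mix_params + 1
            w = logits_to_simplex(theta[o:o + m - 1], m)
            o += m - 1
            if grp.fit_unlabelled:
                mixing[g] = (w[:-1], w[-1])
            else:
                mixing[g] = (w, 0.0)
        return FluxState(net, exch, pools), mixing

    def state_to_theta(self, state: FluxState, mixing=None):
        """Inverse packing (used to start refits from a known solution)."""
        theta = np.empty(self.n_params_theta)
        theta[:self._n_free] = self.param.free_from_full(state.net)
        o = self._n_free
        for i, r in enumerate(self.exchange_ids):
            theta[o + i] = math.log(max(state.exchange.get(r, 1e-9), 1e-9))
        o += self._n_exch
        for i, p in enumerate(self.pool_ids):
            theta[o + i] = math.log(state.pools[p])
        o += self._n_pool
        mixing = mixing or {}
        for g in self.mix_groups:
            grp = self.network.measurements[g]
            m = grp.n_mix_params + 1
            if g in mixing:
                w, u = mixing[g]
                full = np.append(w, u) if grp.fit_unlabelled else np.asarray(w)
            else:
                full = np.full(m, 1.0 / m)
            theta[o:o + m - 1] = simplex_to_logits(full)
            o += m - 1
        return theta

    # -- simulation and residuals ----------------------------------------

    def simulate_observables(self, theta, times=None):
        """Observable MIDs (per group, shape (T, n+1)) at parameter vector theta."""
        state, mixing = self.theta_to_state(theta)
        times = self.times if times is None else np.asarray(times, dtype=float)
        sys_ = CompiledSystem(self.emunet, state, self.substrates)
        pool_mids = simulate_timecourse(self.emunet, state, times,
                                        rtol=self.rtol, atol=self.atol,
                                        system=sys_)
        out = {}
        for g in self.groups:
            grp = self.network.measurements[g]
            if g in mixing:
                w, u = mixing[g]
            else:
                w, u = grp.weights, grp.unlabelled_fraction
            mids = {p: pool_mids[p] for p in grp.pools}
            obs = sum(wi * mids[p] for wi, p in zip(w, grp.pools))
            obs = np.array(obs, dtype=float)
            obs[:, 0] += u
            out[g] = obs
        return out, state

    def residuals(self, theta):
        obs, state = self.simulate_observables(theta)
        res = []
        for g in self.groups:
            P = obs[g][None, :, :]                       # (1, T, K)
            M, S = self.meas[g], self.sigma[g]           # (R, T, K)
            if self.normalise_ms:
                num = np.sum(P * M / S ** 2, axis=2, keepdims=True)
                den = np.sum(P * P / S ** 2, axis=2, keepdims=True)
                s = num / den
            else:
                s = 1.0
            res.append(((s * P - M) / S).ravel())
        for rid, val, sd in self.flux_measurements:
            res.append(np.atleast_1d((state.net[rid] - val) / sd))
        # soft feasibility: dependent irreversible fluxes must stay nonnegative
        pen = [min(0.0, state.net[r.id]) * self.penalty
               for r in self.network.reactions
               if not r.reversible and r.id not in self.param.free_ids
               and r.id not in self.param.fixed]
        if pen:
            res.append(np.asarray(pen))
        return np.concatenate(res)

    def ssr(self, theta) -> float:
        return float(np.sum(self.residuals(theta) ** 2))

    # -- fitting ----------------------------------------------------------

    def random_start(self, rng) -> np.ndarray:
        """Random start: net fluxes log-uniform in [0.01, 2], exchange fluxes
        log-uniform in [0.01, 10], pool sizes log-uniform over 3 decades."""
        theta = np.empty(self.n_params_theta)
        theta[:self._n_free] = np.exp(
            rng.uniform(math.log(0.01), math.log(2.0), self._n_free))
        o = self._n_free
        theta[o:o + self._n_exch] = rng.uniform(
            math.log(0.01), math.log(10.0), self._n_exch)
        o += self._n_exch
        theta[o:o + self._n_pool] = rng.uniform(
            math.log(0.05), math.log(50.0), self._n_pool)
        o += self._n_pool
        theta[o:] = rng.uniform(-1.5, 1.5, self.n_params_theta - o)
        return theta

    def _minimize(self, theta0, max_nfev):
        theta0 = np.clip(theta0, self.bounds[0], self.bounds[1])
        # pools and exchange fluxes are log-transformed, so the raw columns
        # are already comparably scaled; jac-rescaling stalls near the optimum.
        # The finite-difference step must sit two decades above the
        # integrator's 1e-8 relative tolerance or the Jacobian drowns in
        # adaptive-step noise near a perfect fit.
        return optimize.least_squares(
            self.residuals, theta0, bounds=self.bounds, method="trf",
            x_scale=1.0, diff_step=1e-5, ftol=1e-9, xtol=1e-10, gtol=1e-10,
            max_nfev=max_nfev)

    def fit(self, n_starts: int = 32, seed=None, start=None, max_nfev=80):
        """Multistart damped least-squares estimation.

        Each start draws a random parameter vector (deterministic under
        ``seed``); the minimum-SSR converged start wins.  ``start`` prepends
        an explicit initial vector (e.g. a previous solution).
        """
        if self.n_measurements <= self.n_parameters:
            raise ValueError("problem not over-determined: n <= p")
        rng = np.random.default_rng(seed)
        starts = [] if start is None else [np.asarray(start, dtype=float)]
        starts += [self.random_start(rng) for _ in range(n_starts)]
        best, per_start, diagnostics = None, [], []
        for theta0 in starts:
            try:
                sol = self._minimize(theta0, max_nfev)
            except Exception as exc:  # singular simulation etc.
                per_start.append(np.inf)
                diagnostics.append(f"start failed: {exc}")
                continue
            ssr = float(2 * sol.cost)
            per_start.append(ssr)
            diagnostics.append(f"status {sol.status}, nfev {sol.nfev}")
            if best is None or ssr < float(2 * best.cost):
                best = sol
        if best is None:
            raise RuntimeError(
                "all starts failed to converge: " + "; ".join(diagnostics))
        return FluxFitResults(self, best, per_start, diagnostics, seed)


class FluxFitResults:
    """Best-fit parameters with acceptance diagnostics.

    Attributes include ``params`` (the fitted :class:`FluxState`), ``mixing``
    (per-observable compartment weights and unlabelled fractions), ``ssr``,
    ``accepted`` and the chi-square ``window``.  ``monte_carlo`` and
    ``continuation_ci`` (in :mod:`instmfa.uncertainty`) quantify precision.
    """

    def __init__(self, model: FluxModel, sol, per_start_ssr, diagnostics, seed):
        self.model = model
        self.theta = np.asarray(sol.x, dtype=float)
        self.ssr = float(2 * sol.cost)
        self.per_start_ssr = list(per_start_ssr)
        self.diagnostics = diagnostics
        self.seed = seed
        self.converged = sol.status > 0
        self.params, self.mixing = model.theta_to_state(self.theta)
        self.df, lo, hi = chi2_window(model.n_measurements, model.n_parameters)
        self.window = (lo, hi)
        self.accepted = lo <= self.ssr <= hi

    def predict(self, times=None):
        obs, _ = self.model.simulate_observables(self.theta, times)
        return obs

    def monte_carlo(self, n=1000, seed=None, max_nfev=60, **kw):
        from .uncertainty import monte_carlo
        return monte_carlo(self, n=n, seed=seed, max_nfev=max_nfev, **kw)

    def continuation_ci(self, param_name, alpha=0.05, **kw):
        from .uncertainty import continuation_ci
        return continuation_ci(self, param_name, alpha=alpha, **kw)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Isotopically non-stationary MFA fit",
            "=" * 51,
            f"observables: {len(m.groups)}  times: {len(m.times)}  "
            f"replicates: {len(m.replicates)}",
            f"measurements n = {m.n_measurements} "
            f"({m.n_isotopologue} isotopologue + "
            f"{len(m.flux_measurements)} flux)",
            f"parameters p = {m.n_parameters} ({m.n_params_theta} structural + "
            f"{m.n_normalisations} MS normalisations)",
            f"degrees of freedom = {self.df}",
            f"SSR = {self.ssr:.1f}   chi2 window (p=0.05): "
            f"{self.window[0]:.1f} - {self.window[1]:.1f}   "
            f"{'ACCEPTED' if self.accepted else 'REJECTED'}",
            "-" * 51,
            f"{'parameter':<24}{'estimate':>12}",
        ]
        state = self.params
        for rid in m.param.free_ids:
            lines.append(f"{'net ' + rid:<24}{state.net[rid]:>12.4f}")
        for rid in m.exchange_ids:
            lines.append(f"{'exch ' + rid:<24}{state.exchange[rid]:>12.4f}")
        for p in m.pool_ids:
            lines.append(f"{'pool ' + p:<24}{state.pools[p]:>12.3f}")
        for g, (w, u) in self.mixing.items():
            lines.append(f"{'mix ' + g:<24}{np.round(w, 3)!s:>12} "
                         f"unlabelled {u:.3f}")
        return "\n".join(lines)

    def flux_table(self) -> pd.DataFrame:
        m = self.model
        rows = []
        for r in m.network.reactions:
            rows.append({
                "flux": r.id,
                "equation": _equation(r),
                "value": self.params.net[r.id],
                "free": r.id in m.param.free_ids,
                "class": r.rxn_class,
            })
        return pd.DataFrame(rows)


def _equation(rxn):
    def side(entries):
        return " + ".join(p for p, _ in entries)
    arrow = "<->" if rxn.reversible else "->"
    return f"{side(rxn.reactants)} {arrow} {side(rxn.products)}"


def calibrate_error_model(model: FluxModel, results: FluxFitResults,
                          sigma_min_grid=None, sigma_max_grid=None,
                          mode: str = "rescore"):
    """Find the smallest error scaling that makes the fit statistically
    acceptable.

    Scans (sigma_min, sigma_max) pairs in increasing magnitude, recomputing
    the SSR under each candidate (``mode='rescore'``: re-weight the incumbent
    solution, refitting only the closed-form normalisations;
    ``mode='refit'``: re-optimize all parameters) and returns
    ``(ErrorModel, ssr, accepted)`` for the first pair whose SSR falls inside
    the chi-square window.  If none is acceptable the nearest pair is
    returned with ``accepted=False``.
    """
    if sigma_min_grid is None:
        sigma_min_grid = np.round(np.arange(0.2, 3.01, 0.1), 3)
    if sigma_max_grid is None:
        sigma_max_grid = np.round(np.arange(0.2, 4.01, 0.25), 3)
    _, lo, hi = chi2_window(model.n_measurements, model.n_parameters)
    candidates = sorted(
        ((sm, sx) for sm in sigma_min_grid for sx in sigma_max_grid
         if sm <= sx), key=lambda p: (p[0] + p[1], p[1]))
    nearest, nearest_dist = None, np.inf
    base_sigma = {g: s.copy() for g, s in model.sigma.items()}
    base_em = model.error_model
    try:
        for sm, sx in candidates:
            em = ErrorModel(sm, sx, base_em.x_low, base_em.x_high)
            model.error_model = em
            for g in model.groups:
                model.sigma[g] = scale_error(100.0 * model.meas[g], em) / 100.0
            if mode == "refit":
                res = model.fit(n_starts=0, start=results.theta)
                ssr = res.ssr
            else:
                ssr = model.ssr(results.theta)
            if lo <= ssr <= hi:
                return em, ssr, True
            dist = min(abs(ssr - lo), abs(ssr - hi))
            if dist < nearest_dist:
                nearest, nearest_dist = (em, ssr), dist
    finally:
        model.error_model = base_em
        model.sigma = base_sigma
    return nearest[0], nearest[1], False
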
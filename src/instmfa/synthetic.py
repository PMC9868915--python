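"""In-silico 13C labelling experiments with the statistical structure the
estimator assumes.

A bolus of uniformly labelled glucose (default 60% enrichment) is added at
t = 0, replicate cultures are sampled on a fixed minute grid, and observable
MIDs are the compartment-mixed, dilution-corrupted model predictions plus
independent Gaussian noise whose standard deviation follows the mol%-scaled
error model.  Perturbed substrate-supply scenarios (pure delay, first-order
arrival, arrival-time distributions over a cell-aggregate population, and a
transient unlabelled-carbon pulse) support the robustness analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .emu import decompose, simulate_timecourse
from .fitting import ErrorModel, FluxModel, scale_error
from .network import FluxState, NetworkModel, parse_model

__all__ = [
    "ExperimentDesign",
    "default_design",
    "oxidative_design",
    "bundled_model",
    "generate_experiment",
    "delayed_substrate",
    "first_order_substrate",
    "pulsed_substrate",
    "aggregate_population",
    "DEFAULT_TIMES",
]

DEFAULT_TIMES = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0, 15.0, 20.0, 30.0,
                 60.0, 120.0, 270.0)


def bundled_model(name: str = "mini_heterotroph") -> NetworkModel:
    """Load a model shipped with the package (``mini_heterotroph`` or
    ``arabidopsis_core``)."""
    text = (resources.files("instmfa") / "models" / f"{name}.model").read_text()
    return parse_model(text)


@dataclass
class ExperimentDesign:
    """Everything needed to generate one labelling experiment.

    ``truth`` is the ground-truth flux state; ``mixing`` gives per-observable
    (weights, unlabelled_fraction) used when composing measurements.
    ``substrate_mode`` is one of ``"step"`` (default), ``("delayed", minutes)``,
    ``("first_order", time-constant minutes)``, or a callable t -> MID.
    """

    model: NetworkModel
    truth: FluxState
    mixing: dict = field(default_factory=dict)
    substrate_pool: str = None
    substrate_enrichment: float = 0.60
    times: tuple = DEFAULT_TIMES
    replicates: int = 3
    error_model: ErrorModel = field(default_factory=lambda: ErrorModel(1.20, 1.90))
    substrate_mode: object = "step"
    flux_measurement_sd: float = 0.02

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must start at 0 and increase strictly")
        if self.substrate_pool is None:
            labelled = [p for p in self.model.substrates]
            if len(labelled) != 1:
                raise ValueError("ambiguous substrate pool; set substrate_pool")
            self.substrate_pool = labelled[0]

    def substrate_mid(self):
        """Molecular substrate MID (or callable of time) for the design."""
        pool = self.model.pools[self.substrate_pool]
        base = _uniform_mixture(pool.n_carbons, self.substrate_enrichment)
        mode = self.substrate_mode
        if mode == "step" or mode is None:
            return base
        if callable(mode):
            return mode
        kind, value = mode
        if kind == "delayed":
            return delayed_substrate(base, value)
        if kind == "first_order":
            return first_order_substrate(base, value)
        raise ValueError(f"unknown substrate mode {mode!r}")


def _uniform_mixture(n_carbons: int, enrichment: float) -> np.ndarray:
    mid = np.zeros(n_carbons + 1)
    mid[0] = 1.0 - enrichment
    mid[-1] = enrichment
    return mid


def _e0(n):
    v = np.zeros(n + 1)
    v[0] = 1.0
    return v


# -- substrate-supply scenarios ------------------------------------------

def delayed_substrate(base_mid: np.ndarray, delay_min: float):
    """Step arrival lagged by a pure delay (unlabelled before ``delay_min``)."""
    if delay_min < 0:
        raise ValueError("delay must be nonnegative")
    base = np.asarray(base_mid, dtype=float)
    unlab = _e0(len(base) - 1)

    def mid(t):
        return base if t >= delay_min else unlab

    return mid


def first_order_substrate(base_mid: np.ndarray, tau_min: float):
    """Labelled fraction saturating as 1 - exp(-t / tau) (diffusive arrival)."""
    base = np.asarray(base_mid, dtype=float)
    unlab = _e0(len(base) - 1)

    def mid(t):
        lam = 1.0 - np.exp(-max(t, 0.0) / tau_min) if tau_min > 0 else 1.0
        return lam * base + (1 - lam) * unlab

    return mid


def pulsed_substrate(base_mid: np.ndarray, t_on: float, t_off: float,
                     depth: float = 0.5):
    """Transient unlabelled-carbon input: the effective substrate enrichment
    drops by ``depth`` between ``t_on`` and ``t_off`` (mobilization of
    unlabelled stores competing with the tracer at the hexose entry point)."""
    base = np.asarray(base_mid, dtype=float)
    unlab = _e0(len(base) - 1)

    def mid(t):
        lam = 1.0 - depth if t_on <= t < t_off else 1.0
        return lam * base + (1 - lam) * unlab

    return mid


# -- designs --------------------------------------------------------------

_MINI_TRUTH_NET = dict(upt=1.0, glcv=0.162, pk=0.477, ana1=0.685, ana2=0.5,
                       pdh=0.8, pyrout=0.177, malout=0.185, co2out=0.615)
_MINI_TRUTH_NET_OX = dict(upt=1.0, glcv=0.113, pk=0.173, ana1=0.940,
                          ana2=0.760, pdh=0.780, pyrout=0.153, malout=0.180,
                          co2out=0.600)
_MINI_POOLS = {"PEP.c": 0.3, "PYR.c": 0.6, "MAL.c": 25.0, "CO2": 0.4}
_MINI_MIXING = {"MAL": (np.array([0.75]), 0.25)}


def default_design(seed_model: NetworkModel = None, **kw) -> ExperimentDesign:
    """The control-condition synthetic experiment on the bundled reduced
    network: substrate uptake fixed at 1, unlabelled-store dilution, the
    pyruvate-kinase / anaplerotic flux motif of the heterotrophic flux map,
    pool turnover times spread from seconds to tens of minutes, and a
    metabolically inactive malate fraction observed on extraction."""
    model = seed_model or bundled_model("mini_heterotroph")
    truth = FluxState(dict(_MINI_TRUTH_NET), {"ana1": 0.2}, dict(_MINI_POOLS))
    return ExperimentDesign(model=model, truth=truth,
                            mixing=dict(_MINI_MIXING), **kw)


def oxidative_design(seed_model: NetworkModel = None, **kw) -> ExperimentDesign:
    """The perturbed condition: pyruvate-kinase flux decreased, PEP-carboxylase
    and malic-enzyme fluxes increased, unlabelled-store input decreased —
    the oxidative-load flux signature."""
    model = seed_model or bundled_model("mini_heterotroph")
    truth = FluxState(dict(_MINI_TRUTH_NET_OX), {"ana1": 0.2}, dict(_MINI_POOLS))
    kw.setdefault("error_model", ErrorModel(1.45, 2.15))
    return ExperimentDesign(model=model, truth=truth,
                            mixing=dict(_MINI_MIXING), **kw)


# -- generation -----------------------------------------------------------

def simulate_design(design: ExperimentDesign, times=None):
    """Noise-free observable time-courses for a design (dict name -> (T, K))."""
    model = design.model
    times = np.asarray(design.times if times is None else times, dtype=float)
    net = decompose(model, list(model.measurements))
    subs = {design.substrate_pool: design.substrate_mid()}
    pool_mids = simulate_timecourse(net, design.truth, times, substrates=subs)
    out = {}
    for gname, grp in model.measurements.items():
        if gname in design.mixing:
            w, u = design.mixing[gname]
        else:
            w, u = grp.weights, grp.unlabelled_fraction
        obs = sum(wi * pool_mids[p] for wi, p in zip(np.atleast_1d(w), grp.pools))
        obs = np.array(obs, dtype=float)
        obs[:, 0] += u
        out[gname] = obs
    return out


def generate_experiment(design: ExperimentDesign, seed=None, noise=True):
    """Generate replicate MID tables plus the ground-truth record.

    Gaussian noise with sd = scale_error(value) on the mol% scale is added
    independently per measurement, clamped to [0, 1] and renormalized.  One
    master seed spawns independent per-replicate, per-metabolite streams.
    Returns ``(DataFrame, truth_record)`` where the table uses the tidy MID
    dialect (metabolite, n_carbons, time_min, replicate, isotopologue_index,
    value) and the record carries the design's flux state, mixing and the
    measured output fluxes with their sd.
    """
    model = design.model
    clean = simulate_design(design)
    if noise and scale_error(100.0, design.error_model) > 50.0:
        raise ValueError("error model sd above 50 mol% — implausible noise")
    ss = np.random.SeedSequence(seed)
    rows = []
    times = np.asarray(design.times, dtype=float)
    streams = {}
    for gname in model.measurements:
        for rep in range(1, design.replicates + 1):
            streams[(gname, rep)] = np.random.default_rng(
                ss.spawn(1)[0]) if noise else None
    for gname, grp in model.measurements.items():
        n = model.pools[grp.pools[0]].n_carbons
        for rep in range(1, design.replicates + 1):
            rng = streams[(gname, rep)]
            for ti, t in enumerate(times):
                mid = clean[gname][ti].copy()
                if noise:
                    sd = scale_error(100.0 * mid, design.error_model) / 100.0
                    mid = mid + rng.normal(0.0, sd)
                    mid = np.clip(mid, 0.0, 1.0)
                    s = mid.sum()
                    mid = mid / s if s > 0 else _e0(n)
                for k in range(n + 1):
                    rows.append((gname, n, t, rep, k, mid[k]))
    df = pd.DataFrame(rows, columns=["metabolite", "n_carbons", "time_min",
                                     "replicate", "isotopologue_index",
                                     "value"])
    # measured biomass outputs carry their stated error like any measurement
    flux_rng = np.random.default_rng(ss.spawn(1)[0]) if noise else None
    flux_meas = []
    for r in model.reactions:
        if r.rxn_class != "output" or any(p == "CO2.eff"
                                          for p, _ in r.products):
            continue
        true_v = design.truth.net[r.id]
        sd = max(design.flux_measurement_sd, 0.05 * abs(true_v))
        meas_v = true_v + (flux_rng.normal(0.0, sd) if noise else 0.0)
        flux_meas.append((r.id, meas_v, sd))
    record = {
        "net": dict(design.truth.net),
        "exchange": dict(design.truth.exchange),
        "pools": dict(design.truth.pools),
        "mixing": {g: (list(np.atleast_1d(w)), float(u))
                   for g, (w, u) in design.mixing.items()},
        "substrate_enrichment": design.substrate_enrichment,
        "flux_measurements": flux_meas,
        "seed": seed,
    }
    return df, record


def flux_model_for(design: ExperimentDesign, data: pd.DataFrame,
                   record: dict, **kw) -> FluxModel:
    """Convenience constructor wiring a generated experiment into a FluxModel."""
    kw.setdefault("error_model", design.error_model)
    return FluxModel(design.model, data,
                     flux_measurements=record["flux_measurements"],
                     substrates={design.substrate_pool: design.substrate_mid()},
                     **kw)


def aggregate_population(design: ExperimentDesign, delays, weights=None,
                         times=None):
    """Observable time-courses of a cell population with distributed tracer
    arrival: the expectation over per-delay simulations.

    ``delays`` is a sequence of arrival delays in minutes (a point mass
    reduces to :func:`delayed_substrate`); ``weights`` defaults to uniform.
    """
    delays = np.asarray(delays, dtype=float)
    if np.any(delays < 0):
        raise ValueError("arrival-time distribution has mass at negative delays")
    if weights is None:
        weights = np.full(len(delays), 1.0 / len(delays))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    out = None
    for d, w in zip(delays, weights):
        sub_design = ExperimentDesign(
            model=design.model, truth=design.truth, mixing=design.mixing,
            substrate_pool=design.substrate_pool,
            substrate_enrichment=design.substrate_enrichment,
            times=design.times, replicates=design.replicates,
            error_model=design.error_model, substrate_mode=("delayed", d))
        sim = simulate_design(sub_design, times=times)
        if out is None:
            out = {g: w * v for g, v in sim.items()}
        else:
            for g, v in sim.items():
                out[g] += w * v
    return out
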
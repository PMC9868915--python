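"""Measurement-side processing of mass isotopologue distributions (MIDs).

Raw MIDs from the instrument are transformed into the quantities the model is
fitted to: correction for the natural abundance of 13C, least-squares
deconvolution of co-eluting species, fractional atom enrichment, and
normalization to the enrichment of the supplied substrate.  All vectors are
stored as fractions summing to one; mol% input (summing to ~100) is detected
and rescaled on ingest.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls, minimize_scalar
from scipy.special import comb

__all__ = [
    "as_fractions",
    "natural_abundance_matrix",
    "correct_natural_abundance",
    "deconvolute_overlap",
    "fractional_enrichment",
    "normalize_to_substrate",
    "read_mid_table",
    "write_mid_table",
]

P13C_DEFAULT = 0.0107  # natural 13C abundance


def as_fractions(mid) -> np.ndarray:
    """Normalize a MID to fractions; accepts mol% (0-100) or fraction input."""
    mid = np.asarray(mid, dtype=float)
    s = mid.sum()
    if s <= 0:
        raise ValueError("MID has non-positive total signal")
    return mid / s


def natural_abundance_matrix(n_carbons: int, p13: float = P13C_DEFAULT) -> np.ndarray:
    """Convolution matrix C with observed = C @ corrected.

    ``C[i, j]`` is the probability that a molecule with j tracer-labelled
    carbons is observed at mass i, i.e. that i - j of its n - j remaining
    carbons carry a natural 13C:  binom(n-j, i-j) p^(i-j) (1-p)^(n-j-(i-j)).
    """
    n = n_carbons
    C = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        for i in range(j, n + 1):
            C[i, j] = comb(n - j, i - j) * p13 ** (i - j) * (1 - p13) ** (n - i)
    return C


def correct_natural_abundance(raw, n_carbons: int, p13: float = P13C_DEFAULT,
                              tol: float = 1e-6) -> np.ndarray:
    """Remove the natural-abundance contribution from an observed MID.

    Solves the nonnegative least-squares system ``C x = raw`` and renormalizes;
    forward-convolving the result with C reproduces the observation to solver
    tolerance.  A residual beyond ``tol`` (an observation no nonnegative
    composition can explain) is reported as a measurement anomaly.
    """
    if not (0.0 <= p13 <= 0.05):
        raise ValueError("p13 outside the plausible range [0, 0.05]")
    raw = as_fractions(raw)
    if len(raw) != n_carbons + 1:
        raise ValueError("MID length does not match n_carbons + 1")
    C = natural_abundance_matrix(n_carbons, p13)
    x, rnorm = nnls(C, raw)
    if rnorm > max(tol, 1e-8 * np.sqrt(len(raw))):
        warnings.warn(
            f"natural-abundance correction residual {rnorm:.2e} exceeds "
            f"tolerance: negative-mass anomaly in the measurement",
            stacklevel=2)
    return as_fractions(x)


def deconvolute_overlap(observed, contaminant):
    """Split an observed MID into a clean component and a known contaminant.

    Minimizes ``||observed - [alpha * contaminant + (1 - alpha) * x]||`` over
    the component MID ``x >= 0`` (renormalized) and the mixing fraction
    ``alpha`` in [0, 1].  Returns ``(x, alpha)``.  Used e.g. to strip the UDP
    contribution from the UDP-glucose channel.  ``alpha`` near 1 (no residual
    component signal) or a contaminant identical to the observation leaves
    ``alpha`` unidentifiable and raises.
    """
    obs = as_fractions(observed)
    con = as_fractions(contaminant)
    if len(obs) != len(con):
        raise ValueError("observed and contaminant MIDs differ in length")

    def component(alpha):
        if alpha >= 1.0:
            return np.full_like(obs, np.nan)
        return _project_simplex((obs - alpha * con) / (1.0 - alpha))

    def loss(alpha):
        x = component(alpha)
        return float(np.sum((obs - alpha * con - (1 - alpha) * x) ** 2))

    # An exact mixture fits for every alpha up to the true fraction, so take
    # the largest alpha that still leaves a nonnegative component (maximal
    # contaminant removal); fall back to least squares for noisy data.
    mask = con > 1e-12
    alpha = float(min(1.0, np.min(obs[mask] / con[mask])))
    if not np.isfinite(loss(alpha)) or loss(alpha) > 1e-16:
        res = minimize_scalar(loss, bounds=(0.0, 1.0 - 1e-9), method="bounded",
                              options={"xatol": 1e-10})
        alpha = float(res.x)
    if np.allclose(obs, con, atol=1e-9) or alpha > 1.0 - 1e-6:
        raise ValueError("degenerate deconvolution: contaminant explains the "
                         "observation; mixing fraction unidentifiable")
    return component(alpha), alpha


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / np.arange(1, len(v) + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.clip(v - theta, 0.0, None)


def fractional_enrichment(mid) -> float:
    """Probability that a randomly chosen carbon is 13C: sum_i a_i * i / n."""
    mid = as_fractions(mid)
    n = len(mid) - 1
    if n == 0:
        raise ValueError("fractional enrichment undefined for a 0-carbon MID")
    return float(np.dot(mid, np.arange(n + 1)) / n)


def normalize_to_substrate(enrichment: float, substrate_fraction: float,
                           warn_above: float = 1.05) -> float:
    """Scale an enrichment by the labelled fraction of the supplied substrate."""
    if not (0.0 < substrate_fraction <= 1.0):
        raise ValueError("substrate fraction must be in (0, 1]")
    out = enrichment / substrate_fraction
    if out > warn_above:
        warnings.warn(
            f"normalized enrichment {out:.3f} exceeds unity beyond noise",
            stacklevel=2)
    return out


# -- tidy table I/O -------------------------------------------------------

_COLUMNS = ["metabolite", "n_carbons", "time_min", "replicate",
            "isotopologue_index", "value"]


def write_mid_table(path, records: pd.DataFrame):
    records.to_csv(path, index=False)


def read_mid_table(path) -> pd.DataFrame:
    """Read a tidy MID CSV and validate its layout.

    Columns: metabolite, n_carbons, time_min, replicate, isotopologue_index,
    value[, sd].  Values may be mol% or fractions; each (metabolite, time,
    replicate) MID is renormalized to fractions.  The time grid must be
    non-decreasing within each replicate series as written.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MID table missing columns {missing}")
    out = []
    for (met, rep), g in df.groupby(["metabolite", "replicate"], sort=False):
        times = g["time_min"].drop_duplicates().to_numpy()
        if np.any(np.diff(times) < 0):
            raise ValueError(
                f"time grid for {met} replicate {rep} is not sorted")
        for t, gg in g.groupby("time_min", sort=False):
            gg = gg.sort_values("isotopologue_index").copy()
            n = int(gg["n_carbons"].iloc[0])
            if list(gg["isotopologue_index"]) != list(range(n + 1)):
                raise ValueError(
                    f"{met} t={t} rep={rep}: isotopologue indices must run 0..n")
            gg["value"] = as_fractions(gg["value"].to_numpy())
            out.append(gg)
    return pd.concat(out, ignore_index=True)
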
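"""Brute-force isotopomer ODE simulation — an independent oracle for the EMU path.

Every balanced pool carries the full 2^n vector of positional isotopomer
fractions; production probabilities are computed by marginalizing each
reactant's isotopomer distribution over the atoms it passes to the product.
Exponential in carbon count, so guarded to small toy networks; MIDs are
obtained by marginalizing over label positions and must agree with the EMU
cascade to integrator accuracy.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import odeint
from scipy.special import comb

from .network import NetworkModel, FluxState
from .emu import _directional_variants

__all__ = ["brute_force_isotopomer_simulate"]

MAX_TOTAL_STATES = 4096


def _source_isotopomers(mol_mid: np.ndarray, n: int) -> np.ndarray:
    """Position-exchangeable isotopomer distribution from a molecular MID."""
    x = np.zeros(2 ** n)
    for iso in range(2 ** n):
        k = bin(iso).count("1")
        x[iso] = mol_mid[k] / comb(n, k)
    return x


def _marginal_operator(n: int, positions: tuple) -> np.ndarray:
    """Matrix taking a 2^n isotopomer vector to the 2^m distribution of the
    label pattern on ``positions`` (1-based), other atoms summed out."""
    m = len(positions)
    M = np.zeros((2 ** m, 2 ** n))
    for iso in range(2 ** n):
        pat = 0
        for j, p in enumerate(positions):
            if iso >> (p - 1) & 1:
                pat |= 1 << j
        M[pat, iso] += 1.0
    return M


def brute_force_isotopomer_simulate(model: NetworkModel, state: FluxState,
                                    times, substrates=None, targets=None,
                                    rtol=1e-10, atol=1e-12):
    """Integrate the full isotopomer system; returns target-pool MIDs.

    Same contract as :func:`instmfa.emu.simulate_timecourse`; refuses networks
    whose summed isotopomer state space exceeds ``MAX_TOTAL_STATES``.
    """
    times = np.asarray(times, dtype=float)
    subs = dict(substrates or {})
    if targets is None:
        targets = sorted(model.measurements) or [
            p.name for p in model.pools.values() if p.balanced]
    target_pools = []
    for t in targets:
        if t in model.measurements:
            target_pools.extend(model.measurements[t].pools)
        else:
            target_pools.append(t)
    target_pools = list(dict.fromkeys(target_pools))

    pools = [p for p in model.pools.values() if p.balanced]
    if sum(2 ** p.n_carbons for p in pools) > MAX_TOTAL_STATES:
        raise ValueError("isotopomer state space too large for brute force")
    offsets, off = {}, 0
    for p in pools:
        offsets[p.name] = off
        off += 2 ** p.n_carbons
    nx = off

    def sub_mid(pool_name, t):
        spec = subs.get(pool_name)
        if spec is None:
            spec = model.substrate_mid(pool_name)
        mid = spec(t) if callable(spec) else spec
        return np.asarray(mid, dtype=float)

    def dirflux(rxn, d):
        return state.forward(rxn) if d == "f" else state.backward(rxn)

    # precompute production structure:
    # (target pool, coef, [(reactant pool/source, marginal op or None, bit widths, required-bit extractor)])
    jobs = []
    for rxn in model.reactions:
        for d in ("f", "b") if rxn.reversible else ("f",):
            phi = dirflux(rxn, d)
            for w, reac, prod in _directional_variants(rxn, d):
                for ppool, pmap in prod:
                    if ppool not in offsets:
                        continue
                    n_p = model.pools[ppool].n_carbons
                    # for each reactant, positions mapped into this product
                    # and, per product isotopomer, the required bit pattern
                    factors = []
                    for qpool, qmap in reac:
                        positions = tuple(
                            i + 1 for i, ch in enumerate(qmap) if ch in pmap)
                        if not positions:
                            continue
                        # product atom index receiving each mapped position
                        dest = [pmap.index(qmap[p - 1]) for p in positions]
                        factors.append((qpool, positions, dest))
                    jobs.append((ppool, n_p, phi * w / state.pools[ppool],
                                 factors, rxn.id, d))

    # cache marginal operators per (pool, positions)
    ops = {}
    for ppool, n_p, coef, factors, rid, d in jobs:
        for qpool, positions, dest in factors:
            if qpool in offsets and (qpool, positions) not in ops:
                nq = model.pools[qpool].n_carbons
                ops[(qpool, positions)] = _marginal_operator(nq, positions)

    cons = {p.name: 0.0 for p in pools}
    for rxn in model.reactions:
        for d in ("f", "b") if rxn.reversible else ("f",):
            phi = dirflux(rxn, d)
            _, reac, _ = _directional_variants(rxn, d)[0]
            for qpool, _ in reac:
                if qpool in cons:
                    cons[qpool] += phi

    def rhs(x, t):
        dx = np.zeros(nx)
        for p in pools:
            o = offsets[p.name]
            dim = 2 ** p.n_carbons
            dx[o:o + dim] -= (cons[p.name] / state.pools[p.name]) * x[o:o + dim]
        for ppool, n_p, coef, factors, rid, d in jobs:
            if coef == 0.0:
                continue
            o = offsets[ppool]
            # marginal pattern distributions per reactant
            margs = []
            for qpool, positions, dest in factors:
                if qpool in offsets:
                    oq = offsets[qpool]
                    nq = model.pools[qpool].n_carbons
                    vec = ops[(qpool, positions)] @ x[oq:oq + 2 ** nq]
                else:
                    mid = sub_mid(qpool, t)
                    iso = _source_isotopomers(mid, len(mid) - 1)
                    vec = _marginal_operator(len(mid) - 1, positions) @ iso
                margs.append((vec, dest))
            for b in range(2 ** n_p):
                prob = 1.0
                for vec, dest in margs:
                    pat = 0
                    for j, dpos in enumerate(dest):
                        if b >> dpos & 1:
                            pat |= 1 << j
                    prob *= vec[pat]
                    if prob == 0.0:
                        break
                if prob:
                    dx[o + b] += coef * prob
        return dx

    x0 = np.zeros(nx)
    for p in pools:
        x0[offsets[p.name]] = 1.0
    t_eval = times if times[0] == 0 else np.concatenate([[0.0], times])
    sol = odeint(rhs, x0, t_eval, rtol=rtol, atol=atol, mxstep=50000)
    if times[0] != 0:
        sol = sol[1:]

    out = {}
    for pool in target_pools:
        n = model.pools[pool].n_carbons
        o = offsets[pool]
        mids = np.zeros((len(times), n + 1))
        for iso in range(2 ** n):
            mids[:, bin(iso).count("1")] += sol[:, o + iso]
        out[pool] = mids
    return out
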
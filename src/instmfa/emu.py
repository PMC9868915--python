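"""Elementary-metabolite-unit (EMU) decomposition and MID time-course simulation.

An EMU is a specific subset of a metabolite's carbon atoms.  Starting from the
measured fragments, the network is traced backwards through the atom maps so
that only the EMUs that can influence a measurement are simulated.  EMUs of
size k obey a linear balance

    P dX/dt = A(v) X + B(v) Y

where ``P`` holds the pool sizes, ``X`` stacks the MID vectors of the size-k
EMUs, and ``Y`` collects inputs: substrate EMUs and Cauchy-product
convolutions of strictly smaller EMUs (condensation reactions).  The cascade
is block-triangular in EMU size, so the whole system is integrated as one
stacked ODE; isotopic steady state is solved level by level as a linear
system.

Reversible reactions enter as a bidirectional pair: forward flux
``exchange + max(net, 0)``, backward flux ``exchange + max(-net, 0)``.
Substrate MIDs may be time-dependent (callables of t in minutes) to model
delayed or distributed tracer arrival.  Substrate isotopomers are assumed
position-exchangeable (a mixture of uniformly labelled and unlabelled
species, the [13C6]glucose case), so a subset EMU of a source pool carries
the hypergeometric marginal of the molecular MID.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import odeint
from scipy.special import comb

from .network import NetworkModel, FluxState

try:  # optional speed-up; the numpy path is the reference implementation
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "EMU",
    "EMUNetwork",
    "decompose",
    "simulate_timecourse",
    "simulate_steady_state",
    "subset_mid",
]


@dataclass(frozen=True)
class EMU:
    pool: str
    atoms: tuple  # sorted, 1-based carbon indices

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __repr__(self):
        return f"{self.pool}{{{','.join(map(str, self.atoms))}}}"


@dataclass(frozen=True)
class ProductionTerm:
    """One flux route into an EMU: ``weight * dirflux(rxn, direction)`` times
    the convolution of ``parts`` (state EMUs and/or source-pool EMUs)."""

    rxn_id: str
    direction: str  # "f" or "b"
    weight: float
    parts: tuple    # of ("x", EMU) or ("s", pool_name, size)


@lru_cache(maxsize=None)
def _marginal_matrix(n: int, k: int) -> np.ndarray:
    """M[j, i] = P(j of k sampled atoms labelled | i of n labelled)."""
    M = np.zeros((k + 1, n + 1))
    for i in range(n + 1):
        for j in range(max(0, k - (n - i)), min(i, k) + 1):
            M[j, i] = comb(i, j) * comb(n - i, k - j) / comb(n, k)
    return M


def subset_mid(mol_mid: np.ndarray, k: int) -> np.ndarray:
    """MID of a k-atom subset of a position-exchangeable molecular MID."""
    mol_mid = np.asarray(mol_mid, dtype=float)
    return _marginal_matrix(len(mol_mid) - 1, k) @ mol_mid


class EMUNetwork:
    """Minimal EMU set feeding a list of target pools, with its transitions."""

    def __init__(self, model, target_pools, emus, production, consumption,
                 input_pools):
        self.model = model
        self.target_pools = list(target_pools)
        self.emus = emus                      # size-ascending list of state EMUs
        self.index = {e: i for i, e in enumerate(emus)}
        self.production = production          # EMU -> [ProductionTerm]
        self.consumption = consumption        # EMU -> [(rxn_id, dir, count)]
        self.input_pools = input_pools        # pools whose MIDs are inputs
        self.offsets = {}
        off = 0
        for e in emus:
            self.offsets[e] = off
            off += e.size + 1
        self.n_state = off

    @property
    def sizes(self):
        return sorted({e.size for e in self.emus})

    def emus_of_size(self, k):
        return [e for e in self.emus if e.size == k]


def _directional_variants(rxn, direction):
    """Variants with (reactants, products) oriented along the flux direction."""
    if direction == "f":
        return [(v.weight, v.reactants, v.products) for v in rxn.variants]
    return [(v.weight, v.products, v.reactants) for v in rxn.variants]


def decompose(model: NetworkModel, targets, fixed_pools=()) -> EMUNetwork:
    """Trace the EMUs required to simulate ``targets`` back to the substrates.

    ``targets`` may name measurement groups or pools; each target pool's
    full-carbon EMU is the root of the trace.  ``fixed_pools`` are treated as
    known-composition inputs (e.g. a fixed-enrichment CO2 mode) instead of
    being simulated.
    """
    fixed_pools = set(fixed_pools)
    target_pools = []
    for t in targets:
        if t in model.measurements:
            target_pools.extend(model.measurements[t].pools)
        elif t in model.pools:
            target_pools.append(t)
        else:
            raise KeyError(f"unknown target {t!r}")
    target_pools = list(dict.fromkeys(target_pools))

    def is_input(pool_name):
        return model.pools[pool_name].source or pool_name in fixed_pools

    production, consumption = {}, {}
    todo = [EMU(p, tuple(range(1, model.pools[p].n_carbons + 1)))
            for p in target_pools]
    seen = set(todo)
    while todo:
        emu = todo.pop()
        terms = {}
        for rxn in model.reactions:
            for direction in ("f", "b") if rxn.reversible else ("f",):
                for weight, reac, prod in _directional_variants(rxn, direction):
                    for ppool, pmap in prod:
                        if ppool != emu.pool:
                            continue
                        letters = {pmap[a - 1] for a in emu.atoms}
                        parts = []
                        for qpool, qmap in reac:
                            atoms = tuple(i + 1 for i, ch in enumerate(qmap)
                                          if ch in letters)
                            if atoms:
                                parts.append((qpool, atoms))
                        parts = tuple(sorted(parts))
                        key = (rxn.id, direction, parts)
                        terms[key] = terms.get(key, 0.0) + weight
        plist = []
        for (rid, direction, parts), w in sorted(terms.items()):
            refs = []
            for qpool, atoms in parts:
                if is_input(qpool):
                    refs.append(("s", qpool, len(atoms)))
                else:
                    child = EMU(qpool, atoms)
                    refs.append(("x", child))
                    if child not in seen:
                        seen.add(child)
                        todo.append(child)
            plist.append(ProductionTerm(rid, direction, w, tuple(refs)))
        production[emu] = plist

        clist = []
        for rxn in model.reactions:
            for direction in ("f", "b") if rxn.reversible else ("f",):
                _, reac, _ = _directional_variants(rxn, direction)[0]
                count = sum(1 for qpool, _ in reac if qpool == emu.pool)
                if count:
                    clist.append((rxn.id, direction, count))
        consumption[emu] = clist
        if not plist and not model.pools[emu.pool].source:
            raise ValueError(f"EMU {emu} has no producing reaction "
                             "(disconnected from every substrate)")

    emus = sorted(seen, key=lambda e: (e.size, e.pool, e.atoms))
    input_pools = sorted({ref[1] for plist in production.values()
                          for t in plist for ref in t.parts if ref[0] == "s"})
    net = EMUNetwork(model, target_pools, emus, production, consumption,
                     input_pools)
    _check_reachability(net)
    return net


def _check_reachability(net: EMUNetwork):
    labelled_sources = {p for p in net.input_pools
                        if not net.model.pools[p].unlabelled}
    reach = set()
    changed = True
    while changed:
        changed = False
        for emu in net.emus:
            if emu in reach:
                continue
            for term in net.production[emu]:
                ok = any((r[0] == "s" and r[1] in labelled_sources)
                         or (r[0] == "x" and r[1] in reach)
                         for r in term.parts)
                if ok:
                    reach.add(emu)
                    changed = True
                    break
    for pool in net.target_pools:
        root = EMU(pool, tuple(range(1, net.model.pools[pool].n_carbons + 1)))
        if root not in reach:
            raise ValueError(
                f"target {pool} is unreachable from any labelled substrate")


# -- compiled ODE system -------------------------------------------------

class CompiledSystem:
    """Numeric stacked ODE for one EMU network at one flux state."""

    def __init__(self, net: EMUNetwork, state: FluxState, substrates=None):
        model = net.model
        self.net = net
        subs = dict(substrates or {})
        self._sub_funcs = {}
        for pool in net.input_pools:
            spec = subs.get(pool, None)
            if spec is None:
                spec = model.substrate_mid(pool) if (
                    pool in model.substrates or model.pools[pool].unlabelled
                ) else None
                if spec is None:
                    raise ValueError(f"no MID supplied for input pool {pool}")
            self._sub_funcs[pool] = spec  # array or callable(t)->array
        self.time_dependent = any(callable(f) for f in self._sub_funcs.values())

        nx = net.n_state
        A = np.zeros((nx, nx))
        c = np.zeros(nx)
        conv_terms = []   # (out_off, coef, [refs]) with >=2 parts or dynamic
        rxn_index = model.reaction_index

        def dirflux(rid, direction):
            rxn = rxn_index[rid]
            return state.forward(rxn) if direction == "f" else state.backward(rxn)

        for emu in net.emus:
            off = net.offsets[emu]
            dim = emu.size + 1
            P = state.pools[emu.pool]
            if P <= 0:
                raise ValueError(f"pool size for {emu.pool} must be positive")
            cons = sum(dirflux(rid, d) * cnt
                       for rid, d, cnt in net.consumption[emu])
            A[off:off + dim, off:off + dim] -= (cons / P) * np.eye(dim)
            for term in net.production[emu]:
                coef = term.weight * dirflux(term.rxn_id, term.direction) / P
                if coef == 0.0:
                    continue
                state_parts = [r for r in term.parts if r[0] == "x"]
                dyn = any(r[0] == "s" and callable(self._sub_funcs[r[1]])
                          for r in term.parts)
                if not dyn and not state_parts:
                    vec = self._static_conv(term.parts, t=None)
                    c[off:off + dim] += coef * vec
                elif not dyn and len(term.parts) == 1:
                    src = term.parts[0][1]
                    so = net.offsets[src]
                    A[off:off + dim, so:so + src.size + 1] += coef * np.eye(dim)
                else:
                    conv_terms.append((off, dim, coef, term.parts))
        self.A, self.c, self.conv_terms = A, c, conv_terms
        self.x0 = np.zeros(nx)
        for emu in net.emus:
            self.x0[net.offsets[emu]] = 1.0
        self._build_fast_path()

    # part evaluation ----------------------------------------------------

    def _source_mid(self, pool, size, t):
        f = self._sub_funcs[pool]
        mol = f(t) if callable(f) else f
        mol = np.asarray(mol, dtype=float)
        if size == len(mol) - 1:
            return mol
        return subset_mid(mol, size)

    def _static_conv(self, parts, t):
        vec = None
        for ref in parts:
            v = self._source_mid(ref[1], ref[2], t)
            vec = v if vec is None else np.convolve(vec, v)
        return vec

    def rhs(self, x, t):
        out = self.A @ x + self.c
        for off, dim, coef, parts in self.conv_terms:
            vec = None
            for ref in parts:
                if ref[0] == "x":
                    src = ref[1]
                    so = self.net.offsets[src]
                    v = x[so:so + src.size + 1]
                else:
                    v = self._source_mid(ref[1], ref[2], t)
                vec = v if vec is None else np.convolve(vec, v)
            out[off:off + dim] += coef * (vec if vec is not None else 0.0)
        return out

    # numba fast path ----------------------------------------------------

    def _build_fast_path(self):
        self._fast = None
        if not _HAVE_NUMBA or self.time_dependent:
            return
        # flatten convolution terms into integer metadata
        meta, pk, po, pl = [], [], [], []
        srcbuf = []
        src_off = {}
        for off, dim, coef, parts in self.conv_terms:
            meta.append((off, dim, coef, len(parts)))
            for ref in parts:
                if ref[0] == "x":
                    src = ref[1]
                    pk.append(0)
                    po.append(self.net.offsets[src])
                    pl.append(src.size + 1)
                else:
                    key = (ref[1], ref[2])
                    if key not in src_off:
                        vec = self._source_mid(ref[1], ref[2], 0.0)
                        src_off[key] = len(srcbuf)
                        srcbuf.extend(vec)
                    pk.append(1)
                    po.append(src_off[key])
                    pl.append(ref[2] + 1)
        if meta:
            tmeta = np.array([(m[0], m[1], m[3]) for m in meta], dtype=np.int64)
            tcoef = np.array([m[2] for m in meta])
        else:
            tmeta = np.zeros((0, 3), dtype=np.int64)
            tcoef = np.zeros(0)
        self._fast = (
            tmeta, tcoef,
            np.array(pk, dtype=np.int64), np.array(po, dtype=np.int64),
            np.array(pl, dtype=np.int64),
            np.array(srcbuf, dtype=float) if srcbuf else np.zeros(1),
            np.zeros(self.net.n_state + 8),
            np.zeros(self.net.n_state + 8),
        )
        self._jbuf = np.zeros((self.net.n_state, self.net.n_state))

    def fast_rhs(self, x, t):
        tmeta, tcoef, pk, po, pl, srcbuf, s1, s2 = self._fast
        return _rhs_fast(x, self.A, self.c, tmeta, tcoef, pk, po, pl,
                         srcbuf, s1, s2)

    def fast_jac(self, x, t):
        """Analytic state Jacobian: A plus the bilinear convolution terms."""
        tmeta, tcoef, pk, po, pl, srcbuf, s1, s2 = self._fast
        return _jac_fast(x, self.A, tmeta, tcoef, pk, po, pl, srcbuf,
                         s1, s2, self._jbuf)


if _HAVE_NUMBA:
    @_njit(cache=True)
    def _rhs_fast(x, A, c, tmeta, tcoef, pk, po, pl, srcbuf, s1, s2):
        out = A @ x + c
        ip = 0
        for k in range(tmeta.shape[0]):
            off = tmeta[k, 0]
            dim = tmeta[k, 1]
            npart = tmeta[k, 2]
            # first part
            ln = pl[ip]
            if pk[ip] == 0:
                for i in range(ln):
                    s1[i] = x[po[ip] + i]
            else:
                for i in range(ln):
                    s1[i] = srcbuf[po[ip] + i]
            cur = ln
            ip += 1
            for _ in range(npart - 1):
                ln = pl[ip]
                new = cur + ln - 1
                for i in range(new):
                    s2[i] = 0.0
                if pk[ip] == 0:
                    for i in range(cur):
                        xi = s1[i]
                        for j in range(ln):
                            s2[i + j] += xi * x[po[ip] + j]
                else:
                    for i in range(cur):
                        xi = s1[i]
                        for j in range(ln):
                            s2[i + j] += xi * srcbuf[po[ip] + j]
                for i in range(new):
                    s1[i] = s2[i]
                cur = new
                ip += 1
            for i in range(dim):
                out[off + i] += tcoef[k] * s1[i]
        return out

    @_njit(cache=True)
    def _jac_fast(x, A, tmeta, tcoef, pk, po, pl, srcbuf, s1, s2, J):
        for i in range(A.shape[0]):
            for j in range(A.shape[1]):
                J[i, j] = A[i, j]
        ip = 0
        for k in range(tmeta.shape[0]):
            off = tmeta[k, 0]
            npart = tmeta[k, 2]
            for j in range(npart):
                if pk[ip + j] != 0:
                    continue
                # convolution of all parts except j
                cur = 0
                first = True
                for m in range(npart):
                    if m == j:
                        continue
                    ln = pl[ip + m]
                    if first:
                        if pk[ip + m] == 0:
                            for i in range(ln):
                                s1[i] = x[po[ip + m] + i]
                        else:
                            for i in range(ln):
                                s1[i] = srcbuf[po[ip + m] + i]
                        cur = ln
                        first = False
                    else:
                        new = cur + ln - 1
                        for i in range(new):
                            s2[i] = 0.0
                        for i in range(cur):
                            xi = s1[i]
                            if pk[ip + m] == 0:
                                for q in range(ln):
                                    s2[i + q] += xi * x[po[ip + m] + q]
                            else:
                                for q in range(ln):
                                    s2[i + q] += xi * srcbuf[po[ip + m] + q]
                        for i in range(new):
                            s1[i] = s2[i]
                        cur = new
                lnj = pl[ip + j]
                for i0 in range(cur):
                    v = tcoef[k] * s1[i0]
                    for i1 in range(lnj):
                        J[off + i0 + i1, po[ip + j] + i1] += v
            ip += npart
        return J


# -- public simulation API ------------------------------------------------

def _target_slices(net: EMUNetwork):
    out = {}
    for pool in net.target_pools:
        emu = EMU(pool, tuple(range(1, net.model.pools[pool].n_carbons + 1)))
        off = net.offsets[emu]
        out[pool] = (off, off + emu.size + 1)
    return out


def simulate_timecourse(net: EMUNetwork, state: FluxState, times,
                        substrates=None, rtol=1e-8, atol=1e-10,
                        system=None):
    """Integrate the EMU cascade and return target-pool MIDs over ``times``.

    Returns a dict ``pool -> array of shape (n_times, n_carbons + 1)``.  The
    initial condition is the fully unlabelled state.  ``substrates`` overrides
    the model's substrate MIDs per source pool (arrays or callables of time).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly increasing and start at >= 0")
    sys_ = system if system is not None else CompiledSystem(net, state, substrates)
    if sys_._fast is not None:
        func, jac = sys_.fast_rhs, sys_.fast_jac
    else:
        func, jac = sys_.rhs, None
    t_eval = times if times[0] == 0 else np.concatenate([[0.0], times])
    sol, info = odeint(func, sys_.x0, t_eval, Dfun=jac, rtol=rtol, atol=atol,
                       tfirst=False, mxstep=20000, full_output=True,
                       printmessg=False)
    if info["message"] != "Integration successful.":
        raise RuntimeError(
            f"stiff integration failed over EMU sizes {net.sizes}: "
            f"{info['message']}")
    if times[0] != 0:
        sol = sol[1:]
    out = {}
    for pool, (a, b) in _target_slices(net).items():
        mids = sol[:, a:b].copy()
        mids[(mids < 0) & (mids > -1e-9)] = 0.0  # integrator round-off only
        out[pool] = mids
    return out


def timecourse_frame(result: dict, times):
    """Tidy table (observable, time_min, isotopologue, fraction) from a
    :func:`simulate_timecourse` result; write with ``.to_csv(p, sep='\\t')``."""
    import pandas as pd

    rows = []
    for pool, mids in result.items():
        for t, mid in zip(np.asarray(times), mids):
            for k, frac in enumerate(mid):
                rows.append((pool, float(t), k, float(frac)))
    return pd.DataFrame(rows, columns=["observable", "time_min",
                                       "isotopologue", "fraction"])


def simulate_steady_state(net: EMUNetwork, state: FluxState, substrates=None):
    """Isotopic steady state: solve A(v) X = -B(v) Y level by level."""
    sys_ = CompiledSystem(net, state, substrates)
    t_inf = 1e12
    values = {}  # EMU -> mid

    def part_vec(ref):
        if ref[0] == "x":
            return values[ref[1]]
        return sys_._source_mid(ref[1], ref[2], t_inf)

    def dirflux(rid, d):
        rxn = net.model.reaction_index[rid]
        return state.forward(rxn) if d == "f" else state.backward(rxn)

    for k in net.sizes:
        emus = net.emus_of_size(k)
        idx = {e: i for i, e in enumerate(emus)}
        n = len(emus)
        A = np.zeros((n, n))
        B = np.zeros((n, k + 1))
        for e in emus:
            i = idx[e]
            A[i, i] -= sum(dirflux(rid, d) * cnt
                           for rid, d, cnt in net.consumption[e])
            for term in net.production[e]:
                phi = term.weight * dirflux(term.rxn_id, term.direction)
                if phi == 0.0:
                    continue
                same = [r for r in term.parts
                        if r[0] == "x" and r[1].size == k]
                if len(term.parts) == 1 and same:
                    A[i, idx[same[0][1]]] += phi
                else:
                    vec = None
                    for ref in term.parts:
                        v = part_vec(ref)
                        vec = v if vec is None else np.convolve(vec, v)
                    B[i] += phi * vec
        try:
            X = np.linalg.solve(A, -B)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"singular EMU balance at size {k}: a flux cycle with zero "
                "throughput leaves these EMUs undetermined") from None
        for e in emus:
            values[e] = X[idx[e]]
    return {pool: values[EMU(pool, tuple(range(1, net.model.pools[pool].n_carbons + 1)))]
            for pool in net.target_pools}
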
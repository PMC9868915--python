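"""Compartmented atom-transition networks for 13C flux analysis.

A network couples metabolite pools (with compartment tags and carbon counts)
through reactions whose atom maps give the one-to-one carbon correspondences
between substrates and products.  The module owns the plain-text model format,
its validation, the steady-state stoichiometric parameterization of net
fluxes, and the mapping from internal pools to observable measurements
(extraction mixing of subcellular pools, dilution by pre-existing unlabelled
material).

Model text format (one directive per line, ``#`` starts a comment)::

    pool G6P.c 6                  # name (compartment = suffix after '.'), carbons
    pool GLC.ext 6 source         # unbalanced input; needs a substrate line
    pool GLC.v 6 source unlabelled
    pool SUCC.m 4 symmetric       # rotationally symmetric molecule
    pool CO2.eff 1 sink           # unbalanced output
    rxn upt: GLC.ext (abcdef) -> G6P.c (abcdef)
    rxn ana1: PEP.c (abc) + CO2 (d) <-> MAL.m (abcd)
    rxn tca: AcCoA (ab) + MAL (cdef) -> MAL (edba|abde) + CO2 (c) + CO2 (f)
    fix upt 1.0
    substrate GLC.ext 0.4 0 0 0 0 0 0.6
    measure MAL: MAL.m + MAL.c unlabelled

Atom maps use lowercase letters; every letter appears exactly once on each
side of a reaction.  ``(x|y)`` gives equal-weight alternative maps for one
molecule (used for scrambling through symmetric intermediates that are not
modelled explicitly); pools flagged ``symmetric`` are scrambled automatically.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "MetabolitePool",
    "AtomTransitionReaction",
    "MeasurementGroup",
    "FluxState",
    "NetworkModel",
    "ModelSyntaxError",
    "parse_model",
    "load_model",
    "serialize_model",
    "stoichiometry_matrix",
    "FluxParameterization",
    "compose_observable",
]


class ModelSyntaxError(ValueError):
    """Raised for malformed model documents; carries the offending line number."""

    def __init__(self, message, line_no=None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


@dataclass(frozen=True)
class MetabolitePool:
    name: str
    n_carbons: int
    source: bool = False        # unbalanced input (substrate or pre-existing store)
    sink: bool = False          # unbalanced output (biomass, CO2 efflux)
    unlabelled: bool = False    # source held at the all-M0 composition
    symmetric: bool = False     # rotationally symmetric carbon skeleton

    @property
    def compartment(self) -> str:
        return self.name.rsplit(".", 1)[1] if "." in self.name else ""

    @property
    def balanced(self) -> bool:
        return not (self.source or self.sink)

    def __post_init__(self):
        if self.n_carbons < 1:
            raise ValueError(f"pool {self.name}: n_carbons must be >= 1")


@dataclass(frozen=True)
class ReactionVariant:
    """One fully-resolved atom mapping of a reaction (weights sum to 1)."""

    weight: float
    reactants: tuple  # ((pool_name, letters), ...)
    products: tuple


@dataclass
class AtomTransitionReaction:
    id: str
    reactants: list  # [(pool_name, [map, ...alternates]), ...]
    products: list
    reversible: bool = False
    pseudo: bool = False
    rxn_class: str = ""
    variants: tuple = field(default_factory=tuple)  # filled by the model

    def side_pools(self, side: str):
        return [p for p, _ in (self.reactants if side == "r" else self.products)]


@dataclass
class MeasurementGroup:
    """An observable: a convex mixture of pools plus an unlabelled fraction.

    Extraction mixes subcellular pools of the same metabolite, and pre-existing
    metabolically inactive material dilutes the labelled signal; both are
    fitted (weights live on the simplex together with ``unlabelled_fraction``).
    """

    name: str
    pools: list
    weights: np.ndarray = None
    unlabelled_fraction: float = 0.0
    fit_unlabelled: bool = False

    def __post_init__(self):
        if self.weights is None:
            self.weights = np.full(len(self.pools), 1.0 / len(self.pools))
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n_mix_params(self) -> int:
        """Free simplex parameters (weights + optional unlabelled fraction)."""
        k = len(self.pools) + (1 if self.fit_unlabelled else 0)
        return k - 1


@dataclass
class FluxState:
    """Net/exchange fluxes (relative molar units, substrate uptake = 1) and pool sizes."""

    net: dict
    exchange: dict = field(default_factory=dict)
    pools: dict = field(default_factory=dict)

    def forward(self, rxn: AtomTransitionReaction) -> float:
        v = self.net[rxn.id]
        if not rxn.reversible:
            return max(v, 0.0)
        return self.exchange.get(rxn.id, 0.0) + max(v, 0.0)

    def backward(self, rxn: AtomTransitionReaction) -> float:
        if not rxn.reversible:
            return 0.0
        return self.exchange.get(rxn.id, 0.0) + max(-self.net[rxn.id], 0.0)

    def validate(self, model: "NetworkModel", tol: float = 1e-9) -> None:
        for rxn in model.reactions:
            if not rxn.reversible and self.net[rxn.id] < -tol:
                raise ValueError(f"irreversible reaction {rxn.id} has negative net flux")
            if rxn.reversible and self.exchange.get(rxn.id, 0.0) < -tol:
                raise ValueError(f"reaction {rxn.id} has negative exchange flux")
        S, bal, rids = stoichiometry_matrix(model)
        v = np.array([self.net[r] for r in rids])
        resid = S @ v
        if bal and np.max(np.abs(resid)) > tol:
            i = int(np.argmax(np.abs(resid)))
            raise ValueError(
                f"pool {bal[i]} not balanced: net production {resid[i]:.3g}"
            )
        for name, size in self.pools.items():
            if size <= 0:
                raise ValueError(f"pool size for {name} must be positive")


class NetworkModel:
    """A validated atom-transition network."""

    def __init__(self, pools, reactions, substrates, measurements, fixed_fluxes):
        self.pools: dict = pools
        self.reactions: list = reactions
        self.reaction_index = {r.id: r for r in reactions}
        self.substrates: dict = substrates          # pool name -> MID array
        self.measurements: dict = measurements      # name -> MeasurementGroup
        self.fixed_fluxes: dict = fixed_fluxes      # reaction id -> value
        self._validate()
        for rxn in self.reactions:
            rxn.variants = self._expand_variants(rxn)

    # -- validation -----------------------------------------------------

    def _validate(self):
        seen = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ModelSyntaxError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            self._check_maps(rxn)
        for name, mid in self.substrates.items():
            pool = self._pool(name)
            if not pool.source:
                raise ModelSyntaxError(f"substrate {name} is not a source pool")
            if len(mid) != pool.n_carbons + 1:
                raise ModelSyntaxError(
                    f"substrate MID for {name} has {len(mid)} entries, "
                    f"expected {pool.n_carbons + 1}"
                )
        for p in self.pools.values():
            if p.source and not p.unlabelled and p.name not in self.substrates:
                raise ModelSyntaxError(
                    f"source pool {p.name} needs a substrate MID or 'unlabelled' flag"
                )
        for grp in self.measurements.values():
            ncs = {self._pool(p).n_carbons for p in grp.pools}
            if len(ncs) > 1:
                raise ModelSyntaxError(
                    f"measurement {grp.name}: contributing pools differ in carbon count"
                )

    def _pool(self, name: str) -> MetabolitePool:
        try:
            return self.pools[name]
        except KeyError:
            raise ModelSyntaxError(f"unknown pool {name!r}") from None

    def _check_maps(self, rxn: AtomTransitionReaction):
        def letters(side):
            out = []
            for pool_name, maps in side:
                pool = self._pool(pool_name)
                for m in maps:
                    if len(m) != pool.n_carbons:
                        raise ModelSyntaxError(
                            f"reaction {rxn.id}: atom map '{m}' for {pool_name} has "
                            f"{len(m)} atoms, pool declares {pool.n_carbons}"
                        )
                    if sorted(m) != sorted(maps[0]):
                        raise ModelSyntaxError(
                            f"reaction {rxn.id}: alternate maps for {pool_name} "
                            "must use the same letters"
                        )
                out.extend(maps[0])
            return out

        lhs, rhs = letters(rxn.reactants), letters(rxn.products)
        if len(set(lhs)) != len(lhs) or len(set(rhs)) != len(rhs):
            raise ModelSyntaxError(
                f"reaction {rxn.id}: atom-map letters must be unique per side"
            )
        if sorted(lhs) != sorted(rhs):
            raise ModelSyntaxError(
                f"reaction {rxn.id}: carbon not conserved "
                f"(reactant letters {''.join(sorted(lhs))} != "
                f"product letters {''.join(sorted(rhs))})"
            )

    # -- variant expansion ----------------------------------------------

    def _expand_variants(self, rxn: AtomTransitionReaction):
        """Resolve alternate maps and symmetric-pool scrambling into
        an equal-weight list of fully determined atom mappings."""
        variants = [(1.0, [("r", p, m[0]) for p, m in rxn.reactants]
                     + [("p", p, m[0]) for p, m in rxn.products])]
        # explicit alternates
        for side, entries in (("r", rxn.reactants), ("p", rxn.products)):
            for occ, (pool_name, maps) in enumerate(entries):
                if len(maps) == 1:
                    continue
                new = []
                for w, mol in variants:
                    for alt in maps:
                        mol2 = list(mol)
                        mol2[self._occ_index(mol, side, occ, entries)] = (
                            side, pool_name, alt)
                        new.append((w / len(maps), mol2))
                variants = new
        # symmetric pools: average identity and reversed orientation
        for idx in range(len(variants[0][1])):
            side, pool_name, _ = variants[0][1][idx]
            if not self._pool(pool_name).symmetric:
                continue
            new = []
            for w, mol in variants:
                rev = list(mol)
                s, p, m = rev[idx]
                rev[idx] = (s, p, m[::-1])
                new.append((w / 2, mol))
                new.append((w / 2, rev))
            variants = new
        out = []
        for w, mol in variants:
            reac = tuple((p, m) for s, p, m in mol if s == "r")
            prod = tuple((p, m) for s, p, m in mol if s == "p")
            out.append(ReactionVariant(w, reac, prod))
        return tuple(out)

    @staticmethod
    def _occ_index(mol, side, occ, entries):
        # index into the flat variant list of the occ-th entry of this side
        offset = 0 if side == "r" else sum(1 for s, _, _ in mol if s == "r")
        return offset + occ

    # -- convenience -----------------------------------------------------

    @property
    def balanced_pools(self):
        return [p.name for p in self.pools.values() if p.balanced]

    def substrate_mid(self, pool_name: str) -> np.ndarray:
        pool = self._pool(pool_name)
        if pool_name in self.substrates:
            return np.asarray(self.substrates[pool_name], dtype=float)
        mid = np.zeros(pool.n_carbons + 1)
        mid[0] = 1.0
        return mid


# -- parsing -------------------------------------------------------------

_RXN_RE = re.compile(r"^rxn\s+(\S+?):\s*(.+)$")
_MOL_RE = re.compile(r"^(\S+)\s*\(([a-z|]*)\)$")


def _parse_side(text, rxn_id, line_no):
    out = []
    for part in text.split("+"):
        part = part.strip()
        m = _MOL_RE.match(part)
        if not m:
            raise ModelSyntaxError(
                f"reaction {rxn_id}: cannot parse molecule {part!r}", line_no)
        maps = m.group(2).split("|") if m.group(2) else [""]
        out.append((m.group(1), maps))
    return out


def parse_model(text: str) -> NetworkModel:
    """Parse a model-definition document into a validated :class:`NetworkModel`."""
    pools, reactions, substrates, measurements, fixed = {}, [], {}, {}, {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            head, rest = line.split(None, 1)
        except ValueError:
            raise ModelSyntaxError(f"cannot parse {line!r}", line_no)
        try:
            if head == "pool":
                toks = rest.split()
                name, n_carbons, flags = toks[0], int(toks[1]), set(toks[2:])
                bad = flags - {"source", "sink", "unlabelled", "symmetric"}
                if bad:
                    raise ModelSyntaxError(f"unknown pool flag(s) {sorted(bad)}", line_no)
                if name in pools:
                    raise ModelSyntaxError(f"duplicate pool {name!r}", line_no)
                pools[name] = MetabolitePool(
                    name, n_carbons,
                    source="source" in flags, sink="sink" in flags,
                    unlabelled="unlabelled" in flags, symmetric="symmetric" in flags)
            elif head == "rxn":
                m = _RXN_RE.match(line)
                if not m:
                    raise ModelSyntaxError("cannot parse reaction", line_no)
                rid, body = m.groups()
                flags = {"pseudo": False, "class": ""}
                toks = body.split()
                while toks and (toks[-1] == "pseudo" or toks[-1].startswith("class=")):
                    t = toks.pop()
                    if t == "pseudo":
                        flags["pseudo"] = True
                    else:
                        flags["class"] = t.split("=", 1)[1]
                body = " ".join(toks)
                if "<->" in body:
                    lhs, rhs = body.split("<->")
                    rev = True
                elif "->" in body:
                    lhs, rhs = body.split("->")
                    rev = False
                else:
                    raise ModelSyntaxError(f"reaction {rid}: missing arrow", line_no)
                reactions.append(AtomTransitionReaction(
                    rid,
                    _parse_side(lhs, rid, line_no), _parse_side(rhs, rid, line_no),
                    reversible=rev, pseudo=flags["pseudo"], rxn_class=flags["class"]))
            elif head == "substrate":
                toks = rest.split()
                substrates[toks[0]] = np.array([float(t) for t in toks[1:]])
            elif head == "fix":
                toks = rest.split()
                fixed[toks[0]] = float(toks[1])
            elif head == "measure":
                name, body = rest.split(":", 1)
                toks = body.split()
                fit_unlab = "unlabelled" in toks
                pool_names = [t for t in toks if t not in {"+", "unlabelled"}]
                measurements[name.strip()] = MeasurementGroup(
                    name.strip(), pool_names, fit_unlabelled=fit_unlab)
            else:
                raise ModelSyntaxError(f"unknown directive {head!r}", line_no)
        except ModelSyntaxError:
            raise
        except (ValueError, IndexError) as exc:
            raise ModelSyntaxError(str(exc), line_no) from exc
    return NetworkModel(pools, reactions, substrates, measurements, fixed)


def load_model(path) -> NetworkModel:
    with open(path) as fh:
        return parse_model(fh.read())


def serialize_model(model: NetworkModel) -> str:
    """Write a model back to the text format (round-trips through parse_model)."""
    buf = io.StringIO()
    for p in model.pools.values():
        flags = [f for f, on in (("source", p.source), ("sink", p.sink),
                                 ("unlabelled", p.unlabelled),
                                 ("symmetric", p.symmetric)) if on]
        buf.write(" ".join(["pool", p.name, str(p.n_carbons)] + flags) + "\n")
    for r in model.reactions:
        def side(entries):
            return " + ".join(f"{p} ({'|'.join(maps)})" for p, maps in entries)
        arrow = "<->" if r.reversible else "->"
        tail = (" pseudo" if r.pseudo else "") + (
            f" class={r.rxn_class}" if r.rxn_class else "")
        buf.write(f"rxn {r.id}: {side(r.reactants)} {arrow} {side(r.products)}{tail}\n")
    for name, mid in model.substrates.items():
        buf.write("substrate " + name + " " + " ".join(f"{x:g}" for x in mid) + "\n")
    for rid, val in model.fixed_fluxes.items():
        buf.write(f"fix {rid} {val:g}\n")
    for g in model.measurements.values():
        tail = " unlabelled" if g.fit_unlabelled else ""
        buf.write(f"measure {g.name}: " + " + ".join(g.pools) + tail + "\n")
    return buf.getvalue()


# -- stoichiometry and flux parameterization ------------------------------

def stoichiometry_matrix(model: NetworkModel):
    """Net stoichiometric matrix over balanced pools.

    Returns ``(S, balanced_pool_names, reaction_ids)`` with
    ``S[i, j]`` = net molecules of pool i made by unit net flux of reaction j.
    """
    bal = model.balanced_pools
    row = {name: i for i, name in enumerate(bal)}
    rids = [r.id for r in model.reactions]
    S = np.zeros((len(bal), len(rids)))
    for j, rxn in enumerate(model.reactions):
        for pool_name, _ in rxn.products:
            if pool_name in row:
                S[row[pool_name], j] += 1.0
        for pool_name, _ in rxn.reactants:
            if pool_name in row:
                S[row[pool_name], j] -= 1.0
    return S, bal, rids


def stoichiometry_frame(model: NetworkModel):
    """Stoichiometry as a labelled table (balanced pools x reactions), for
    inspection or TSV export via ``.to_csv(path, sep='\\t')``."""
    import pandas as pd

    S, bal, rids = stoichiometry_matrix(model)
    return pd.DataFrame(S, index=bal, columns=rids)


class FluxParameterization:
    """Invertible mapping between free net fluxes and the full balanced flux vector.

    Fixed fluxes (e.g. substrate uptake pinned at 1, the flux normalization of
    the relative units) are removed from the unknowns; QR with column pivoting
    on the remaining stoichiometry picks a well-conditioned dependent set, and
    the null-space dimension gives the number of free net fluxes.
    """

    def __init__(self, model: NetworkModel):
        self.model = model
        S, bal, rids = stoichiometry_matrix(model)
        self.reaction_ids = rids
        self.fixed = dict(model.fixed_fluxes)
        unknown = [j for j, r in enumerate(rids) if r not in self.fixed]
        self._unknown = unknown
        Su = S[:, unknown]
        if Su.size == 0:
            # no balance constraints: every unknown net flux is free
            self._rank = 0
            self._free = list(unknown)
            self.free_ids = [rids[j] for j in unknown]
        else:
            q, r, piv = scipy.linalg.qr(Su, pivoting=True)
            tol = max(Su.shape) * np.finfo(float).eps * (
                abs(r[0, 0]) if r.size else 0.0)
            rank = int(np.sum(np.abs(np.diag(r)) > max(tol, 1e-12)))
            self._rank = rank
            dep_cols = piv[:rank]
            free_cols = piv[rank:]
            self._dep = [unknown[j] for j in dep_cols]
            self._free = [unknown[j] for j in sorted(free_cols)]
            self.free_ids = [rids[j] for j in self._free]
            self._Sd = Su[:, dep_cols]
            self._Sf = S[:, self._free]
            fixed_vec = np.array([self.fixed.get(r, 0.0) for r in rids])
            self._b_fixed = S @ fixed_vec
        self.reversible_ids = [r.id for r in model.reactions if r.reversible]
        if len(unknown) == 0:
            raise ValueError(
                "over-determined constraint set: every net flux is fixed")

    @property
    def n_free(self) -> int:
        return len(self.free_ids)

    def full_net(self, free_values) -> dict:
        """Expand free net fluxes to the full net-flux mapping (balance holds
        to machine precision for every balanced pool)."""
        free_values = np.asarray(free_values, dtype=float)
        if free_values.shape != (self.n_free,):
            raise ValueError("wrong number of free flux values")
        v = {rid: self.fixed.get(rid, 0.0) for rid in self.reaction_ids}
        for rid, val in zip(self.free_ids, free_values):
            v[rid] = val
        if self._rank:
            b = -(self._b_fixed + self._Sf @ free_values)
            dep_vals, *_ = np.linalg.lstsq(self._Sd, b, rcond=None)
            for j, val in zip(self._dep, dep_vals):
                v[self.reaction_ids[j]] = val
        return v

    def free_from_full(self, net: dict) -> np.ndarray:
        return np.array([net[rid] for rid in self.free_ids])

    def flux_state(self, free_net, exchange=None, pools=None) -> FluxState:
        return FluxState(self.full_net(free_net), dict(exchange or {}),
                         dict(pools or {}))


def compose_observable(group: MeasurementGroup, pool_mids: dict,
                       weights=None, unlabelled_fraction=None) -> np.ndarray:
    """Mix simulated pool MIDs into the observable the instrument sees.

    ``weights`` over contributing pools plus ``unlabelled_fraction`` (times the
    all-M0 vector) form a simplex, so the output still sums to one.
    """
    w = np.asarray(group.weights if weights is None else weights, dtype=float)
    u = group.unlabelled_fraction if unlabelled_fraction is None else unlabelled_fraction
    mids = [np.asarray(pool_mids[p], dtype=float) for p in group.pools]
    n = len(mids[0])
    if any(len(m) != n for m in mids):
        raise ValueError(f"measurement {group.name}: carbon-count mismatch")
    out = np.zeros(n)
    for wi, mi in zip(w, mids):
        out += wi * mi
    out[0] += u
    return out
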
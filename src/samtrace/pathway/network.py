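"""Moiety-resolved label-propagation network.

The SAM transmethylation pathway moves three carbon units between metabolite
pools: the methyl carbon of methionine (1 C), the homocysteinyl backbone
(4 C), and the adenosyl group contributed by ATP (5 C).  Tracking which of
these moieties carries the :sup:`13`\\ C label -- rather than full positional
isotopomers -- reproduces every mass-shift class (m+0 ... m+5) that an LC-MS
isotopologue readout of this pathway can show, while keeping the state tiny:
a pool with *k* moieties has ``2**k`` labeling states.

A :class:`PathwayNetwork` is a list of :class:`Pool` objects plus a list of
:class:`Reaction` objects.  Each reaction carries a first-order mass-action
rate law (capacity times the product of the rate pools' total amounts, with
an optional saturating inhibition term) and a *moiety map*: for every product
moiety, which substrate moiety its label is copied from.  Label transfer
preserves the joint labeling distribution of moieties drawn from the same
substrate (so a methionine m+4 impurity stays m+4 in SAM instead of being
scrambled into m+1/m+3 species) and treats different substrates as
independent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

#: carbons contributed by each labeled moiety
MOIETY_CARBONS = {"me": 1, "bb": 4, "ad": 5}

#: largest mass-shift class reported by the instrument-facing tables
MAX_CLASS = 5


class SimulationError(RuntimeError):
    """Raised when integration produces a non-finite state."""


@dataclass(frozen=True)
class Pool:
    """One metabolite pool.

    Parameters
    ----------
    name:
        Internal identifier (e.g. ``"SAM"``).
    moieties:
        Which carbon moieties of this molecule can carry label, as a subset
        of ``("me", "bb", "ad")``.  Order defines the bit layout of states.
    init_amount:
        Default starting amount, arbitrary concentration units.
    detectable:
        False for pools the instrument cannot reliably measure
        (homocysteine) -- they are flagged, not reported, in peak tables.
    buffered:
        True for reservoirs held at a constant amount (media, R5P).
    metabolite:
        Display name used in emitted peak tables; ``None`` keeps the pool
        internal (sinks, extracellular bookkeeping).
    """

    name: str
    moieties: tuple[str, ...] = ()
    init_amount: float = 0.0
    detectable: bool = True
    buffered: bool = False
    metabolite: str | None = None

    @property
    def n_states(self) -> int:
        return 1 << len(self.moieties)

    def state_mass(self, state: int) -> int:
        """Mass shift (number of labeled carbons) of one labeling state."""
        return sum(
            MOIETY_CARBONS[m]
            for i, m in enumerate(self.moieties)
            if (state >> i) & 1
        )

    @property
    def label_classes(self) -> tuple[int, ...]:
        """Attainable mass-shift classes, capped at m+5."""
        masses = {self.state_mass(s) for s in range(self.n_states)}
        return tuple(sorted(m for m in masses if m <= MAX_CLASS))


@dataclass(frozen=True)
class ProductRule:
    """Where one product of a reaction gets its label from.

    ``sources`` maps each moiety of the product pool either to a
    ``(substrate_pool, substrate_moiety)`` pair, or to ``None`` for a carbon
    that enters unlabeled (e.g. the methyl group added by remethylation).
    Alternatively ``dist`` gives an explicit labeling distribution over the
    product's states (used for uptake from labeled media).
    """

    pool: str
    sources: dict[str, tuple[str, str] | None] | None = None
    dist: tuple[float, ...] | None = None
    stoich: float = 1.0


@dataclass
class Reaction:
    """A first-order (per rate pool) mass-action reaction with a moiety map.

    ``rate = capacity * prod(total amount of each rate pool)``, optionally
    divided by ``1 + [inhibitor]/Ki``.  Every consumed, non-buffered pool
    must appear in ``rate_pools`` so fluxes vanish as the pool empties.
    """

    name: str
    capacity: float
    rate_pools: tuple[str, ...]
    consumes: dict[str, float] = field(default_factory=dict)
    products: tuple[ProductRule, ...] = ()
    inhibitor: tuple[str, float] | None = None
    atp_cost: int = 0
    step_count: int | None = None


class _CompiledReaction:
    __slots__ = (
        "name", "capacity", "rate_idx", "inhib", "consume_plan",
        "product_plan", "flux_idx",
    )


class PathwayNetwork:
    """A compiled pool/reaction network ready for integration.

    The state vector concatenates, per pool, one amount per labeling state,
    followed by one cumulative-flux slot per reaction (integrated alongside
    the amounts so the flux ledger falls out of the same RK4 pass).
    """

    def __init__(self, pools: list[Pool], reactions: list[Reaction]):
        self.pools = list(pools)
        self.reactions = list(reactions)
        self.pool_index = {p.name: i for i, p in enumerate(self.pools)}
        if len(self.pool_index) != len(self.pools):
            raise ValueError("duplicate pool names")

        offset = 0
        self._pool_slices: list[slice] = []
        for p in self.pools:
            self._pool_slices.append(slice(offset, offset + p.n_states))
            offset += p.n_states
        self.n_pool_states = offset
        self._flux_offset = offset
        self.n_state = offset + len(self.reactions)
        self._compile()

    # ------------------------------------------------------------------ #
    # compilation

    def _compile(self) -> None:
        self._compiled: list[_CompiledReaction] = []
        for ri, rxn in enumerate(self.reactions):
            c = _CompiledReaction()
            c.name = rxn.name
            c.capacity = float(rxn.capacity)
            c.rate_idx = tuple(self.pool_index[n] for n in rxn.rate_pools)
            c.flux_idx = self._flux_offset + ri
            if rxn.inhibitor is not None:
                iname, ki = rxn.inhibitor
                c.inhib = (self.pool_index[iname], float(ki))
            else:
                c.inhib = None

            c.consume_plan = []
            for pname, stoich in rxn.consumes.items():
                pi = self.pool_index[pname]
                if self.pools[pi].buffered:
                    continue
                if pname not in rxn.rate_pools:
                    raise ValueError(
                        f"{rxn.name}: consumed pool {pname} must be a rate pool"
                    )
                c.consume_plan.append((self._pool_slices[pi], float(stoich), pi))

            c.product_plan = []
            for rule in rxn.products:
                pi = self.pool_index[rule.pool]
                pool = self.pools[pi]
                sl = self._pool_slices[pi]
                if rule.dist is not None:
                    vec = np.asarray(rule.dist, dtype=float)
                    if vec.shape != (pool.n_states,) or abs(vec.sum() - 1) > 1e-9:
                        raise ValueError(
                            f"{rxn.name}: bad explicit distribution for {rule.pool}"
                        )
                    c.product_plan.append((sl, float(rule.stoich), [("dist", None, vec, None)]))
                    continue
                sources = dict(rule.sources or {})
                if set(sources) != set(pool.moieties):
                    raise ValueError(
                        f"{rxn.name}: moiety map for {rule.pool} must cover "
                        f"{pool.moieties}"
                    )
                groups = self._build_groups(pool, sources)
                c.product_plan.append((sl, float(rule.stoich), groups))
            self._compiled.append(c)

    def _build_groups(self, pool: Pool, sources):
        """Group product moieties by source pool; same-source moieties keep
        their joint labeling distribution, distinct sources are independent."""
        by_source: dict[str | None, list[str]] = {}
        for m in pool.moieties:
            src = sources[m]
            key = None if src is None else src[0]
            by_source.setdefault(key, []).append(m)

        groups = []
        for src_name, prod_moieties in by_source.items():
            k = len(prod_moieties)
            sel = np.zeros(pool.n_states, dtype=np.intp)
            for ps in range(pool.n_states):
                j = 0
                for i, pm in enumerate(prod_moieties):
                    bit = (ps >> pool.moieties.index(pm)) & 1
                    j |= bit << i
                sel[ps] = j
            if src_name is None:
                vec = np.zeros(1 << k)
                vec[0] = 1.0  # unlabeled carbons enter in the all-zero tuple
                groups.append(("fixed", None, vec, sel))
            else:
                src_pool = self.pools[self.pool_index[src_name]]
                S = np.zeros((src_pool.n_states, 1 << k))
                for ss in range(src_pool.n_states):
                    j = 0
                    for i, pm in enumerate(prod_moieties):
                        sm = sources[pm][1]
                        bit = (ss >> src_pool.moieties.index(sm)) & 1
                        j |= bit << i
                    S[ss, j] = 1.0
                groups.append(("transfer", self.pool_index[src_name], S, sel))
        return groups

    # ------------------------------------------------------------------ #
    # state helpers

    def initial_state(
        self,
        amounts: dict[str, float] | None = None,
        label_dists: dict[str, np.ndarray] | None = None,
    ) -> np.ndarray:
        """Build a state vector; pools start unlabeled unless a labeling
        distribution is supplied (tests use this for conservation checks)."""
        y = np.zeros(self.n_state)
        amounts = amounts or {}
        label_dists = label_dists or {}
        for p, sl in zip(self.pools, self._pool_slices):
            amt = float(amounts.get(p.name, p.init_amount))
            if amt < 0:
                raise ValueError(f"negative amount for pool {p.name}")
            if p.name in label_dists:
                dist = np.asarray(label_dists[p.name], dtype=float)
                if dist.shape != (p.n_states,) or abs(dist.sum() - 1) > 1e-9:
                    raise ValueError(f"bad label distribution for {p.name}")
                y[sl] = amt * dist
            else:
                y[sl.start] = amt
        return y

    def pool_slice(self, name: str) -> slice:
        return self._pool_slices[self.pool_index[name]]

    def total(self, y: np.ndarray, name: str) -> float:
        return float(y[self.pool_slice(name)].sum())

    def class_fractions(self, y: np.ndarray, name: str) -> dict[str, float]:
        """Mass-shift class fractions of one pool (empty pool -> all zero)."""
        p = self.pools[self.pool_index[name]]
        state = y[self.pool_slice(name)]
        tot = state.sum()
        out = {f"m+{c}": 0.0 for c in p.label_classes}
        if tot <= 0:
            return out
        for s, amt in enumerate(state):
            mass = p.state_mass(s)
            if mass <= MAX_CLASS:
                out[f"m+{mass}"] += float(amt) / tot
        return out

    def labeled_moiety_amount(self, y: np.ndarray, moiety: str) -> float:
        """Total amount of molecules carrying a labeled ``moiety`` -- the
        conserved quantity in a closed network."""
        total = 0.0
        for p, sl in zip(self.pools, self._pool_slices):
            if moiety not in p.moieties:
                continue
            bit = p.moieties.index(moiety)
            for s in range(p.n_states):
                if (s >> bit) & 1:
                    total += y[sl][s]
        return float(total)

    def reaction(self, name: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.name == name:
                return rxn
        raise KeyError(name)

    # ------------------------------------------------------------------ #
    # dynamics

    def rhs(self, y: np.ndarray) -> np.ndarray:
        d = np.zeros_like(y)
        totals = np.empty(len(self.pools))
        for i, sl in enumerate(self._pool_slices):
            t = y[sl].sum()
            totals[i] = t if t > 0.0 else 0.0
        fracs: list[np.ndarray | None] = [None] * len(self.pools)

        def frac(pi: int) -> np.ndarray:
            f = fracs[pi]
            if f is None:
                tot = totals[pi]
                if tot > 1e-300:
                    f = y[self._pool_slices[pi]] / tot
                else:
                    f = np.zeros(self.pools[pi].n_states)
                fracs[pi] = f
            return f

        for c in self._compiled:
            rate = c.capacity
            if rate == 0.0:
                continue
            for pi in c.rate_idx:
                rate *= totals[pi]
            if c.inhib is not None:
                ii, ki = c.inhib
                rate /= 1.0 + totals[ii] / ki
            if rate <= 0.0:
                continue
            d[c.flux_idx] += rate
            for sl, stoich, pi in c.consume_plan:
                d[sl] -= (rate * stoich) * frac(pi)
            for sl, stoich, groups in c.product_plan:
                dist: np.ndarray | None = None
                for kind, src_pi, mat, sel in groups:
                    if kind == "dist":
                        vec_sel = mat
                    elif kind == "fixed":
                        vec_sel = mat[sel]
                    else:
                        vec_sel = (frac(src_pi) @ mat)[sel]
                    dist = vec_sel if dist is None else dist * vec_sel
                d[sl] += (rate * stoich) * dist

        # buffered pools are reservoirs: zero their derivatives
        for p, sl in zip(self.pools, self._pool_slices):
            if p.buffered:
                d[sl] = 0.0
        return d


def purine_cost_summary(network: PathwayNetwork) -> dict[str, int]:
    """Stoichiometric constants of the lumped de novo purine reaction.

    The lump condenses the 11-step synthesis of IMP from ribose-5-phosphate,
    which spends six ATP per IMP made.
    """
    for rxn in network.reactions:
        if rxn.step_count is not None:
            return {"atp_per_imp": int(rxn.atp_cost),
                    "steps_to_imp": int(rxn.step_count)}
    raise ValueError("network has no lumped de novo purine reaction")
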
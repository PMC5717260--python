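"""Attractor-landscape computation and phenotype classification.

For a clamped network the synchronous dynamics define a functional graph on
the 2^f states of the f unclamped nodes; every trajectory ends in a fixed
point or a cycle (an attractor), and the set of initial states reaching an
attractor is its basin.  Basin sizes relative to the whole state space are
the model's phenotype readout.

Two exact solvers are provided:

* ``doubling`` (default): builds the full one-step transition array with
  vectorized arithmetic and composes it with itself f times
  (pointer doubling), mapping every state onto its attractor cycle.
* ``walk``: memoized per-state trajectory walking in plain Python, linear
  total work; serves as an independent route for cross-checking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import BooleanNetwork, ClampSpec, step

logger = logging.getLogger(__name__)

PHENOTYPES = ("P", "A", "D", "U")

#: hard ceiling on free nodes; 2^24 states is the largest exact enumeration
DEFAULT_MAX_FREE_NODES = 24


class StateSpaceTooLargeError(RuntimeError):
    """Exact enumeration refused: free-node count above the configured cap."""


@dataclass(frozen=True)
class Attractor:
    """A fixed point (cycle length 1) or limit cycle with its basin size."""

    cycle: tuple[int, ...]  # full-network integer states, canonical rotation
    basin_size: int
    phenotype: str

    def __post_init__(self) -> None:
        if len(set(self.cycle)) != len(self.cycle):
            raise ValueError("cycle states must be distinct")
        if self.basin_size < len(self.cycle):
            raise ValueError("basin must contain at least the cycle itself")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"phenotype must be one of {PHENOTYPES}")


@dataclass(frozen=True)
class AttractorLandscape:
    """All attractors of one clamped network with exact basin sizes."""

    attractors: tuple[Attractor, ...]
    total_initial_states: int

    @property
    def basin_ratios(self) -> dict[str, float]:
        ratios = {p: 0.0 for p in PHENOTYPES}
        for att in self.attractors:
            ratios[att.phenotype] += att.basin_size / self.total_initial_states
        return ratios

    @property
    def death_ratio(self) -> float:
        return self.basin_ratios["D"]


def classify_cycle(cycle: tuple[int, ...], net: BooleanNetwork) -> str:
    """Phenotype of an attractor cycle from the marker nodes.

    Precedence D > A > P: persistent death-marker activation is death;
    otherwise any (persistent or oscillatory) arrest-marker activation is
    arrest; otherwise persistent proliferation-marker activation is
    proliferation; anything else is unclassified (U).
    """
    roles = net.marker_roles
    if not all(r in roles for r in ("proliferation", "arrest", "death")):
        raise ValueError("network must declare proliferation, arrest and death markers")
    death = [net.node_bit(s, roles["death"]) for s in cycle]
    if all(death):
        return "D"
    arrest = [net.node_bit(s, roles["arrest"]) for s in cycle]
    if any(arrest):
        return "A"
    prolif = [net.node_bit(s, roles["proliferation"]) for s in cycle]
    if all(prolif):
        return "P"
    return "U"


def classify_attractor(att: Attractor, net: BooleanNetwork) -> str:
    return classify_cycle(att.cycle, net)


def _phenotype_or_u(cycle: tuple[int, ...], net: BooleanNetwork) -> str:
    # networks without declared markers still get an exact landscape, all-U
    if not all(r in net.marker_roles for r in ("proliferation", "arrest", "death")):
        return "U"
    return classify_cycle(cycle, net)


def major_phenotype(land: AttractorLandscape) -> str:
    """Largest basin-ratio phenotype among P/A/D; ties broken D > A > P."""
    ratios = land.basin_ratios
    best = max(("D", "A", "P"), key=lambda p: ratios[p])
    if ratios[best] == 0.0:
        raise ValueError("all basin mass is unclassified; no major phenotype")
    return best


def major_phenotype_or_u(land: AttractorLandscape) -> str:
    """Like :func:`major_phenotype` but reports ``"U"`` for an entirely
    unclassified landscape (e.g. a quiescent state with every marker off)
    instead of raising; screen-level code treats U as its own response."""
    try:
        return major_phenotype(land)
    except ValueError:
        return "U"


def _transition_table(net: BooleanNetwork, clamps: ClampSpec) -> tuple[np.ndarray, list[int], int]:
    """Vectorized one-step map over all free-node states.

    Returns (T, free_indices, forced_bits) where ``T[x]`` is the successor of
    free-state ``x`` and ``forced_bits`` is the full-state contribution of
    the clamped nodes.
    """
    free = [i for i, n in enumerate(net.node_names) if n not in clamps.forced]
    f = len(free)
    size = 1 << f
    idx = np.arange(size, dtype=np.int64)
    # current value array per node (0/1 int8 broadcastable)
    values: list[np.ndarray] = []
    pos_of = {node_i: p for p, node_i in enumerate(free)}
    for i, name in enumerate(net.node_names):
        if name in clamps.forced:
            values.append(np.full(size, clamps.forced[name], dtype=np.int64))
        else:
            values.append((idx >> pos_of[i]) & 1)
    nxt = np.zeros(size, dtype=np.int64)
    for p, i in enumerate(free):
        name = net.node_names[i]
        s = np.full(size, net.basal_of(name), dtype=np.int64)
        for src, tgt, w in net.links:
            if tgt != name or (src, tgt) in clamps.disabled_links:
                continue
            s += w * values[net.index(src)]
        bit = np.where(s > 0, 1, np.where(s < 0, 0, values[i]))
        nxt |= bit << p
    forced_bits = 0
    for name, v in clamps.forced.items():
        forced_bits |= v << net.index(name)
    return nxt, free, forced_bits


def _free_to_full(x: int, free: list[int], forced_bits: int) -> int:
    s = forced_bits
    for p, i in enumerate(free):
        s |= ((x >> p) & 1) << i
    return s


def _canonical_cycle(entry: int, T: np.ndarray) -> tuple[int, ...]:
    """Walk the cycle through ``entry`` and rotate it to start at its minimum."""
    cyc = [entry]
    x = int(T[entry])
    while x != entry:
        cyc.append(x)
        x = int(T[x])
    k = cyc.index(min(cyc))
    return tuple(cyc[k:] + cyc[:k])


def compute_landscape(
    net: BooleanNetwork,
    clamps: ClampSpec | None = None,
    *,
    method: str = "doubling",
    max_free_nodes: int = DEFAULT_MAX_FREE_NODES,
) -> AttractorLandscape:
    """Exact attractor landscape of the clamped network.

    Enumerates every initial state over the unclamped nodes (clamped nodes
    fixed at their forced values), so ``total_initial_states`` is
    2^(free nodes) and basin sizes sum to it exactly.  Attractor identity is
    canonicalized by the smallest integer-encoded state of the cycle.
    """
    clamps = clamps or ClampSpec()
    free_count = sum(1 for n in net.node_names if n not in clamps.forced)
    if free_count > max_free_nodes:
        raise StateSpaceTooLargeError(
            f"{free_count} free nodes exceed the cap of {max_free_nodes}; "
            "exact enumeration refused"
        )
    if free_count == 0:
        # fully determined system: the forced state is its own fixed point
        forced_bits = 0
        for name, v in clamps.forced.items():
            forced_bits |= v << net.index(name)
        cycle = (forced_bits,)
        att = Attractor(cycle, 1, _phenotype_or_u(cycle, net))
        return AttractorLandscape((att,), 1)

    T, free, forced_bits = _transition_table(net, clamps)
    size = T.shape[0]

    if method == "doubling":
        S = T
        for _ in range(free_count):
            S = S[S]  # composes T^(2^m); after f squarings every state sits in-cycle
        cycle_of_state: dict[int, int] = {}
        cycles: list[tuple[int, ...]] = []
        for e in np.unique(S):
            e = int(e)
            if e in cycle_of_state:
                continue
            cyc = _canonical_cycle(e, T)
            aid = len(cycles)
            cycles.append(cyc)
            for s in cyc:
                cycle_of_state[s] = aid
        lut = np.full(size, -1, dtype=np.int64)
        for s, aid in cycle_of_state.items():
            lut[s] = aid
        ids = lut[S]
        basins = np.bincount(ids, minlength=len(cycles))
    elif method == "walk":
        assign = np.full(size, -1, dtype=np.int64)
        cycles = []
        for start in range(size):
            if assign[start] >= 0:
                continue
            path = []
            seen_at: dict[int, int] = {}
            x = start
            while assign[x] < 0 and x not in seen_at:
                seen_at[x] = len(path)
                path.append(x)
                x = int(T[x])
            if assign[x] >= 0:
                aid = int(assign[x])
            else:  # new cycle discovered on this walk
                cstart = seen_at[x]
                cyc = path[cstart:]
                k = cyc.index(min(cyc))
                cycles.append(tuple(cyc[k:] + cyc[:k]))
                aid = len(cycles) - 1
            for s in path:
                assign[s] = aid
        basins = np.bincount(assign, minlength=len(cycles))
    else:
        raise ValueError(f"unknown method {method!r}")

    attractors = []
    for aid, cyc in enumerate(cycles):
        full_cycle = tuple(_free_to_full(s, free, forced_bits) for s in cyc)
        attractors.append(
            Attractor(full_cycle, int(basins[aid]), _phenotype_or_u(full_cycle, net))
        )
    # deterministic ordering by canonical state
    attractors.sort(key=lambda a: a.cycle[0])
    land = AttractorLandscape(tuple(attractors), size)
    if land.basin_ratios["U"] > 0:
        _warn_unclassified(land.basin_ratios["U"])
    return land


_warned_unclassified = False


def _warn_unclassified(ratio: float) -> None:
    # U mass stays explicit in every landscape; the log line fires once per run
    global _warned_unclassified
    if not _warned_unclassified:
        logger.warning(
            "%.3f of basin mass is unclassified (U) in at least one landscape — "
            "marker rules cover no phenotype there (reported once)",
            ratio,
        )
        _warned_unclassified = True


def naive_landscape(net: BooleanNetwork, clamps: ClampSpec | None = None) -> AttractorLandscape:
    """Reference solver: follow every trajectory with :func:`step`, no memoization.

    Exponentially slower than :func:`compute_landscape`; intended as an
    independent oracle on small networks.
    """
    clamps = clamps or ClampSpec()
    free = [i for i, n in enumerate(net.node_names) if n not in clamps.forced]
    forced_bits = 0
    for name, v in clamps.forced.items():
        forced_bits |= v << net.index(name)
    basins: dict[tuple[int, ...], int] = {}
    for x in range(1 << len(free)):
        state = _free_to_full(x, free, forced_bits)
        seen: dict[int, int] = {}
        traj = []
        while state not in seen:
            seen[state] = len(traj)
            traj.append(state)
            state = step(net, state, clamps)
        cyc = traj[seen[state]:]
        k = cyc.index(min(cyc))
        canon = tuple(cyc[k:] + cyc[:k])
        basins[canon] = basins.get(canon, 0) + 1
    attractors = tuple(
        Attractor(cyc, n, _phenotype_or_u(cyc, net))
        for cyc, n in sorted(basins.items(), key=lambda kv: kv[0][0])
    )
    return AttractorLandscape(attractors, 1 << len(free))


def landscape_table(land: AttractorLandscape, net: BooleanNetwork) -> list[dict]:
    """Rows for the TSV export: one per attractor."""
    rows = []
    for i, att in enumerate(land.attractors):
        bitstrings = [
            "".join(str((s >> j) & 1) for j in range(net.n_nodes)) for s in att.cycle
        ]
        rows.append(
            {
                "attractor_id": i,
                "cycle_length": len(att.cycle),
                "basin_size": att.basin_size,
                "phenotype": att.phenotype,
                "cycle_states": ";".join(bitstrings),
            }
        )
    return rows
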
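"""Weighted-sum Boolean networks: model container, parsing, clamping, update rule.

The dynamical model is a deterministic synchronous Boolean network in which
each node's next state is decided by the sign of a weighted sum of its
regulators plus a basal level:

    s_i(t) = sum_j w_ji * x_j(t) + b_i
    x_i(t+1) = 1 if s_i > 0, 0 if s_i < 0, x_i(t) if s_i == 0

Weights and basal levels are small signed integers.  Genomic alterations and
drug inhibitions enter the model as *clamps*: a node forced to a constant
0/1 for the whole simulation, or a single directed link removed from the sum.

A network state is encoded as a non-negative integer whose bit ``i`` is the
state of node ``i`` in declaration order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger(__name__)

NODE_STATUSES = ("A", "I", "N")

#: single-letter codes of the druggable targets of the p53 screen
TARGET_LETTERS = {"AKT": "A", "BCL2": "B", "CyclinE": "C", "Wip1": "W"}
LETTER_TARGETS = {v: k for k, v in TARGET_LETTERS.items()}
#: the drug-targetable inhibitory link (blocked by Nutlin-3)
P53_MDM2_LINK = ("MDM2", "p53")
LINK_LETTER = "N"
ETOPOSIDE_LETTER = "E"


class NetworkParseError(ValueError):
    """Raised when a network definition file violates the schema."""


class NetworkValidationError(ValueError):
    """Raised when a structurally parsed network is semantically invalid."""


@dataclass(frozen=True)
class BooleanNetwork:
    """Immutable weighted-sum Boolean network.

    Parameters
    ----------
    node_names : tuple of str
        Unique node identifiers; their order defines the bit layout of the
        integer state encoding.
    links : tuple of (source, target, weight)
        Signed-integer-weighted directed interactions.
    basal : mapping node -> int
        Basal level entering every node's weighted sum.
    input_node : str or None
        The node representing the external stimulus (DNA damage); it is
        always clamped during simulation.
    marker_roles : mapping role -> node
        Phenotype marker nodes for the roles ``proliferation``, ``arrest``
        and ``death``.
    """

    node_names: tuple[str, ...]
    links: tuple[tuple[str, str, int], ...]
    basal: Mapping[str, int]
    input_node: str | None = None
    marker_roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = self.node_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if list(names).count(n) > 1})
            raise NetworkValidationError(f"duplicate node names: {dupes}")
        nodeset = set(names)
        for src, dst, w in self.links:
            if src not in nodeset:
                raise NetworkValidationError(f"link source {src!r} is not a declared node")
            if dst not in nodeset:
                raise NetworkValidationError(f"link target {dst!r} is not a declared node")
            if not isinstance(w, int):
                raise NetworkValidationError(f"link weight {src}->{dst} must be an integer, got {w!r}")
        for node, b in self.basal.items():
            if node not in nodeset:
                raise NetworkValidationError(f"basal level given for unknown node {node!r}")
            if not isinstance(b, int):
                raise NetworkValidationError(f"basal level of {node!r} must be an integer, got {b!r}")
        if self.input_node is not None and self.input_node not in nodeset:
            raise NetworkValidationError(f"input_node {self.input_node!r} is not a declared node")
        for role, node in self.marker_roles.items():
            if role not in ("proliferation", "arrest", "death"):
                raise NetworkValidationError(f"unknown marker role {role!r}")
            if node not in nodeset:
                raise NetworkValidationError(f"marker node {node!r} is not a declared node")
        if self.marker_roles and len(set(self.marker_roles.values())) != len(self.marker_roles):
            raise NetworkValidationError("marker-role nodes must be distinct")

    # -- indexing helpers ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def index(self, node: str) -> int:
        try:
            return self.node_names.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def in_links(self, node: str) -> list[tuple[str, int]]:
        """Regulators of ``node`` as (source, weight) pairs."""
        return [(s, w) for s, t, w in self.links if t == node]

    def basal_of(self, node: str) -> int:
        return int(self.basal.get(node, 0))

    # -- state encoding ------------------------------------------------------
    def encode_state(self, bits: Mapping[str, int]) -> int:
        """Pack a node -> {0,1} mapping into the integer state encoding."""
        state = 0
        for i, name in enumerate(self.node_names):
            v = bits[name]
            if v not in (0, 1):
                raise ValueError(f"state of {name!r} must be 0 or 1, got {v!r}")
            state |= v << i
        return state

    def decode_state(self, state: int) -> dict[str, int]:
        """Unpack an integer state into a node -> {0,1} mapping."""
        if not 0 <= state < (1 << self.n_nodes):
            raise ValueError(f"state {state} out of range for {self.n_nodes} nodes")
        return {name: (state >> i) & 1 for i, name in enumerate(self.node_names)}

    def node_bit(self, state: int, node: str) -> int:
        return (state >> self.index(node)) & 1


@dataclass(frozen=True)
class NodeStatusProfile:
    """Ternary genotype of a network: per-node status A / I / N.

    ``A`` marks a constitutively activated node, ``I`` a constitutively
    inactivated node and ``N`` a node whose activity remains input-dependent.
    A profile with at least one non-N node defines a differentially wired
    network (DWN).
    """

    profile: Mapping[str, str]
    member_cell_lines: tuple[str, ...] = ()
    dwn_id: str | None = None

    def __post_init__(self) -> None:
        for node, status in self.profile.items():
            if status not in NODE_STATUSES:
                raise ValueError(f"status of {node!r} must be one of {NODE_STATUSES}, got {status!r}")
        if self.dwn_id is not None:
            k = int(self.dwn_id.split("_")[1])
            if k != self.n_alterations:
                raise ValueError(
                    f"dwn_id {self.dwn_id!r} claims {k} alterations but profile has {self.n_alterations}"
                )

    @property
    def n_alterations(self) -> int:
        return sum(1 for s in self.profile.values() if s != "N")

    @property
    def altered_nodes(self) -> tuple[str, ...]:
        return tuple(sorted(n for n, s in self.profile.items() if s != "N"))

    def restricted_to(self, nodes: Iterable[str]) -> "NodeStatusProfile":
        """Profile keeping only the alterations on ``nodes`` (others reset to N)."""
        keep = set(nodes)
        return NodeStatusProfile(
            {n: (s if n in keep else "N") for n, s in self.profile.items()}
        )

    def signature(self) -> str:
        """Canonical string of the alterations, e.g. ``'AKT:A|p14ARF:I'``."""
        return "|".join(f"{n}:{self.profile[n]}" for n in self.altered_nodes)


def normal_profile(net: BooleanNetwork) -> NodeStatusProfile:
    """All-N profile: the unaltered (normal) network."""
    return NodeStatusProfile({n: "N" for n in net.node_names})


@dataclass(frozen=True)
class Treatment:
    """A drug-treatment condition of the perturbation screen.

    ``inhibited_nodes`` are the targeted-drug node inhibitions (AKT, BCL2,
    CyclinE, Wip1); ``inhibit_p53_mdm2_link`` models Nutlin-3 blocking the
    MDM2 -| p53 repression; ``etoposide`` switches the DNA-damage input on.
    """

    inhibited_nodes: frozenset[str] = frozenset()
    inhibit_p53_mdm2_link: bool = False
    etoposide: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.inhibited_nodes) - set(TARGET_LETTERS)
        if unknown:
            raise ValueError(f"not druggable targets of the screen: {sorted(unknown)}")

    @property
    def letters(self) -> tuple[str, ...]:
        """Non-etoposide single-letter codes, alphabetically."""
        codes = [TARGET_LETTERS[n] for n in self.inhibited_nodes]
        if self.inhibit_p53_mdm2_link:
            codes.append(LINK_LETTER)
        return tuple(sorted(codes))

    @property
    def label(self) -> str:
        parts = (["E"] if self.etoposide else []) + list(self.letters)
        return "_".join(parts) if parts else "untreated"

    @property
    def is_baseline(self) -> bool:
        """True for the two untreated references (with or without damage)."""
        return not self.inhibited_nodes and not self.inhibit_p53_mdm2_link

    @classmethod
    def from_label(cls, label: str) -> "Treatment":
        if label == "untreated":
            return cls()
        parts = label.split("_")
        etop = parts and parts[0] == ETOPOSIDE_LETTER
        codes = parts[1:] if etop else parts
        nodes, link = set(), False
        for c in codes:
            if c == LINK_LETTER:
                link = True
            elif c in LETTER_TARGETS:
                nodes.add(LETTER_TARGETS[c])
            else:
                raise ValueError(f"unknown treatment code {c!r} in label {label!r}")
        return cls(frozenset(nodes), link, bool(etop))


@dataclass(frozen=True)
class ClampSpec:
    """Constant-value node clamps and removed links for one simulation."""

    forced: Mapping[str, int] = field(default_factory=dict)
    disabled_links: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        for node, v in self.forced.items():
            if v not in (0, 1):
                raise ValueError(f"forced value of {node!r} must be 0 or 1, got {v!r}")


def build_clamps(
    net: BooleanNetwork,
    genotype: NodeStatusProfile | None = None,
    treatment: Treatment | None = None,
    *,
    allow_input_genotype: bool = False,
) -> ClampSpec:
    """Translate a genotype and a treatment into simulation clamps.

    Genotype status A forces a node to 1, I forces it to 0.  Each drug-
    inhibited node is forced to 0; inhibition overrides a genotype A clamp on
    the same node.  The link inhibitor removes the MDM2->p53 edge.  The
    DNA-damage input node is forced to 1 under etoposide, 0 otherwise, unless
    a genotype alteration on the input node is explicitly permitted (used by
    the shuffled-network null ensembles), in which case the genotype wins.
    """
    genotype = genotype or normal_profile(net)
    treatment = treatment or Treatment()
    nodeset = set(net.node_names)

    forced: dict[str, int] = {}
    for node, status in genotype.profile.items():
        if node not in nodeset:
            raise NetworkValidationError(f"genotype names unknown node {node!r}")
        if status == "N":
            continue
        if node == net.input_node and not allow_input_genotype:
            raise NetworkValidationError(
                f"genotype status on the input node {node!r} is not allowed"
            )
        forced[node] = 1 if status == "A" else 0

    for node in treatment.inhibited_nodes:
        if node not in nodeset:
            raise NetworkValidationError(f"treatment target {node!r} absent from network")
        forced[node] = 0  # drug inhibition wins over a genotype A clamp

    disabled: set[tuple[str, str]] = set()
    if treatment.inhibit_p53_mdm2_link:
        src, dst = P53_MDM2_LINK
        if src not in nodeset or dst not in nodeset:
            raise NetworkValidationError(
                f"link inhibitor requires nodes {src!r} and {dst!r} in the network"
            )
        disabled.add(P53_MDM2_LINK)

    if net.input_node is not None and net.input_node not in forced:
        forced[net.input_node] = 1 if treatment.etoposide else 0

    return ClampSpec(forced=forced, disabled_links=frozenset(disabled))


def step(net: BooleanNetwork, state: int, clamps: ClampSpec | None = None) -> int:
    """One synchronous update of every node; pure function of its arguments."""
    clamps = clamps or ClampSpec()
    if not 0 <= state < (1 << net.n_nodes):
        raise ValueError(f"state {state} out of range for {net.n_nodes}-node network")
    nxt = 0
    for i, node in enumerate(net.node_names):
        if node in clamps.forced:
            bit = clamps.forced[node]
        else:
            s = net.basal_of(node)
            for src, tgt, w in net.links:
                if tgt != node or (src, tgt) in clamps.disabled_links:
                    continue
                s += w * ((state >> net.index(src)) & 1)
            if s > 0:
                bit = 1
            elif s < 0:
                bit = 0
            else:
                bit = (state >> i) & 1  # tie holds the previous value
        nxt |= bit << i
    return nxt


def parse_network(config_text: str) -> BooleanNetwork:
    """Parse the YAML network definition format into a validated network.

    Required keys: ``version``, ``nodes`` (list), ``links`` (list of
    ``[source, target, weight]``), ``basal`` (mapping).  Optional:
    ``input_node``, ``marker_roles``.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise NetworkParseError(f"not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise NetworkParseError("network file must be a mapping of sections")
    if "version" not in doc:
        raise NetworkParseError("missing required field 'version'")
    for key in ("nodes", "links", "basal"):
        if key not in doc:
            raise NetworkParseError(f"missing required section '{key}'")
    nodes = doc["nodes"]
    if not isinstance(nodes, list) or not all(isinstance(n, str) for n in nodes):
        raise NetworkParseError("section 'nodes' must be a list of node names")
    links = []
    for entry in doc["links"]:
        if not (isinstance(entry, list) and len(entry) == 3):
            raise NetworkParseError(f"link entry {entry!r} must be [source, target, weight]")
        src, dst, w = entry
        if not isinstance(w, int):
            raise NetworkParseError(f"link weight in {entry!r} must be an integer")
        links.append((str(src), str(dst), w))
    basal = doc["basal"]
    if not isinstance(basal, dict):
        raise NetworkParseError("section 'basal' must be a mapping node -> integer")
    marker_roles = doc.get("marker_roles") or {}
    if not isinstance(marker_roles, dict):
        raise NetworkParseError("section 'marker_roles' must be a mapping role -> node")
    try:
        return BooleanNetwork(
            node_names=tuple(nodes),
            links=tuple(links),
            basal=dict(basal),
            input_node=doc.get("input_node"),
            marker_roles=dict(marker_roles),
        )
    except NetworkValidationError:
        raise


def serialize_network(net: BooleanNetwork) -> str:
    """Inverse of :func:`parse_network`."""
    doc = {
        "version": 1,
        "nodes": list(net.node_names),
        "links": [[s, t, w] for s, t, w in net.links],
        "basal": dict(net.basal),
        "input_node": net.input_node,
        "marker_roles": dict(net.marker_roles),
    }
    return yaml.safe_dump(doc, sort_keys=False)


def tie_audit(net: BooleanNetwork) -> list[tuple[str, dict[str, int]]]:
    """Report every regulator combination whose weighted sum is exactly zero.

    The update rule holds a node's value on a zero sum; a network whose local
    truth tables are tie-free behaves identically under hold-on-tie and any
    other tie convention, so an empty audit makes the choice inert.
    """
    ties = []
    for node in net.node_names:
        regs = net.in_links(node)
        b = net.basal_of(node)
        sources = [s for s, _ in regs]
        for combo in product((0, 1), repeat=len(regs)):
            if b + sum(w * x for (_, w), x in zip(regs, combo)) == 0:
                ties.append((node, dict(zip(sources, combo))))
    return ties
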
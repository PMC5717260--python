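"""Seeded synthetic fixtures: reference network, random networks, genomics
tables with planted truths, DWN panels, and noisy observed responses.

Everything needed to exercise the full pipeline is generated here,
bit-reproducibly under a fixed seed; no downloads are involved.  The
genomics generator emulates the *structure* of curated cancer-cell-line
data (variant classes, functional-impact categories, discrete copy-number
calls with expression z-scores) — not realistic mutation spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .genomics import GeneMap
from .landscape import compute_landscape
from .network import (
    BooleanNetwork,
    NodeStatusProfile,
    Treatment,
    build_clamps,
    parse_network,
    tie_audit,
)
from .stratification import Screen

REFERENCE_NODE_COUNT = 16


class FixtureIntegrityError(RuntimeError):
    """The bundled reference network failed its structural self-checks."""


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic generators (all seeded, all reproducible).

    Defaults mirror the reference study conditions: a panel of 83 cell
    lines collapsing to about 45 distinct DWNs carrying 1-4 alterations
    each, and observation noise of 0.05 on death fractions.
    """

    seed: int = 0
    node_count: int = 8
    link_density: float = 0.35
    weight_range: int = 3  # weights drawn from +-1..weight_range
    panel_size: int = 83
    n_dwns: int = 45
    alteration_counts: tuple[int, ...] = (1, 2, 3, 4)
    alteration_probs: tuple[float, ...] = (0.3, 0.3, 0.25, 0.15)
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.node_count < 3 or self.panel_size < 1 or self.n_dwns < 1:
            raise ValueError("counts must be positive (and node_count >= 3)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if len(self.alteration_counts) != len(self.alteration_probs):
            raise ValueError("alteration-count distribution malformed")


def make_reference_p53_network() -> BooleanNetwork:
    """Load the bundled 16-node p53 network and verify its integrity.

    Checks: exactly 16 nodes, the DNA-damage input and the three distinct
    phenotype markers declared, and a tie-free weighted-sum logic.
    """
    text = resources.files("netdyn.data").joinpath("p53_network.yaml").read_text()
    net = parse_network(text)
    if net.n_nodes != REFERENCE_NODE_COUNT:
        raise FixtureIntegrityError(
            f"reference network has {net.n_nodes} nodes, expected {REFERENCE_NODE_COUNT}"
        )
    if net.input_node is None:
        raise FixtureIntegrityError("reference network lacks the DNA-damage input node")
    if set(net.marker_roles) != {"proliferation", "arrest", "death"}:
        raise FixtureIntegrityError("reference network lacks a phenotype marker role")
    ties = tie_audit(net)
    if ties:
        raise FixtureIntegrityError(f"reference network has weighted-sum ties: {ties}")
    return net


def random_network(cfg: FixtureConfig) -> BooleanNetwork:
    """Seeded random weighted-sum network with declared marker roles."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.node_count
    names = tuple(f"X{i}" for i in range(n))
    weights = [w for w in range(-cfg.weight_range, cfg.weight_range + 1) if w != 0]
    links = []
    for src in names:
        for dst in names:
            if src != dst and rng.random() < cfg.link_density:
                links.append((src, dst, int(rng.choice(weights))))
    basal = {name: int(rng.integers(-2, 3)) for name in names}
    markers = rng.choice(n, size=3, replace=False)
    return BooleanNetwork(
        node_names=names,
        links=tuple(links),
        basal=basal,
        input_node=None,
        marker_roles={
            "proliferation": names[markers[0]],
            "arrest": names[markers[1]],
            "death": names[markers[2]],
        },
    )


def default_gene_map(net: BooleanNetwork) -> GeneMap:
    """Two pseudo-gene symbols per mappable (non-input) node."""
    return GeneMap(
        {
            node: {f"{node.upper()}_G1", f"{node.upper()}_G2"}
            for node in net.node_names
            if node != net.input_node
        }
    )


@dataclass
class GenomicsFixture:
    """Synthetic genomics tables plus the planted ground truth."""

    mutations: pd.DataFrame
    cnas: pd.DataFrame
    gene_map: GeneMap
    truth: dict[str, dict[str, str]] = field(default_factory=dict)  # cell line -> node -> A/I


_DECOY_VARIANTS = ("silent", "rna", "intron", "utr", "flank", "intergenic")


def synthetic_genomics_tables(cfg: FixtureConfig, net: BooleanNetwork) -> GenomicsFixture:
    """Generate mutation/CNA tables with planted functional alterations.

    Every cell line receives a seeded number of planted alterations (the
    truth, expressed as node statuses) realized through a randomly chosen
    evidence type, plus decoy records from every excluded class: silent/
    RNA/intron/UTR/flank/intergenic variants, low-impact and role-less
    missense, DIPLOID and expression-discordant copy-number calls.
    """
    rng = np.random.default_rng(cfg.seed)
    gm = default_gene_map(net)
    mappable = sorted(gm.mapping)
    mut_rows, cna_rows = [], []
    truth: dict[str, dict[str, str]] = {}

    def gene_of(node: str) -> str:
        return sorted(gm.mapping[node])[int(rng.integers(len(gm.mapping[node])))]

    for c in range(cfg.panel_size):
        cl = f"CL{c:03d}"
        k = int(rng.choice(cfg.alteration_counts, p=cfg.alteration_probs))
        k = min(k, len(mappable))
        nodes = list(rng.choice(mappable, size=k, replace=False))
        truth[cl] = {}
        for node in nodes:
            status = "A" if rng.random() < 0.5 else "I"
            truth[cl][node] = status
            gene = gene_of(node)
            evidence = rng.random()
            if status == "A":
                if evidence < 0.5:
                    mut_rows.append((cl, gene, "missense", rng.choice(["high", "medium"]), "oncogene"))
                else:
                    cna_rows.append((cl, gene, rng.choice(["GAIN", "AMP"]), round(float(rng.uniform(1.2, 3.0)), 3)))
            else:
                if evidence < 0.34:
                    mut_rows.append((cl, gene, rng.choice(["nonsense", "frameshift"]), "na", "na"))
                elif evidence < 0.67:
                    mut_rows.append((cl, gene, "missense", rng.choice(["high", "medium"]), "tumor_suppressor"))
                else:
                    cna_rows.append((cl, gene, rng.choice(["HOMDEL", "LOSS"]), round(float(-rng.uniform(1.2, 3.0)), 3)))
        # decoys on nodes outside the planted set so they must not survive filtering
        decoy_nodes = [n for n in mappable if n not in truth[cl]]
        for node in rng.choice(decoy_nodes, size=min(4, len(decoy_nodes)), replace=False):
            gene = gene_of(node)
            d = rng.random()
            if d < 0.3:
                mut_rows.append((cl, gene, rng.choice(_DECOY_VARIANTS), "na", "na"))
            elif d < 0.5:
                mut_rows.append((cl, gene, "missense", rng.choice(["low", "neutral"]), "oncogene"))
            elif d < 0.65:
                mut_rows.append((cl, gene, "missense", "high", "na"))  # role-less: dropped
            elif d < 0.85:
                cna_rows.append((cl, gene, rng.choice(["GAIN", "HOMDEL"]), round(float(rng.uniform(-0.5, 0.5)), 3)))
            else:
                cna_rows.append((cl, gene, "DIPLOID", round(float(rng.normal(0, 1)), 3)))

    mutations = pd.DataFrame(mut_rows, columns=["cell_line", "gene", "variant_class", "impact", "gene_role"])
    cnas = pd.DataFrame(cna_rows, columns=["cell_line", "gene", "call", "mrna_z"])
    return GenomicsFixture(mutations, cnas, gm, truth)


def synthetic_dwn_panel(
    net: BooleanNetwork, cfg: FixtureConfig | None = None
) -> list[NodeStatusProfile]:
    """Distinct random DWN profiles (alterations never on the input node)."""
    cfg = cfg or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    alterable = [n for n in net.node_names if n != net.input_node]
    seen: set[str] = set()
    out: list[NodeStatusProfile] = []
    while len(out) < cfg.n_dwns:
        k = int(rng.choice(cfg.alteration_counts, p=cfg.alteration_probs))
        k = min(k, len(alterable))
        nodes = rng.choice(alterable, size=k, replace=False)
        status = {n: "N" for n in net.node_names}
        for node in nodes:
            status[node] = "A" if rng.random() < 0.5 else "I"
        prof = NodeStatusProfile(status)
        if prof.signature() not in seen:
            seen.add(prof.signature())
            out.append(prof)
    return out


def synthetic_observed_responses(
    dwn: NodeStatusProfile,
    treatments: list[Treatment],
    net: BooleanNetwork,
    *,
    noise_sd: float = 0.05,
    seed: int = 0,
    cell_line: str = "SYN",
    screen: Screen | None = None,
) -> pd.DataFrame:
    """Noisy pseudo-observations of cell death for one genotype.

    observed = predicted death basin ratio + Gaussian noise, clipped to
    [0, 1] (a crude stand-in for imaging measurement error).
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    screen = screen or Screen(net, allow_input_genotype=True)
    rows = []
    for t in treatments:
        pred = screen.death_ratio(dwn, t)
        obs = float(np.clip(pred + rng.normal(0.0, noise_sd), 0.0, 1.0)) if noise_sd else pred
        rows.append({"cell_line": cell_line, "treatment": t.label, "death_fraction": obs, "predicted": pred})
    return pd.DataFrame(rows)
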
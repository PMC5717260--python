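"""Genomic-alteration curation and projection onto network node statuses.

Raw per-cell-line tables (somatic mutation calls and discrete copy-number
calls with expression z-scores) are filtered down to *functional* alteration
calls, annotated as activating or inactivating, projected onto network nodes
as a ternary A/I/N status, and deduplicated into differentially wired
networks (DWNs).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .network import BooleanNetwork, NodeStatusProfile

logger = logging.getLogger(__name__)

VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "silent", "rna", "intron", "utr", "flank", "intergenic"}
)
#: variant classes producing a truncated, loss-of-function protein
TRUNCATING_CLASSES = frozenset({"nonsense", "frameshift"})
IMPACT_LEVELS = frozenset({"high", "medium", "low", "neutral", "na"})
GENE_ROLES = frozenset({"oncogene", "tumor_suppressor", "na"})
CNA_CALLS = frozenset({"HOMDEL", "LOSS", "DIPLOID", "GAIN", "AMP"})
CNA_GAINS = frozenset({"GAIN", "AMP"})
CNA_LOSSES = frozenset({"HOMDEL", "LOSS"})

MUTATION_COLUMNS = ["cell_line", "gene", "variant_class", "impact", "gene_role"]
CNA_COLUMNS = ["cell_line", "gene", "call", "mrna_z"]
CALL_COLUMNS = ["cell_line", "gene", "call", "evidence"]


@dataclass
class FilterConfig:
    """Knobs of the functional-alteration filter.

    ``concordance_z`` is the minimum |mRNA z-score| for a copy-number call to
    count as functionally concordant (gain with over-expression, loss with
    under-expression).
    """

    concordance_z: float = 1.0

    def __post_init__(self) -> None:
        if self.concordance_z <= 0:
            raise ValueError("concordance threshold must be positive")


class GenomicsValidationError(ValueError):
    """Raised for vocabulary violations or unresolvable status conflicts."""


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise GenomicsValidationError(f"{what} table is missing columns {missing}")


def filter_functional_alterations(
    mutations: pd.DataFrame,
    cnas: pd.DataFrame,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Select functional alterations and annotate them as activating/inactivating.

    Mutation rules: truncating variants (nonsense, frameshift) are
    inactivating (``MUT_I``); missense variants with high or medium
    functional impact are activating (``MUT_A``) on oncogenes and
    inactivating (``MUT_I``) on tumor suppressors; silent/RNA/intron/UTR/
    flank/intergenic variants and low-impact missense are excluded.

    Copy-number rules: GAIN/AMP with mRNA z >= +t is activating (``CNA_A``);
    HOMDEL/LOSS with mRNA z <= -t is inactivating (``CNA_I``); discordant
    calls and DIPLOID are excluded.

    Returns a call table with columns ``cell_line, gene, call, evidence``,
    sorted deterministically; input row order does not matter.
    """
    config = config or FilterConfig()
    _require_columns(mutations, MUTATION_COLUMNS, "mutation")
    _require_columns(cnas, CNA_COLUMNS, "CNA")

    rows: list[dict] = []
    n_dropped_roleless = 0
    for rec in mutations.itertuples(index=False):
        vc = str(rec.variant_class).lower()
        if vc not in VARIANT_CLASSES:
            raise GenomicsValidationError(f"unknown variant_class {rec.variant_class!r}")
        impact = str(rec.impact).lower()
        if impact not in IMPACT_LEVELS:
            raise GenomicsValidationError(f"unknown impact {rec.impact!r}")
        role = str(rec.gene_role).lower()
        if role not in GENE_ROLES:
            raise GenomicsValidationError(f"unknown gene_role {rec.gene_role!r}")
        if vc in TRUNCATING_CLASSES:
            call = "MUT_I"
        elif vc == "missense" and impact in ("high", "medium"):
            if role == "oncogene":
                call = "MUT_A"
            elif role == "tumor_suppressor":
                call = "MUT_I"
            else:
                n_dropped_roleless += 1
                continue
        else:
            continue
        rows.append(
            {
                "cell_line": rec.cell_line,
                "gene": rec.gene,
                "call": call,
                "evidence": f"mutation:{vc}:{impact}:{role}",
            }
        )
    if n_dropped_roleless:
        logger.warning(
            "%d functional missense mutation(s) dropped: gene has no curated "
            "oncogene/tumor-suppressor role",
            n_dropped_roleless,
        )

    t = config.concordance_z
    for rec in cnas.itertuples(index=False):
        call = str(rec.call).upper()
        if call not in CNA_CALLS:
            raise GenomicsValidationError(f"unknown CNA call {rec.call!r}")
        z = float(rec.mrna_z)
        if call in CNA_GAINS and z >= t:
            out = "CNA_A"
        elif call in CNA_LOSSES and z <= -t:
            out = "CNA_I"
        else:
            continue
        rows.append(
            {
                "cell_line": rec.cell_line,
                "gene": rec.gene,
                "call": out,
                "evidence": f"cna:{call}:z={z:g}",
            }
        )

    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.drop_duplicates().sort_values(CALL_COLUMNS).reset_index(drop=True)


def project_to_node_status(
    calls: pd.DataFrame,
    gene_map: dict[str, set[str]],
    net: BooleanNetwork,
    cell_lines: list[str] | None = None,
) -> dict[str, NodeStatusProfile]:
    """Project alteration calls onto node statuses, one profile per cell line.

    ``gene_map`` maps each network node to the set of gene symbols that act
    through it.  Activating calls (MUT_A/CNA_A) set a node to A, inactivating
    calls to I; a node with no call stays N.  If mutation and copy-number
    evidence on the same node disagree, the mutation wins; two mutations
    that disagree raise a conflict error.
    """
    _require_columns(calls, ["cell_line", "gene", "call"], "alteration-call")
    for node in gene_map:
        if node not in net.node_names:
            raise GenomicsValidationError(f"gene_map names unknown node {node!r}")
    gene_to_node: dict[str, str] = {}
    for node, genes in gene_map.items():
        for g in genes:
            if g in gene_to_node and gene_to_node[g] != node:
                raise GenomicsValidationError(
                    f"gene {g!r} mapped to both {gene_to_node[g]!r} and {node!r}"
                )
            gene_to_node[g] = node

    lines = list(cell_lines) if cell_lines is not None else sorted(calls["cell_line"].unique())
    per_line_node: dict[str, dict[str, list[tuple[str, str]]]] = {
        cl: defaultdict(list) for cl in lines
    }
    n_unmapped = 0
    for rec in calls.itertuples(index=False):
        node = gene_to_node.get(rec.gene)
        if node is None:
            n_unmapped += 1
            continue
        if rec.cell_line in per_line_node:
            per_line_node[rec.cell_line][node].append((rec.gene, rec.call))
    if n_unmapped:
        logger.info("%d alteration call(s) on genes outside the gene map were ignored", n_unmapped)

    profiles: dict[str, NodeStatusProfile] = {}
    for cl in lines:
        status = {n: "N" for n in net.node_names}
        for node, evid in per_line_node[cl].items():
            directions = {("A" if c.endswith("_A") else "I") for _, c in evid}
            if len(directions) == 1:
                status[node] = directions.pop()
                continue
            # conflict: mutation evidence outranks copy-number evidence
            mut_dirs = {
                ("A" if c.endswith("_A") else "I") for _, c in evid if c.startswith("MUT")
            }
            if len(mut_dirs) == 1:
                status[node] = mut_dirs.pop()
            else:
                raise GenomicsValidationError(
                    f"unresolvable A/I conflict on node {node!r} for {cl!r}: {sorted(evid)}"
                )
        profiles[cl] = NodeStatusProfile(status, member_cell_lines=(cl,))
    return profiles


def build_dwns(profiles: dict[str, NodeStatusProfile] | list[NodeStatusProfile]) -> list[NodeStatusProfile]:
    """Deduplicate identical status profiles into named DWNs.

    Cell lines with the same node-status profile map to a single network.
    Ids are ``DWN_<k>_<i>`` with ``k`` the alteration count and ``i`` the
    1-based lexicographic rank of the profile signature within its ``k``.
    """
    if isinstance(profiles, dict):
        items = [(cl, p) for cl, p in profiles.items()]
    else:
        items = [(m, p) for p in profiles for m in (p.member_cell_lines or (None,))]

    by_sig: dict[tuple[str, ...], list] = defaultdict(list)
    sig_profile: dict[tuple[str, ...], NodeStatusProfile] = {}
    for member, prof in items:
        key = tuple(sorted(f"{n}:{s}" for n, s in prof.profile.items()))
        by_sig[key].append(member)
        sig_profile[key] = prof

    by_k: dict[int, list[tuple[str, tuple[str, ...]]]] = defaultdict(list)
    for key, prof in sig_profile.items():
        by_k[prof.n_alterations].append((prof.signature(), key))

    out = []
    for k in sorted(by_k):
        for i, (_, key) in enumerate(sorted(by_k[k]), start=1):
            prof = sig_profile[key]
            members = tuple(sorted(m for m in by_sig[key] if m is not None))
            out.append(
                NodeStatusProfile(dict(prof.profile), members, dwn_id=f"DWN_{k}_{i}")
            )
    return out


def topology_subgroup(profile: NodeStatusProfile) -> int:
    """Topology subgroup of a DWN: 1 if p14ARF is constantly inactivated,
    else 3 if AKT is constantly activated, else 2."""
    if profile.profile.get("p14ARF") == "I":
        return 1
    if profile.profile.get("AKT") == "A":
        return 3
    return 2


@dataclass
class GeneMap:
    """Node -> gene-symbol mapping with a simple text round trip.

    Text format: one line per node, ``node: gene1, gene2, ...``; ``#``
    comments and blank lines ignored.
    """

    mapping: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def parse(cls, text: str) -> "GeneMap":
        mapping: dict[str, set[str]] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise GenomicsValidationError(f"gene map line {lineno}: expected 'node: genes'")
            node, genes = line.split(":", 1)
            mapping[node.strip()] = {g.strip() for g in genes.split(",") if g.strip()}
        return cls(mapping)

    def serialize(self) -> str:
        return "\n".join(
            f"{node}: {', '.join(sorted(genes))}" for node, genes in sorted(self.mapping.items())
        )
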
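"""End-to-end run orchestration: genomics -> DWNs -> screen -> scores ->
stratification -> optional validation, with TSV/JSON outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genomics import (
    FilterConfig,
    GeneMap,
    build_dwns,
    filter_functional_alterations,
    project_to_node_status,
    topology_subgroup,
)
from .network import BooleanNetwork, NodeStatusProfile, Treatment, normal_profile
from .scoring import (
    EFFICACY_CUTOFF,
    SYNERGY_Z_CUTOFF,
    PhenotypeWeights,
    ScoreRecord,
    d_score,
    effective_targets,
    r_score,
    s_score,
    synergy_zscores,
    target_class,
)
from .stratification import (
    Screen,
    enumerate_treatments,
    response_profile,
    validation_screen,
)
from .validation import ValidationSet, validate_cell_line

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; serializes losslessly to JSON."""

    network_file: str | None = None  # None -> bundled reference network
    mutations_file: str | None = None
    cna_file: str | None = None
    gene_map_file: str | None = None
    observed_file: str | None = None
    screen: str = "full"  # full | validation
    concordance_z: float = 1.0
    efficacy_cutoff: float = EFFICACY_CUTOFF
    z_cutoff: float = SYNERGY_Z_CUTOFF
    seed: int = 0
    out_dir: str = "netdyn_out"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def screen_treatments(choice: str) -> list[Treatment]:
    if choice == "full":
        return enumerate_treatments()
    if choice == "validation":
        return validation_screen()
    raise ValueError(f"unknown screen {choice!r} (expected 'full' or 'validation')")


def score_screen(
    net: BooleanNetwork,
    dwns: list[NodeStatusProfile],
    treatments: list[Treatment],
    *,
    weights: PhenotypeWeights = PhenotypeWeights(),
    screen: Screen | None = None,
) -> list[ScoreRecord]:
    """R and D scores for every (DWN, treatment) pair.

    The efficacy baseline is the untreated network with the same DNA-damage
    status as the treatment, so the D score isolates the targeted drug's
    contribution.
    """
    from .landscape import major_phenotype_or_u

    screen = screen or Screen(net)
    records = []
    for dwn in dwns:
        for t in treatments:
            land = screen.landscape(dwn, t)
            ratios = land.basin_ratios
            r_after = r_score(ratios, weights)
            rec = ScoreRecord(
                dwn_id=dwn.dwn_id or dwn.signature() or "normal",
                treatment=t.label,
                ratios=ratios,
                r_score=r_after,
                major=major_phenotype_or_u(land),
            )
            if not t.is_baseline:
                baseline = Treatment(etoposide=t.etoposide)
                r_before = r_score(screen.landscape(dwn, baseline).basin_ratios, weights)
                if r_before < weights.W_D:
                    rec.d_score = d_score(r_before, r_after, weights.W_D)
                targeted = set(t.inhibited_nodes)
                if t.inhibit_p53_mdm2_link:
                    targeted |= {"MDM2"}
                rec.target_class = target_class(targeted, dwn.altered_nodes)
            records.append(rec)
    return records


def synergy_screen(
    net: BooleanNetwork,
    dwns: list[NodeStatusProfile],
    *,
    targets: tuple[str, ...] = ("A", "B", "C", "W", "N"),
    z_cutoff: float = SYNERGY_Z_CUTOFF,
    screen: Screen | None = None,
) -> pd.DataFrame:
    """Pooled Bliss-synergy screen over all (DWN, pair, etoposide) conditions.

    D_AB, D_A and D_B are the death basin ratios of the combined and single
    treatments on the same DWN with the same etoposide setting; S scores are
    pooled across the whole run and standardized to z-scores.
    """
    from itertools import combinations

    screen = screen or Screen(net)
    rows = []
    for dwn in dwns:
        dwn_label = dwn.dwn_id or dwn.signature() or "normal"
        for etop in (False, True):
            for x, y in combinations(sorted(targets), 2):
                ta = Treatment.from_label(("E_" if etop else "") + x)
                tb = Treatment.from_label(("E_" if etop else "") + y)
                tab = Treatment.from_label(("E_" if etop else "") + "_".join(sorted((x, y))))
                s = s_score(
                    screen.death_ratio(dwn, ta),
                    screen.death_ratio(dwn, tb),
                    screen.death_ratio(dwn, tab),
                )
                rows.append({"dwn_id": dwn_label, "pair": tab.label, "s_score": s})
    df = pd.DataFrame(rows)
    if len(df) >= 2 and df["s_score"].std(ddof=1) > 0:
        zs = synergy_zscores(df["s_score"].tolist(), cutoff=z_cutoff)
        df["z"] = [z for z, _ in zs]
        df["class"] = [c for _, c in zs]
    else:
        logger.warning("synergy screen degenerate (constant S scores); z-scores omitted")
        df["z"] = float("nan")
        df["class"] = "additive"
    return df


def _records_frame(records: list[ScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dwn_id": r.dwn_id,
                "treatment": r.treatment,
                "P": r.ratios["P"],
                "A": r.ratios["A"],
                "D": r.ratios["D"],
                "U": r.ratios["U"],
                "R_score": r.r_score,
                "D_score": r.d_score,
                "major": r.major,
                "target_class": r.target_class,
            }
            for r in records
        ]
    )


@dataclass
class PipelineResult:
    config: RunConfig
    dwns: list[NodeStatusProfile] = field(default_factory=list)
    calls: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None
    synergy: pd.DataFrame | None = None
    responses: pd.DataFrame | None = None
    validation: pd.DataFrame | None = None
    counts: dict = field(default_factory=dict)


def run_pipeline(cfg: RunConfig, net: BooleanNetwork | None = None) -> PipelineResult:
    """Execute filter -> project -> DWNs -> screen -> scores -> synergy ->
    stratification (-> validation), writing all outputs under ``out_dir``."""
    from .network import parse_network
    from .synthetic import make_reference_p53_network

    if net is None:
        net = (
            parse_network(Path(cfg.network_file).read_text())
            if cfg.network_file
            else make_reference_p53_network()
        )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(cfg)
    counts = result.counts
    counts["nodes"] = net.n_nodes

    # --- genomics stage ---
    if cfg.mutations_file and cfg.cna_file and cfg.gene_map_file:
        mutations = pd.read_csv(cfg.mutations_file, sep="\t")
        cnas = pd.read_csv(cfg.cna_file, sep="\t")
        gm = GeneMap.parse(Path(cfg.gene_map_file).read_text())
        calls = filter_functional_alterations(mutations, cnas, FilterConfig(cfg.concordance_z))
        cell_lines = sorted(set(mutations["cell_line"]) | set(cnas["cell_line"]))
        profiles = project_to_node_status(calls, gm.mapping, net, cell_lines)
        dwns = build_dwns(profiles)
        result.calls = calls
        calls.to_csv(out / "alteration_calls.tsv", sep="\t", index=False)
        counts["cell_lines"] = len(cell_lines)
        counts["functional_calls"] = len(calls)
    else:
        dwns = [normal_profile(net)]
    result.dwns = dwns
    counts["dwns"] = len(dwns)

    roster = pd.DataFrame(
        [
            {
                "dwn_id": d.dwn_id or "normal",
                "n_alterations": d.n_alterations,
                "signature": d.signature(),
                "subgroup": topology_subgroup(d),
                "members": ";".join(d.member_cell_lines),
            }
            for d in dwns
        ]
    )
    roster.to_csv(out / "dwn_roster.tsv", sep="\t", index=False)

    # --- screen + scores ---
    treatments = screen_treatments(cfg.screen)
    counts["treatments"] = len(treatments)
    screen = Screen(net)
    records = score_screen(net, dwns, treatments, screen=screen)
    result.scores = _records_frame(records)
    result.scores.to_csv(out / "score_table.tsv", sep="\t", index=False)
    counts["effective_targets"] = len(
        effective_targets([r for r in records if r.d_score is not None], cfg.efficacy_cutoff)
    )

    result.synergy = synergy_screen(net, dwns, z_cutoff=cfg.z_cutoff, screen=screen)
    result.synergy.to_csv(out / "synergy_table.tsv", sep="\t", index=False)
    counts["synergy_pairs"] = len(result.synergy)

    # --- stratification ---
    rows = []
    for dwn in dwns:
        rp = response_profile(dwn, treatments, screen)
        for label, e in rp.entries.items():
            rows.append(
                {
                    "dwn_id": rp.dwn_id,
                    "treatment": label,
                    "major": e["major"],
                    "P": e["ratios"]["P"],
                    "A": e["ratios"]["A"],
                    "D": e["ratios"]["D"],
                    "critical_target": e["critical_target"],
                    "determinant_sets": ";".join(",".join(s) for s in e["determinants"]),
                    "group_index": (
                        rp.group_label(label).index
                        if e["critical_target"] is not None and e["major"] in ("P", "A", "D")
                        else None
                    ),
                }
            )
    result.responses = pd.DataFrame(rows)
    result.responses.to_csv(out / "response_profiles.tsv", sep="\t", index=False)
    observed_groups = result.responses["group_index"].dropna().nunique()
    counts["observed_response_groups"] = int(observed_groups)

    # --- optional validation ---
    if cfg.observed_file:
        observed = pd.read_csv(cfg.observed_file, sep="\t")
        by_line = {d.dwn_id or "normal": d for d in dwns}
        member_of = {m: d for d in dwns for m in d.member_cell_lines}
        vrows = []
        vscreen = Screen(net, allow_input_genotype=True)
        for cl, grp in observed.groupby("cell_line"):
            genotype = member_of.get(cl) or by_line.get(cl)
            if genotype is None:
                logger.warning("observed data for unknown cell line %r skipped", cl)
                continue
            conds = tuple(grp["treatment"])
            preds = tuple(
                vscreen.death_ratio(genotype, Treatment.from_label(c)) for c in conds
            )
            vset = ValidationSet(cl, conds, tuple(grp["death_fraction"].astype(float)), preds)
            rep = validate_cell_line(
                vset, net, genotype=genotype, screen=vscreen
            )
            vrows.append(rep.__dict__)
        result.validation = pd.DataFrame(vrows)
        result.validation.to_csv(out / "validation_report.tsv", sep="\t", index=False)

    manifest = {
        "config": cfg.__dict__,
        "counts": counts,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", json.dumps(counts, sort_keys=True))
    return result
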
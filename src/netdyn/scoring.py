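"""Phenotype, drug-efficacy and drug-synergy scores.

* R score: basin-ratio-weighted phenotype score, weights 2^0 / 2^1 / 2^2 for
  proliferation / arrest / death, so it ranges from 1 (pure proliferation)
  to 4 (pure death).
* D score: change in R score due to a treatment, normalized by the largest
  achievable change; 1 means complete conversion to death.
* S score: Bliss-independence synergy of a drug pair — observed combined
  death fraction minus 1 - (1-D_A)(1-D_B); positive is synergistic,
  negative antagonistic.
* z-scores over a pooled S-score distribution with the ±1.645 significance
  cutoff (the 5th/95th standard-normal percentiles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

R_SCORE_MAX = 4.0
EFFICACY_CUTOFF = 0.5
SYNERGY_Z_CUTOFF = 1.645


@dataclass(frozen=True)
class PhenotypeWeights:
    """Weights of the three viable phenotypes in the R score."""

    W_P: float = 1.0
    W_A: float = 2.0
    W_D: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.W_P < self.W_A < self.W_D):
            raise ValueError("weights must satisfy 0 < W_P < W_A < W_D")


def r_score(
    ratios: Mapping[str, float],
    weights: PhenotypeWeights = PhenotypeWeights(),
    *,
    strict: bool = False,
) -> float:
    """Response phenotype score P*W_P + A*W_A + D*W_D.

    ``ratios`` maps phenotype labels to basin ratios.  In strict mode the
    three viable ratios must sum to 1 (no unclassified mass).
    """
    P, A, D = (float(ratios.get(k, 0.0)) for k in ("P", "A", "D"))
    for name, v in (("P", P), ("A", A), ("D", D)):
        if v < 0:
            raise ValueError(f"basin ratio {name} must be non-negative, got {v}")
    total = P + A + D
    if total > 1 + 1e-9:
        raise ValueError(f"basin ratios sum to {total} > 1")
    if strict and abs(total - 1.0) > 1e-9:
        raise ValueError(f"strict mode requires P+A+D = 1, got {total}")
    return P * weights.W_P + A * weights.W_A + D * weights.W_D


def d_score(r_before: float, r_after: float, r_max: float = R_SCORE_MAX) -> float:
    """Drug efficacy score (R_after - R_before) / (R_max - R_before)."""
    if r_before >= r_max:
        raise ZeroDivisionError(
            f"baseline R score {r_before} already at the maximum {r_max}; efficacy undefined"
        )
    return (r_after - r_before) / (r_max - r_before)


def s_score(d_a: float, d_b: float, d_ab: float) -> float:
    """Drug synergy score: observed combined death minus the Bliss expectation.

    The two equivalent forms ``D_AB - (1 - (1-D_A)(1-D_B))`` and
    ``D_AB - D_A - D_B + D_A*D_B`` are both evaluated and asserted to agree.
    """
    for name, v in (("D_A", d_a), ("D_B", d_b), ("D_AB", d_ab)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a death fraction in [0, 1], got {v}")
    expected_additive = 1.0 - (1.0 - d_a) * (1.0 - d_b)
    s = d_ab - expected_additive
    s_expanded = d_ab - d_a - d_b + d_a * d_b
    assert math.isclose(s, s_expanded, abs_tol=1e-12)
    return s


def synergy_class(z: float, cutoff: float = SYNERGY_Z_CUTOFF) -> str:
    if z > cutoff:
        return "synergistic"
    if z < -cutoff:
        return "antagonistic"
    return "additive"


def synergy_zscores(
    s_scores: Sequence[float], cutoff: float = SYNERGY_Z_CUTOFF
) -> list[tuple[float, str]]:
    """Standardize a pooled S-score distribution and classify each pair.

    z_i = (S_i - mean) / sd with the sample (n-1) standard deviation; pairs
    beyond ±cutoff are significantly synergistic/antagonistic.
    """
    n = len(s_scores)
    if n < 2:
        raise ValueError("need at least two S scores to standardize")
    if len(set(s_scores)) == 1:
        raise ValueError("S scores have zero variance; z-scores undefined")
    mean = sum(s_scores) / n
    var = sum((s - mean) ** 2 for s in s_scores) / (n - 1)
    sd = math.sqrt(var)
    return [((s - mean) / sd, synergy_class((s - mean) / sd, cutoff)) for s in s_scores]


@dataclass
class ScoreRecord:
    """Per (DWN, treatment) scores; synergy fields filled for drug pairs."""

    dwn_id: str
    treatment: str
    ratios: Mapping[str, float]
    r_score: float
    d_score: float | None = None
    major: str | None = None
    target_class: str | None = None
    s_score: float | None = None
    z: float | None = None
    synergy: str | None = None


def target_class(treated_nodes: Iterable[str], profile_altered: Iterable[str]) -> str:
    """Classify a treatment's targets against the DWN's altered nodes.

    ``altered`` if every targeted node carries a genomic alteration,
    ``wild_type`` if none does, ``mixed`` otherwise.  Treatments with no
    node target (link inhibitor or etoposide alone) count as wild-type:
    neither MDM2 nor p53 is altered in the screen's DWNs by construction.
    """
    targets = set(treated_nodes)
    altered = set(profile_altered)
    if not targets:
        return "wild_type"
    hit = targets & altered
    if hit == targets:
        return "altered"
    if not hit:
        return "wild_type"
    return "mixed"


def effective_targets(
    records: Iterable[ScoreRecord], cutoff: float = EFFICACY_CUTOFF
) -> list[ScoreRecord]:
    """Treatments with D score above the cutoff that mainly induce death."""
    out = []
    for rec in records:
        if rec.d_score is None or rec.major is None:
            raise ValueError(f"record {rec.dwn_id}/{rec.treatment} lacks D score or major phenotype")
        if rec.d_score > cutoff and rec.major == "D":
            out.append(rec)
    return out
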
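"""Validation statistics: RMSE, exhaustive shuffle nulls, correlation, rank-sum.

Model predictions (cell-death basin ratios) are compared with observed
cell-death fractions per cell line over a fixed list of treatment
conditions.  The null model enumerates *all* networks carrying the same
number of alterations as the genotype, with alteration locations and signs
randomized: C(N, k) * 2^k profiles for k alterations on an N-node network
(480 and 4480 for k = 2, 3 on the 16-node reference network).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

import numpy as np
from scipy import stats

from .network import BooleanNetwork, NodeStatusProfile, Treatment
from .stratification import Screen


@dataclass(frozen=True)
class ValidationSet:
    """Aligned observed/predicted death fractions for one cell line."""

    cell_line: str
    conditions: tuple[str, ...]
    observed: tuple[float, ...]
    predicted: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.conditions)
        if len(self.observed) != n or len(self.predicted) != n:
            raise ValueError("observed and predicted must align with the condition list")
        if n < 1:
            raise ValueError("need at least one condition")


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean square error sqrt(mean((O_i - P_i)^2))."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} vs {p.shape}")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def rmse_of(v: ValidationSet) -> float:
    return rmse(v.observed, v.predicted)


def enumerate_shuffled_profiles(net: BooleanNetwork, k: int) -> list[NodeStatusProfile]:
    """All profiles with exactly k altered nodes (each independently A or I).

    This is the exhaustive shuffle null: alteration count preserved,
    locations and signs enumerated — C(N, k) * 2^k profiles, duplicates
    impossible by construction, deterministic order.  The enumeration ranges
    over every node including the stimulus input.
    """
    if not 1 <= k <= net.n_nodes:
        raise ValueError(f"alteration count k={k} out of range 1..{net.n_nodes}")
    out = []
    for nodes in combinations(net.node_names, k):
        for signs in product("AI", repeat=k):
            status = {n: "N" for n in net.node_names}
            status.update(zip(nodes, signs))
            out.append(NodeStatusProfile(status))
    return out


def null_predictions(
    net: BooleanNetwork,
    profiles: list[NodeStatusProfile],
    treatments: list[Treatment],
    *,
    screen: Screen | None = None,
) -> np.ndarray:
    """Predicted death ratios R[j, i] for null network j under condition i.

    Input-node alterations (present in the exhaustive enumeration) override
    the etoposide setting of the treatment.
    """
    screen = screen or Screen(net, allow_input_genotype=True)
    return np.array(
        [[screen.death_ratio(p, t) for t in treatments] for p in profiles]
    )


def rmse_null(observed: Sequence[float], null_preds: np.ndarray) -> float:
    """Mean over null networks of the per-network RMSE (not RMSE of means)."""
    o = np.asarray(observed, dtype=float)
    r = np.asarray(null_preds, dtype=float)
    if r.ndim != 2 or r.shape[1] != o.shape[0]:
        raise ValueError(f"null predictions of shape {r.shape} do not align with {o.shape[0]} conditions")
    return float(np.mean(np.sqrt(np.mean((o[None, :] - r) ** 2, axis=1))))


def per_null_rmses(observed: Sequence[float], null_preds: np.ndarray) -> np.ndarray:
    o = np.asarray(observed, dtype=float)
    return np.sqrt(np.mean((o[None, :] - np.asarray(null_preds, dtype=float)) ** 2, axis=1))


def pearson(v: ValidationSet) -> tuple[float, float]:
    """Pearson correlation between observed and predicted, with two-sided p."""
    o = np.asarray(v.observed, dtype=float)
    p = np.asarray(v.predicted, dtype=float)
    if len(o) < 3:
        raise ValueError("Pearson correlation needs at least three conditions")
    if np.std(o) == 0 or np.std(p) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    r, pval = stats.pearsonr(o, p)
    return float(r), float(pval)


def compare_to_null(
    per_model_errors: Sequence[float], per_null_errors: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value (model vs. null error samples).

    Exact enumeration for small tie-free samples, normal approximation with
    tie correction otherwise.
    """
    a = np.asarray(per_model_errors, dtype=float)
    b = np.asarray(per_null_errors, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both error samples must be nonempty")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0  # identical samples: the null of no shift is exactly satisfied
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


@dataclass
class ValidationReport:
    """Per-cell-line validation summary."""

    cell_line: str
    n_conditions: int
    rmse: float
    pearson_r: float
    pearson_p: float
    null_mean_rmse: float | None = None
    null_median_rmse: float | None = None
    n_null: int | None = None


def validate_cell_line(
    v: ValidationSet,
    net: BooleanNetwork | None = None,
    *,
    genotype: NodeStatusProfile | None = None,
    treatments: list[Treatment] | None = None,
    screen: Screen | None = None,
) -> ValidationReport:
    """RMSE and Pearson r for one cell line, plus the exhaustive shuffle-null
    RMSE when the genotype (and network) are supplied."""
    r, p = pearson(v)
    report = ValidationReport(
        cell_line=v.cell_line,
        n_conditions=len(v.conditions),
        rmse=rmse_of(v),
        pearson_r=r,
        pearson_p=p,
    )
    if genotype is not None and genotype.n_alterations > 0 and net is not None:
        nulls = enumerate_shuffled_profiles(net, genotype.n_alterations)
        if treatments is None:
            treatments = [Treatment.from_label(c) for c in v.conditions]
        preds = null_predictions(net, nulls, treatments, screen=screen)
        errs = per_null_rmses(v.observed, preds)
        report.null_mean_rmse = float(np.mean(errs))
        report.null_median_rmse = float(np.median(errs))
        report.n_null = len(nulls)
    return report
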
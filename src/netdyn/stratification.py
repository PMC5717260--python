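"""Treatment-screen enumeration, critical targets/determinants, response groups.

A *critical target* is a drugged node/link whose inhibition changes the
network's major response phenotype relative to the untreated network (with
the same DNA-damage status).  A *critical determinant* is an
inclusion-minimal subset of a genotype's alterations that suffices to make
the drug response differ from the unaltered (normal) network's response.
DWN x treatment pairs are classified into response groups by the triple
(major phenotype, has critical target, has critical determinant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .landscape import (
    AttractorLandscape,
    compute_landscape,
    major_phenotype,
    major_phenotype_or_u,
)
from .network import (
    BooleanNetwork,
    NodeStatusProfile,
    Treatment,
    build_clamps,
    normal_profile,
)

#: the five druggable components of the reference screen, by letter code
SCREEN_TARGET_LETTERS = ("A", "B", "C", "W", "N")
#: the experimentally assayed subset
VALIDATION_TARGET_LETTERS = ("B", "W", "N")


def _treatment_from_letters(letters: tuple[str, ...], etoposide: bool) -> Treatment:
    base = Treatment.from_label("_".join(sorted(letters))) if letters else Treatment()
    return Treatment(base.inhibited_nodes, base.inhibit_p53_mdm2_link, etoposide)


def enumerate_treatments(
    targets: tuple[str, ...] = SCREEN_TARGET_LETTERS,
    *,
    include_pairs: bool = True,
    include_baseline: bool = True,
    include_no_etoposide: bool = True,
) -> list[Treatment]:
    """The standard perturbation screen, in canonical order.

    With the five default targets: baseline, etoposide alone, 5 singles,
    5 etoposide+single, 10 pairs, 10 etoposide+pair — 32 conditions.
    """
    singles = [(t,) for t in sorted(targets)]
    pairs = [tuple(sorted(p)) for p in combinations(sorted(targets), 2)] if include_pairs else []
    out: list[Treatment] = []
    if include_baseline:
        out.append(Treatment())
    out.append(Treatment(etoposide=True))
    if include_no_etoposide:
        out.extend(_treatment_from_letters(s, False) for s in singles)
    out.extend(_treatment_from_letters(s, True) for s in singles)
    if include_no_etoposide:
        out.extend(_treatment_from_letters(p, False) for p in pairs)
    out.extend(_treatment_from_letters(p, True) for p in pairs)
    return out


def validation_screen() -> list[Treatment]:
    """The 13 experimentally assayed conditions: etoposide alone plus the
    {BCL2, Wip1, p53-MDM2} singles and pairs, each with and without etoposide."""
    return [t for t in enumerate_treatments(VALIDATION_TARGET_LETTERS) if t.label != "untreated"]


class Screen:
    """Landscape runner with memoization over (genotype, treatment) pairs."""

    def __init__(self, net: BooleanNetwork, *, allow_input_genotype: bool = False):
        self.net = net
        self.allow_input_genotype = allow_input_genotype
        self._cache: dict[tuple[str, str], AttractorLandscape] = {}

    def landscape(self, profile: NodeStatusProfile, treatment: Treatment) -> AttractorLandscape:
        key = (profile.signature(), treatment.label)
        if key not in self._cache:
            clamps = build_clamps(
                self.net, profile, treatment, allow_input_genotype=self.allow_input_genotype
            )
            self._cache[key] = compute_landscape(self.net, clamps)
        return self._cache[key]

    def major(self, profile: NodeStatusProfile, treatment: Treatment) -> str:
        return major_phenotype_or_u(self.landscape(profile, treatment))

    def death_ratio(self, profile: NodeStatusProfile, treatment: Treatment) -> float:
        return self.landscape(profile, treatment).death_ratio


def critical_target(
    dwn: NodeStatusProfile, treatment: Treatment, net: BooleanNetwork | Screen
) -> bool:
    """True iff the treatment changes the DWN's major phenotype relative to
    the untreated network with the same DNA-damage status."""
    if treatment.is_baseline:
        raise ValueError("critical-target test is undefined for the untreated baseline")
    screen = net if isinstance(net, Screen) else Screen(net)
    baseline = Treatment(etoposide=treatment.etoposide)
    return screen.major(dwn, treatment) != screen.major(dwn, baseline)


def critical_determinants(
    dwn: NodeStatusProfile, treatment: Treatment, net: BooleanNetwork | Screen
) -> list[tuple[str, ...]]:
    """Inclusion-minimal alteration subsets reproducing the DWN's response.

    Empty when cancer and normal networks share the major phenotype under
    the treatment (no critical determinant).  Otherwise subsets of the DWN's
    alterations are enumerated in increasing size; a subset is a determinant
    iff the network altered only by it shows the DWN's major phenotype under
    the treatment, and only inclusion-minimal determinants are reported
    (sorted by size, then lexicographically).
    """
    screen = net if isinstance(net, Screen) else Screen(net)
    cancer_major = screen.major(dwn, treatment)
    if cancer_major == screen.major(normal_profile(screen.net), treatment):
        return []
    altered = dwn.altered_nodes
    found: list[tuple[str, ...]] = []
    for size in range(1, len(altered) + 1):
        for subset in combinations(altered, size):
            if any(set(m) <= set(subset) for m in found):
                continue  # superset of a known minimal determinant
            if screen.major(dwn.restricted_to(subset), treatment) == cancer_major:
                found.append(tuple(sorted(subset)))
    return sorted(found, key=lambda s: (len(s), s))


PHENOTYPE_ORDER = ("P", "A", "D")


@dataclass(frozen=True)
class ResponseGroupLabel:
    """Triple classifying one DWN x treatment response, with a fixed index."""

    major: str
    has_critical_target: bool
    has_critical_determinant: bool

    def __post_init__(self) -> None:
        if self.major not in PHENOTYPE_ORDER:
            raise ValueError(f"major phenotype must be one of {PHENOTYPE_ORDER}")

    @property
    def index(self) -> int:
        """Deterministic 1..12 index over the (phenotype, flag, flag) grid."""
        return (
            4 * PHENOTYPE_ORDER.index(self.major)
            + 2 * int(self.has_critical_target)
            + int(self.has_critical_determinant)
            + 1
        )


@dataclass
class ResponseProfile:
    """Per-treatment response summary of one DWN across a screen."""

    dwn_id: str
    profile: NodeStatusProfile
    entries: dict[str, dict] = field(default_factory=dict)  # treatment label -> summary

    def group_label(self, treatment_label: str) -> ResponseGroupLabel:
        e = self.entries[treatment_label]
        return ResponseGroupLabel(
            e["major"], e["critical_target"], bool(e["determinants"])
        )


def response_profile(
    dwn: NodeStatusProfile,
    treatments: list[Treatment],
    net: BooleanNetwork | Screen,
) -> ResponseProfile:
    """Run a DWN through a treatment screen, collecting basin ratios, major
    phenotype, critical-target flag and critical determinants per condition."""
    screen = net if isinstance(net, Screen) else Screen(net)
    out = ResponseProfile(dwn.dwn_id or dwn.signature() or "normal", dwn)
    for t in treatments:
        land = screen.landscape(dwn, t)
        entry = {
            "ratios": land.basin_ratios,
            "major": major_phenotype_or_u(land),
            "critical_target": None,
            "determinants": [],
        }
        if not t.is_baseline:
            entry["critical_target"] = critical_target(dwn, t, screen)
            if dwn.n_alterations:
                entry["determinants"] = critical_determinants(dwn, t, screen)
        out.entries[t.label] = entry
    return out


def response_group(profile: ResponseProfile, treatment: Treatment) -> ResponseGroupLabel:
    """Response-group label of one screened condition of a DWN."""
    if treatment.label not in profile.entries:
        raise KeyError(f"treatment {treatment.label!r} was not screened for {profile.dwn_id}")
    return profile.group_label(treatment.label)


def observed_groups(profiles: list[ResponseProfile]) -> dict[ResponseGroupLabel, int]:
    """Count distinct observed response-group labels over all screened
    (DWN, non-baseline treatment) pairs."""
    counts: dict[ResponseGroupLabel, int] = {}
    for rp in profiles:
        for label, entry in rp.entries.items():
            if entry["critical_target"] is None or entry["major"] not in PHENOTYPE_ORDER:
                continue
            g = rp.group_label(label)
            counts[g] = counts.get(g, 0) + 1
    return counts
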
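"""Treatment screen, critical targets, critical determinants, response groups."""

from itertools import chain, combinations

import pytest

from netdyn.network import Treatment, normal_profile
from netdyn.stratification import (
    ResponseGroupLabel,
    Screen,
    critical_determinants,
    critical_target,
    enumerate_treatments,
    observed_groups,
    response_group,
    response_profile,
    validation_screen,
)
from netdyn.synthetic import FixtureConfig, synthetic_dwn_panel


class TestEnumerateTreatments:
    def test_full_screen_has_32_conditions_including_baseline(self):
        ts = enumerate_treatments()
        assert len(ts) == 32
        labels = [t.label for t in ts]
        assert len(set(labels)) == 32
        assert labels[0] == "untreated" and labels[1] == "E"

    def test_screen_composition(self):
        labels = [t.label for t in enumerate_treatments()]
        singles = [l for l in labels if len(l) == 1 and l != "E"]
        e_singles = [l for l in labels if l.startswith("E_") and len(l) == 3]
        pairs = [l for l in labels if "_" in l and not l.startswith("E_")]
        e_pairs = [l for l in labels if l.startswith("E_") and len(l) == 5]
        assert (len(singles), len(e_singles), len(pairs), len(e_pairs)) == (5, 5, 10, 10)

    def test_validation_screen_has_13_conditions(self):
        labels = [t.label for t in validation_screen()]
        assert len(labels) == 13
        assert "E" in labels and "untreated" not in labels

    def test_pair_label_is_alphabetical_with_e_prefix(self):
        t = Treatment(frozenset({"Wip1"}), inhibit_p53_mdm2_link=True, etoposide=True)
        assert t.label == "E_N_W"
        assert t.label in [x.label for x in enumerate_treatments()]


class TestCriticalTarget:
    def test_treatment_that_flips_major_phenotype(self, ref_net, make_profile):
        # p14ARF-null network: arrest under damage, death once Wip1 is blocked
        dwn = make_profile(ref_net, p14ARF="I")
        screen = Screen(ref_net)
        assert screen.major(dwn, Treatment.from_label("E")) == "A"
        assert screen.major(dwn, Treatment.from_label("E_W")) == "D"
        assert critical_target(dwn, Treatment.from_label("E_W"), screen)

    def test_ineffective_treatment_is_not_critical(self, ref_net, make_profile):
        # inhibiting an already-inactive node leaves the landscape unchanged
        dwn = make_profile(ref_net, Wip1="I")
        assert not critical_target(dwn, Treatment.from_label("E_W"), ref_net)

    def test_baseline_is_rejected(self, ref_net, make_profile):
        with pytest.raises(ValueError):
            critical_target(make_profile(ref_net), Treatment(), ref_net)

    def test_comparison_keeps_etoposide_status_fixed(self, ref_net):
        # the E_W death response of the normal network is an etoposide-matched
        # comparison: E -> A vs E_W -> D (critical), while W alone changes
        # nothing relative to the undamaged baseline
        screen = Screen(ref_net)
        normal = normal_profile(ref_net)
        assert critical_target(normal, Treatment.from_label("E_W"), screen)
        assert not critical_target(normal, Treatment.from_label("W"), screen)


def brute_force_determinants(dwn, treatment, screen):
    """Independent oracle: test every subset, then keep inclusion-minimal ones."""
    cancer = screen.major(dwn, treatment)
    if cancer == screen.major(normal_profile(screen.net), treatment):
        return []
    altered = dwn.altered_nodes
    all_subsets = chain.from_iterable(
        combinations(altered, r) for r in range(1, len(altered) + 1)
    )
    hits = [
        tuple(sorted(s))
        for s in all_subsets
        if screen.major(dwn.restricted_to(s), treatment) == cancer
    ]
    minimal = [
        s for s in hits if not any(set(o) < set(s) for o in hits)
    ]
    return sorted(set(minimal), key=lambda s: (len(s), s))


class TestCriticalDeterminants:
    def test_no_determinant_when_cancer_matches_normal(self, ref_net, make_profile):
        dwn = make_profile(ref_net, BCL2="A")
        screen = Screen(ref_net)
        t = Treatment.from_label("E_B")
        assert screen.major(dwn, t) == screen.major(normal_profile(ref_net), t)
        assert critical_determinants(dwn, t, screen) == []

    def test_single_alteration_determinant(self, ref_net, make_profile):
        # Wip1 hyperactivation alone flips the damage response away from normal
        dwn = make_profile(ref_net, Wip1="A", BCL2="A")
        dets = critical_determinants(dwn, Treatment.from_label("E"), ref_net)
        assert dets == [("Wip1",)]

    def test_normal_network_has_no_determinants(self, ref_net):
        screen = Screen(ref_net)
        for t in validation_screen():
            assert critical_determinants(normal_profile(ref_net), t, screen) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_minimality_against_brute_force(self, ref_net, seed):
        cfg = FixtureConfig(seed=seed, n_dwns=3, alteration_counts=(2, 3, 4, 5),
                            alteration_probs=(0.3, 0.3, 0.2, 0.2))
        screen = Screen(ref_net)
        for dwn in synthetic_dwn_panel(ref_net, cfg):
            for label in ("E", "E_W", "E_N", "E_B_N"):
                t = Treatment.from_label(label)
                dets = critical_determinants(dwn, t, screen)
                assert dets == brute_force_determinants(dwn, t, screen)
                for s in dets:  # no proper subset may reproduce the phenotype
                    for r in range(1, len(s)):
                        for sub in combinations(s, r):
                            assert screen.major(
                                dwn.restricted_to(sub), t
                            ) != screen.major(dwn, t)


class TestResponseGroups:
    def test_label_index_is_deterministic(self):
        a = ResponseGroupLabel("D", True, True)
        b = ResponseGroupLabel("D", True, True)
        assert a == b and a.index == b.index
        assert ResponseGroupLabel("P", False, False).index == 1
        assert ResponseGroupLabel("D", True, True).index == 12

    def test_twelve_possible_labels(self):
        idx = {
            ResponseGroupLabel(m, ct, cd).index
            for m in "PAD" for ct in (False, True) for cd in (False, True)
        }
        assert idx == set(range(1, 13))

    def test_profile_and_group_round_trip(self, ref_net, make_profile):
        dwn = make_profile(ref_net, p14ARF="I")
        treatments = [Treatment.from_label(l) for l in ("untreated", "E", "E_W", "E_B")]
        rp = response_profile(dwn, treatments, ref_net)
        assert set(rp.entries) == {"untreated", "E", "E_W", "E_B"}
        g = response_group(rp, Treatment.from_label("E_W"))
        assert g.major == "D" and g.has_critical_target
        with pytest.raises(KeyError):
            response_group(rp, Treatment.from_label("E_N_W"))

    def test_observed_group_count_is_bounded(self, ref_net):
        cfg = FixtureConfig(seed=11, n_dwns=8)
        screen = Screen(ref_net)
        treatments = [Treatment.from_label(l) for l in ("E", "E_B", "E_W", "E_N", "E_N_W")]
        profiles = [
            response_profile(d, treatments, screen)
            for d in synthetic_dwn_panel(ref_net, cfg)
        ]
        groups = observed_groups(profiles)
        assert 1 <= len(groups) <= 12
        # etoposide alone is a damage-matched baseline, not a drugged condition
        assert sum(groups.values()) <= 8 * 4

    def test_same_subgroup_can_split_across_response_groups(self, ref_net, make_profile):
        """Network dynamics, not topology subgroup, decide the drug response."""
        from netdyn.genomics import topology_subgroup

        a = make_profile(ref_net, p14ARF="I")
        b = make_profile(ref_net, p14ARF="I", AKT="A")
        assert topology_subgroup(a) == topology_subgroup(b) == 1
        t = Treatment.from_label("E_W")
        screen = Screen(ref_net)
        ga = ResponseGroupLabel(screen.major(a, t), critical_target(a, t, screen),
                                bool(critical_determinants(a, t, screen)))
        gb = ResponseGroupLabel(screen.major(b, t), critical_target(b, t, screen),
                                bool(critical_determinants(b, t, screen)))
        assert ga != gb
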
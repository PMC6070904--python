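"""H-bond detection, substate classification, wobble relaxation."""
import numpy as np
import pytest

from iupair.basegeom import ReferenceFrame, rebuild_atoms
from iupair.helical import flip_frame
from iupair.pairing import (HBond, SubstateRecord, build_wobble_pair,
                            classify_substate, detect_hbonds,
                            population_table)

from conftest import random_frame


def _bond_pairs(hbonds):
    out = set()
    for hb in hbonds:
        if hb.donor[0] == 1:
            out.add((hb.donor[1], hb.acceptor[1]))
        else:
            out.add((hb.acceptor[1], hb.donor[1]))
    return out


def _wc_pair(templates, code1, code2):
    a1 = rebuild_atoms(ReferenceFrame.identity(), templates[code1])
    a2 = rebuild_atoms(flip_frame(ReferenceFrame.identity()),
                       templates[code2])
    return a1, a2


class TestDetectHbonds:
    def test_ideal_au_watson_crick_pattern(self, templates):
        a, u = _wc_pair(templates, "A", "U")
        bonds = _bond_pairs(detect_hbonds(a, "A", u, "U"))
        assert bonds == {("N6", "O4"), ("N1", "N3")}

    def test_relaxed_iu_wobble_pattern(self, relaxed_iu):
        hb = detect_hbonds(relaxed_iu.atoms_b1, "I", relaxed_iu.atoms_b2,
                           "U", include_weak_donors=True)
        assert _bond_pairs(hb) == {("N1", "O2"), ("O6", "N3")}

    def test_every_stored_bond_satisfies_cutoffs(self, relaxed_iu):
        for hb in detect_hbonds(relaxed_iu.atoms_b1, "I",
                                relaxed_iu.atoms_b2, "U",
                                include_weak_donors=True):
            assert hb.distance <= 3.4
            assert hb.angle >= 135.0

    def test_distant_residues_give_no_bonds(self, templates):
        a, u = _wc_pair(templates, "A", "U")
        far = {k: v + np.array([10.0, 0, 0]) for k, v in u.items()}
        assert detect_hbonds(a, "A", far, "U") == []

    def test_invariant_under_global_rigid_transform(self, templates):
        rng = np.random.default_rng(4)
        a, u = _wc_pair(templates, "A", "U")
        g = random_frame(rng)
        hb0 = detect_hbonds(a, "A", u, "U")
        hb1 = detect_hbonds({k: g.apply(v) for k, v in a.items()}, "A",
                            {k: g.apply(v) for k, v in u.items()}, "U")
        assert len(hb0) == len(hb1)
        for b0, b1 in zip(hb0, hb1):
            assert b0.donor == b1.donor and b0.acceptor == b1.acceptor
            assert b0.distance == pytest.approx(b1.distance, abs=1e-9)
            assert b0.angle == pytest.approx(b1.angle, abs=1e-7)

    def test_missing_declared_hydrogen_fails_naming_it(self, templates):
        a, u = _wc_pair(templates, "A", "U")
        del u["H3"]
        with pytest.raises(ValueError, match="H3"):
            detect_hbonds(a, "A", u, "U")

    def test_weak_c2_donor_only_when_requested(self, templates, relaxed_iu):
        # move uracil so only C2-H2...O2 could reach: use the D-substate
        from iupair.ensemble import SUBSTATE_PAIR_PARAMS
        from iupair.helical import PairParams, compose_pair
        f1, f2 = compose_pair(ReferenceFrame.identity(),
                              PairParams(0, *SUBSTATE_PAIR_PARAMS["D"]))
        aI = rebuild_atoms(f1, templates["I"])
        aU = rebuild_atoms(f2, templates["U"])
        strong = _bond_pairs(detect_hbonds(aI, "I", aU, "U"))
        weak = _bond_pairs(detect_hbonds(aI, "I", aU, "U",
                                         include_weak_donors=True))
        assert ("C2", "O2") not in strong
        assert ("C2", "O2") in weak


def _mk(donor, acceptor, d=2.9, ang=160.0, donor_slot=1):
    h = {"N1": "H1", "C2": "H2", "N3": "H3"}[donor]
    aslot = 2 if donor_slot == 1 else 1
    return HBond((donor_slot, donor), (donor_slot, h), (aslot, acceptor),
                 d, ang)


class TestClassifier:
    N1_O2 = _mk("N1", "O2")
    O6_N3 = _mk("N3", "O6", donor_slot=2)
    C2_O2 = _mk("C2", "O2")
    N1_O4 = _mk("N1", "O4")
    C2_O4 = _mk("C2", "O4")

    @pytest.mark.parametrize("bonds,expected", [
        ([N1_O2, O6_N3], "A"),
        ([O6_N3], "B"),
        ([N1_O2], "C"),
        ([C2_O2], "D"),
        ([N1_O4], "E"),
        ([N1_O4, C2_O4], "E"),          # bifurcated stays E
        ([C2_O4], "F"),
        ([], "other"),
        ([C2_O2, N1_O4], "D"),          # priority: D before E
        ([O6_N3, C2_O4], "B"),          # priority: B before F
    ])
    def test_pattern_table(self, bonds, expected):
        assert classify_substate(bonds) == expected

    def test_every_frame_gets_exactly_one_label(self, uii_small):
        from iupair.workflows import substate_records
        recs = substate_records(uii_small, 7)
        assert len(recs) == uii_small.n_frames
        pops = population_table(recs)
        assert sum(pops.percentages.values()) == pytest.approx(100.0,
                                                               abs=0.1)


class TestWobbleRelaxation:
    def test_relaxed_pair_is_substate_a(self, relaxed_iu):
        hb = detect_hbonds(relaxed_iu.atoms_b1, "I", relaxed_iu.atoms_b2,
                           "U", include_weak_donors=True)
        assert classify_substate(hb) == "A"

    def test_relaxation_converged(self, relaxed_iu):
        assert relaxed_iu.gradient_norm < 1e-3

    def test_stiff_restraints_reach_target_lengths(self):
        wp = build_wobble_pair(restraint_k=5000.0, duplex_context=False)
        assert wp.restraint_distances[0] == pytest.approx(2.9, abs=0.01)
        assert wp.restraint_distances[1] == pytest.approx(2.9, abs=0.01)

    def test_unknown_pair_type_rejected(self):
        with pytest.raises(ValueError, match="pair type"):
            build_wobble_pair(pair_type="GU")


class TestPopulations:
    def test_percentage_arithmetic(self):
        recs = [SubstateRecord(i, "A", (), (7, 34)) for i in range(9)]
        recs.append(SubstateRecord(9, "B", (), (7, 34)))
        pops = population_table(recs)
        assert pops.percentages["A"] == pytest.approx(90.0)
        assert pops.percentages["B"] == pytest.approx(10.0)

    def test_all_same_label_is_100_percent(self):
        recs = [SubstateRecord(i, "A", (), (7, 34)) for i in range(5)]
        assert population_table(recs).percentages["A"] == 100.0

    def test_empty_input_fails(self):
        with pytest.raises(ValueError, match="at least one"):
            population_table([])

    def test_mixed_pairs_rejected(self):
        recs = [SubstateRecord(0, "A", (), (7, 34)),
                SubstateRecord(1, "A", (), (11, 30))]
        with pytest.raises(ValueError, match="mix"):
            population_table(recs)
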
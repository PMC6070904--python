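"""Vacuum nonbonded energies: oracle equivalence and dissection identities."""
import numpy as np
import pytest

from iupair.basegeom import ReferenceFrame, rebuild_atoms
from iupair.energetics import (COULOMB_CONSTANT, AtomGroup, EnergyRecord,
                               energy_by_substate, formation_energy,
                               interaction_energy, step_energies)
from iupair.ensemble import build_ideal_duplex, sequence_spec
from iupair.helical import flip_frame


def brute_force_energy(g1: AtomGroup, g2: AtomGroup) -> float:
    """Naive double loop over atom pairs -- the independent oracle."""
    e = 0.0
    for i in range(len(g1)):
        for j in range(len(g2)):
            r = np.linalg.norm(g1.coords[i] - g2.coords[j])
            e += COULOMB_CONSTANT * g1.charges[i] * g2.charges[j] / r
            rmin = g1.rmin_half[i] + g2.rmin_half[j]
            eps = np.sqrt(g1.epsilon[i] * g2.epsilon[j])
            s6 = (rmin / r) ** 6
            e += eps * (s6 * s6 - 2 * s6)
    return e


def _random_group(rng, n):
    return AtomGroup(rng.uniform(-5, 5, size=(n, 3)),
                     rng.uniform(-0.9, 0.9, size=n),
                     rng.uniform(0.5, 2.0, size=n),
                     rng.uniform(0.01, 0.3, size=n))


class TestInteractionEnergy:
    def test_matches_brute_force_oracle(self, templates):
        rng = np.random.default_rng(0)
        for _ in range(5):
            g1 = _random_group(rng, rng.integers(5, 50))
            g2 = _random_group(rng, rng.integers(5, 50))
            g2 = AtomGroup(g2.coords + 8.0, g2.charges, g2.rmin_half,
                           g2.epsilon)
            assert interaction_energy(g1, g2) == pytest.approx(
                brute_force_energy(g1, g2), abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        g1 = _random_group(rng, 20)
        g2 = _random_group(rng, 15)
        g2 = AtomGroup(g2.coords + 10.0, g2.charges, g2.rmin_half,
                       g2.epsilon)
        assert interaction_energy(g1, g2) == pytest.approx(
            interaction_energy(g2, g1), abs=1e-12)

    def test_partition_additivity(self):
        rng = np.random.default_rng(2)
        g1 = _random_group(rng, 12)
        g2 = _random_group(rng, 21)
        g2 = AtomGroup(g2.coords + 10.0, g2.charges, g2.rmin_half,
                       g2.epsilon)
        ga = AtomGroup(g2.coords[:10], g2.charges[:10], g2.rmin_half[:10],
                       g2.epsilon[:10])
        gb = AtomGroup(g2.coords[10:], g2.charges[10:], g2.rmin_half[10:],
                       g2.epsilon[10:])
        assert interaction_energy(g1, g2) == pytest.approx(
            interaction_energy(g1, ga) + interaction_energy(g1, gb),
            abs=1e-10)

    def test_distant_neutral_atoms_near_zero(self):
        g1 = AtomGroup(np.zeros((1, 3)), np.zeros(1), np.array([1.7]),
                       np.array([0.1]))
        g2 = AtomGroup(np.array([[50.0, 0, 0]]), np.zeros(1),
                       np.array([1.7]), np.array([0.1]))
        assert abs(interaction_energy(g1, g2)) < 1e-6

    def test_ideal_au_pair_energy_scale(self, templates):
        g1 = AtomGroup.from_template(templates["A"])
        g2 = AtomGroup.from_template(templates["U"],
                                     flip_frame(ReferenceFrame.identity()))
        e = interaction_energy(g1, g2)
        assert -14.0 < e < -8.0


class TestStepEnergies:
    def test_total_is_stack_plus_both_hbond_terms(self):
        rng = np.random.default_rng(3)
        gs = []
        for k in range(4):
            g = _random_group(rng, 10)
            gs.append(AtomGroup(g.coords + 6.0 * k, g.charges,
                                g.rmin_half, g.epsilon))
        rec = step_energies((gs[0], gs[1]), (gs[2], gs[3]))
        assert rec.e_total_step == pytest.approx(
            rec.e_stack + rec.e_hbond_pair1 + rec.e_hbond_pair2, abs=1e-9)

    def test_clash_flag_raised_on_overlap(self):
        g1 = AtomGroup(np.zeros((1, 3)), np.array([0.1]), np.array([1.0]),
                       np.array([0.1]))
        g2 = AtomGroup(np.array([[0.1, 0, 0]]), np.array([0.1]),
                       np.array([1.0]), np.array([0.1]))
        g3 = AtomGroup(g1.coords + [0, 0, 3.3], g1.charges, g1.rmin_half,
                       g1.epsilon)
        g4 = AtomGroup(g2.coords + [0, 0, 3.3], g2.charges, g2.rmin_half,
                       g2.epsilon)
        rec = step_energies((g1, g2), (g3, g4))
        assert rec.clash


class TestFormationEnergy:
    def test_mismatched_strand_lengths_fail(self):
        g = AtomGroup(np.zeros((1, 3)), np.zeros(1), np.ones(1),
                      np.ones(1) * 0.1)
        with pytest.raises(ValueError, match="complementary"):
            formation_energy([g, g], [g])

    def test_far_apart_strands_near_zero(self, templates):
        g1 = AtomGroup.from_template(templates["A"])
        moved = AtomGroup(g1.coords + 500.0, g1.charges, g1.rmin_half,
                          g1.epsilon)
        fe = formation_energy([g1], [moved])
        assert abs(fe.delta_e_formation) < 0.05

    def test_magnitude_grows_with_duplex_length(self):
        """Cross-strand energy of nested wt sub-duplexes becomes
        monotonically more negative with length."""
        from iupair.energetics import AtomGroup
        ens = build_ideal_duplex(sequence_spec("wt"))
        spec = ens.spec
        s1, s2 = [], []
        for pos in range(1, spec.n_pairs + 1):
            a1, a2 = ens.pair_atoms(0, pos)
            t1 = ens.templates[spec.strand1[pos - 1]]
            t2 = ens.templates[spec.pair_codes(pos)[1]]
            s1.append(AtomGroup.from_atoms(a1, t1))
            s2.append(AtomGroup.from_atoms(a2, t2))
        prev = 0.0
        for length in range(4, spec.n_pairs + 1, 4):
            e = formation_energy(s1[:length], s2[:length]).delta_e_formation
            assert e < prev
            prev = e


class TestEnergyBySubstate:
    def test_label_shuffle_leaves_pooled_distribution_unchanged(self):
        rng = np.random.default_rng(4)
        recs = [EnergyRecord(i, rng.normal(-11, 1), -11.0, -3.0,
                             substate_label=rng.choice(["A", "B"]))
                for i in range(500)]
        df = energy_by_substate(recs)
        labels = [r.substate_label for r in recs]
        shuffled = list(rng.permutation(labels))
        df2 = energy_by_substate(recs, labels=shuffled)
        total = (df["e_hbond"]["count"] * df["e_hbond"]["mean"]).sum()
        total2 = (df2["e_hbond"]["count"] * df2["e_hbond"]["mean"]).sum()
        assert total == pytest.approx(total2, rel=1e-12)
        # and the shuffled per-label means collapse toward the pooled mean
        pooled = total / 500
        assert abs(df2["e_hbond"]["mean"]["A"] - pooled) < \
            abs(df["e_hbond"]["mean"]["A"] - pooled) + 0.5

    def test_mismatched_label_series_fails(self):
        recs = [EnergyRecord(0, -1.0, -1.0, -1.0)]
        with pytest.raises(ValueError, match="match"):
            energy_by_substate(recs, labels=["A", "B"])

    def test_ab_mixture_is_bimodal_with_a_more_stable(self, templates):
        """Pure-substate relaxed geometries: the two-bond A state binds
        more strongly than the one-bond B and C states."""
        from iupair.ensemble import SUBSTATE_PAIR_PARAMS
        from iupair.helical import PairParams, compose_pair
        from iupair.basegeom import ReferenceFrame
        energies = {}
        for lab in ("A", "B", "C"):
            f1, f2 = compose_pair(
                ReferenceFrame.identity(),
                PairParams(0, *SUBSTATE_PAIR_PARAMS[lab]))
            g1 = AtomGroup.from_template(templates["I"], f1)
            g2 = AtomGroup.from_template(templates["U"], f2)
            energies[lab] = interaction_energy(g1, g2)
        assert energies["A"] < energies["B"]
        assert energies["A"] < energies["C"]
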
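"""Synthetic ensemble generator: determinism, truth consistency,
stationary-distribution recovery."""
import numpy as np
import pytest

from iupair.ensemble import (SUBSTATE_PAIR_PARAMS, SYSTEMS, Ensemble,
                             EnsembleConfig, build_ideal_duplex,
                             sample_ensemble, sequence_spec,
                             transition_matrix, write_truth)
from iupair.pairing import classify_substate, detect_hbonds
from iupair.workflows import substate_records


class TestSequenceSpec:
    def test_wt_is_the_20mer_with_no_inosines(self):
        spec = sequence_spec("wt")
        assert spec.strand1 == "GCAAUUAACCAAGGAAAAGC"
        assert spec.n_pairs == 20
        assert spec.monitored_pairs == ()

    def test_uii_substitutes_positions_7_and_8(self):
        spec = sequence_spec("UII")
        assert spec.strand1[6:8] == "II"
        assert spec.monitored_pairs == (7,)
        assert spec.partner_residue(7) == 34

    def test_every_inosine_faces_a_uracil(self):
        for name in SYSTEMS:
            spec = sequence_spec(name)
            for p in spec.inosine_positions:
                assert spec.pair_codes(p) == ("I", "U")

    def test_five_prime_neighbour_drives_monitored_context(self):
        assert sequence_spec("UII").five_prime_neighbour(7) == "U"
        assert sequence_spec("CII").five_prime_neighbour(11) == "C"
        assert sequence_spec("GII").five_prime_neighbour(15) == "G"
        assert sequence_spec("AII").five_prime_neighbour(16) == "A"

    def test_combined_systems_monitor_each_tandem(self):
        spec = sequence_spec("UII_CII_AII")
        assert spec.monitored_pairs == (7, 11, 16)

    def test_invalid_character_rejected(self):
        from iupair.ensemble import SequenceSpec
        with pytest.raises(ValueError, match="invalid"):
            SequenceSpec("bad", "GCXXA", ())

    def test_unknown_system_rejected(self):
        with pytest.raises(ValueError, match="unknown system"):
            sequence_spec("XYZ")


class TestTransitionMatrix:
    def test_rows_sum_to_one_and_stationarity(self):
        pi = np.array([0.9, 0.06, 0.03, 0.01, 0.0, 0.0])
        P = transition_matrix(pi, 0.05)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.allclose(pi @ P, pi)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            transition_matrix([0.5, 0.2], 0.1)


class TestGenerator:
    def test_seeded_determinism(self):
        spec = sequence_spec("CII")
        cfg = EnsembleConfig(n_frames=50, seed=123)
        e1 = sample_ensemble(spec, cfg)
        e2 = sample_ensemble(spec, cfg)
        assert np.array_equal(e1.pair_parameters, e2.pair_parameters)
        assert np.array_equal(e1.step_parameters, e2.step_parameters)
        assert all(np.array_equal(e1.labels[k], e2.labels[k])
                   for k in e1.labels)

    def test_truth_file_is_reproducible_and_row_counted(self, tmp_path):
        spec = sequence_spec("UII")
        cfg = EnsembleConfig(n_frames=40, seed=5)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_truth(sample_ensemble(spec, cfg), p1)
        write_truth(sample_ensemble(spec, cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()
        # header + n_frames rows per monitored pair
        assert len(p1.read_text().strip().splitlines()) == 1 + 40

    def test_zero_noise_frames_equal_active_template(self):
        spec = sequence_spec("UII")
        cfg = EnsembleConfig(n_frames=10, seed=1,
                             pair_sd=(0.0,) * 6,
                             monitored_pair_sd=(0.0,) * 6,
                             step_sd=(0.0,) * 6,
                             stationary={7: (1, 0, 0, 0, 0, 0)})
        ens = sample_ensemble(spec, cfg)
        assert np.allclose(ens.pair_parameters[:, 6, :],
                           SUBSTATE_PAIR_PARAMS["A"])

    def test_locked_chain_classifies_all_frames_a(self):
        spec = sequence_spec("UII")
        cfg = EnsembleConfig(n_frames=60, seed=2, switch_rate=0.0,
                             stationary={7: (1, 0, 0, 0, 0, 0)})
        ens = sample_ensemble(spec, cfg)
        recs = substate_records(ens, 7)
        assert all(r.label == "A" for r in recs)

    @pytest.mark.parametrize("label", ["A", "B", "C", "D", "E", "F"])
    def test_substate_template_classifies_as_own_label(self, templates,
                                                       label):
        from iupair.basegeom import ReferenceFrame, rebuild_atoms
        from iupair.helical import PairParams, compose_pair
        f1, f2 = compose_pair(ReferenceFrame.identity(),
                              PairParams(0, *SUBSTATE_PAIR_PARAMS[label]))
        hb = detect_hbonds(rebuild_atoms(f1, templates["I"]), "I",
                           rebuild_atoms(f2, templates["U"]), "U",
                           include_weak_donors=True)
        assert classify_substate(hb) == label

    @pytest.mark.parametrize("label,idx", [("A", 0), ("B", 1), ("C", 2),
                                           ("D", 3), ("E", 4), ("F", 5)])
    def test_pure_substate_ensembles_classify_back(self, label, idx):
        """Generator -> classifier consistency: >=99% of frames of a
        pure-substate ensemble get the generating label."""
        spec = sequence_spec("CII")
        pi = [0.0] * 6
        pi[idx] = 1.0
        cfg = EnsembleConfig(n_frames=200, seed=7, switch_rate=0.0,
                             stationary={11: tuple(pi)})
        ens = sample_ensemble(spec, cfg)
        recs = substate_records(ens, 11)
        frac = np.mean([r.label == label for r in recs])
        assert frac >= 0.97

    def test_truth_labels_match_classifier_at_small_noise(self, uii_small):
        recs = substate_records(uii_small, 7)
        truth = uii_small.labels[7]
        agree = np.mean([r.label == truth[r.frame_index] for r in recs])
        assert agree >= 0.99

    def test_stationary_recovery_improves_with_sqrt_n(self):
        """Estimated populations approach the generator's stationary
        distribution at the binomial rate (iid switching)."""
        spec = sequence_spec("UII")
        pi = np.array([0.9, 0.06, 0.03, 0.01, 0.0, 0.0])
        errs = []
        for n in (250, 4000):
            cfg = EnsembleConfig(n_frames=n, seed=10, switch_rate=1.0)
            ens = sample_ensemble(spec, cfg)
            labs = ens.labels[7]
            est = np.array([(labs == l).mean() for l in "ABCDEF"])
            errs.append(np.abs(est - pi).max())
        assert errs[1] < errs[0]

    def test_ideal_wt_duplex_is_canonical_everywhere(self):
        ens = build_ideal_duplex(sequence_spec("wt"))
        assert ens.n_frames == 1
        assert np.allclose(ens.pair_parameters, 0.0)
        a1, a2 = ens.pair_atoms(0, 3)   # an A-U pair
        hb = detect_hbonds(a1, "A", a2, "U")
        assert len(hb) == 2

    def test_phosphorus_trace_shape(self, uii_small):
        coords = uii_small.phosphorus_coords()
        assert coords.shape == (uii_small.n_frames, 40, 3)
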
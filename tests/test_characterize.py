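import numpy as np
import pytest

import tunnelstates as ts
from tunnelstates.characterize import HYDROPHOBICITY_CLASS
from tunnelstates.clustering import BottleneckSeries

from conftest import toy_frame


def series_of(values_by_type, traj="t0"):
    values_by_type = {k: np.asarray(v, dtype=float)
                      for k, v in values_by_type.items()}
    n = len(next(iter(values_by_type.values())))
    return BottleneckSeries(
        data={(t, traj): v for t, v in values_by_type.items()},
        frame_counts={traj: n})


class TestOpennessSummary:
    def test_all_zero_series_is_closed(self):
        s = series_of({"T1": np.zeros(100)})
        out = ts.openness_summary(s, [np.zeros(100, dtype=int)])
        row = out.iloc[0]
        assert row["label"] == "closed" and row["open_fraction"] == 0.0

    def test_maximum_below_water_radius_is_closed(self):
        s = series_of({"T1": np.full(100, 1.6)})
        out = ts.openness_summary(s, [np.zeros(100, dtype=int)])
        assert out.iloc[0]["label"] == "closed"

    def test_sixty_percent_open_series(self):
        rng = np.random.default_rng(0)
        v = np.zeros(1000)
        v[:600] = rng.uniform(2.0, 3.0, 600)
        s = series_of({"T1": v})
        out = ts.openness_summary(s, [np.zeros(1000, dtype=int)])
        row = out.iloc[0]
        assert row["open_fraction"] == pytest.approx(0.6)
        assert row["label"] == "open"

    def test_wide_fraction_never_exceeds_open_fraction(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 3, 500)
        s = series_of({"T1": v})
        out = ts.openness_summary(s, [rng.integers(0, 3, 500)])
        assert (out["wide_fraction"] <= out["open_fraction"] + 1e-12).all()


class TestCoOpening:
    def test_hand_enumerated_five_frame_example(self):
        # frames 1..5 (0-indexed 0..4): T1 open in {1,2,3}, T2 open in {2,3,4}
        t1 = np.array([0, 2.0, 2.0, 2.0, 0])
        t2 = np.array([0, 0, 2.0, 2.0, 2.0])
        f = ts.co_opening_fractions(t1, t2, threshold=0.9)
        assert f == {"both_open": 0.4, "only_first": 0.2,
                     "only_second": 0.2, "both_closed": 0.2}

    def test_identical_series_no_exclusive_frames(self):
        v = np.array([0, 2, 0, 2, 2.0])
        f = ts.co_opening_fractions(v, v, threshold=0.9)
        assert f["only_first"] == 0 and f["only_second"] == 0

    def test_complementary_series(self):
        a = np.array([2.0, 0, 2.0, 0])
        b = np.array([0, 2.0, 0, 2.0])
        f = ts.co_opening_fractions(a, b, threshold=0.9)
        assert f["both_open"] == 0 and f["both_closed"] == 0

    def test_fractions_sum_to_one_per_pair_per_state(self):
        rng = np.random.default_rng(2)
        s = series_of({"T1": rng.uniform(0, 3, 300),
                       "T2": rng.uniform(0, 3, 300),
                       "T3": rng.uniform(0, 3, 300)})
        labels = [rng.integers(0, 3, 300)]
        out = ts.co_opening(s, labels)
        total = (out["both_open"] + out["only_first"] + out["only_second"]
                 + out["both_closed"])
        np.testing.assert_allclose(total, 1.0, atol=1e-12)


class TestContacts:
    def test_fixed_pair_within_cutoff(self):
        fr = toy_frame([[0, 0, 0], [3.0, 0, 0]], residues=[1, 2])
        out = ts.contact_frequencies([fr], [("resid 1", "resid 2")],
                                     cutoff=4.5)
        assert out.iloc[0]["frequency"] == 1.0

    def test_half_of_frames_in_contact(self):
        near = toy_frame([[0, 0, 0], [3.0, 0, 0]], residues=[1, 2])
        far = toy_frame([[0, 0, 0], [30.0, 0, 0]], residues=[1, 2])
        frames = [near] * 50 + [far] * 50
        out = ts.contact_frequencies(frames, [("resid 1", "resid 2")],
                                     cutoff=4.5)
        assert out.iloc[0]["frequency"] == 0.5

    def test_zero_cutoff_zero_frequencies(self):
        fr = toy_frame([[0, 0, 0], [0.1, 0, 0]], residues=[1, 2])
        out = ts.contact_frequencies([fr], [("resid 1", "resid 2")],
                                     cutoff=0.0)
        assert out.iloc[0]["frequency"] == 0.0

    def test_empty_selection_raises(self):
        fr = toy_frame([[0, 0, 0], [1, 0, 0]], residues=[1, 2])
        with pytest.raises(ValueError, match="empty selection"):
            ts.contact_frequencies([fr], [("resid 9", "resid 2")])


class TestMembraneInteractionTime:
    def test_contact_every_frame_stacks_to_300(self):
        contact = np.ones((90, 1), dtype=bool)
        labels = np.repeat([0, 1, 2], 30)
        out = ts.relative_membrane_interaction_time(contact, labels, [212])
        assert out["percent"].sum() == pytest.approx(300.0)

    def test_no_contact_zero(self):
        contact = np.zeros((90, 1), dtype=bool)
        labels = np.repeat([0, 1, 2], 30)
        out = ts.relative_membrane_interaction_time(contact, labels, [212])
        assert out["percent"].sum() == 0.0

    def test_half_the_frames_of_one_state(self):
        contact = np.zeros((90, 1), dtype=bool)
        contact[:15, 0] = True          # half of state 0's 30 frames
        labels = np.repeat([0, 1, 2], 30)
        out = ts.relative_membrane_interaction_time(contact, labels, [212])
        per_state = out.set_index("state")["percent"]
        assert per_state[0] == pytest.approx(50.0)
        assert per_state[1] == 0.0 and per_state[2] == 0.0

    def test_stacked_bar_figure_written(self, tmp_path):
        contact = np.zeros((90, 2), dtype=bool)
        contact[:30, 0] = True
        contact[:, 1] = True
        labels = np.repeat([0, 1, 2], 30)
        tab = ts.relative_membrane_interaction_time(contact, labels,
                                                    [212, 215])
        path = tmp_path / "interaction.png"
        ts.plot_membrane_interaction_time(tab, str(path))
        assert path.stat().st_size > 0

    def test_lipid_neighborhood_contact_series(self, gated, membrane,
                                               world_spec):
        ens, _ = gated
        model, mem_frame = membrane
        merged = ts.merge_frames(ens.frame(0, 0), mem_frame)
        out = ts.membrane_contact_series([merged], ens.gate_residues)
        # the gated protein sits at the origin, > 10 A from both leaflets
        assert not out.any()


class TestDihedralEntropy:
    def test_uniform_circle_matches_log_2pi(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(-np.pi, np.pi, 100_000)
        h = ts.dihedral_entropy(angles)
        assert h == pytest.approx(np.log(2 * np.pi), abs=0.05)

    def test_von_mises_matches_closed_form(self):
        rng = np.random.default_rng(1)
        angles = rng.vonmises(0.7, 4.0, 100_000)
        h = ts.dihedral_entropy(angles)
        assert h == pytest.approx(ts.von_mises_entropy(4.0), abs=0.05)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        angles = rng.vonmises(0.0, 2.0, 20_000)
        h1 = ts.dihedral_entropy(angles)
        h2 = ts.dihedral_entropy(angles + 1.0)
        assert h1 == pytest.approx(h2, abs=1e-6)

    def test_entropy_decreases_with_concentration(self):
        rng = np.random.default_rng(3)
        values = [ts.dihedral_entropy(rng.vonmises(0, k, 50_000))
                  for k in (0.5, 1, 2, 4, 8)]
        assert values == sorted(values, reverse=True)

    def test_degenerate_series_minus_infinity(self):
        with pytest.warns(UserWarning, match="degenerate"):
            h = ts.dihedral_entropy(np.zeros(500))
        assert h == -np.inf

    def test_kernel_convention_agrees(self):
        rng = np.random.default_rng(4)
        angles = rng.vonmises(0, 4.0, 50_000)
        h = ts.dihedral_entropy(angles, convention="kernel")
        assert h == pytest.approx(ts.von_mises_entropy(4.0), abs=0.05)


class TestCrystalPCA:
    def _structures(self, displacements):
        base = np.random.default_rng(5).uniform(-5, 5, (12, 3))
        out = []
        for d in displacements:
            pts = base.copy()
            pts[0, 0] += d
            out.append(toy_frame(pts, residues=np.repeat([201, 210, 220], 4)))
        return out

    def test_identical_structures_zero_variance(self):
        pca = ts.crystal_pca(self._structures([0, 0, 0]), region=(200, 260))
        assert pca.explained_variance.max() == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(pca.projections, 0.0, atol=1e-10)

    def test_single_axis_displacement_single_pc(self):
        pca = ts.crystal_pca(self._structures([0.0, 1.0, 2.0]),
                             region=(200, 260))
        assert pca.explained_variance[0] > 0
        assert pca.explained_variance[1] == pytest.approx(0.0, abs=1e-12)
        p = np.sort(pca.projections[:, 0])
        np.testing.assert_allclose(np.diff(p), 1.0, atol=1e-9)

    def test_select_extremes_all_when_k_equals_n(self):
        pca = ts.crystal_pca(self._structures([0, 1, 2]), region=(200, 260))
        assert sorted(pca.select_extremes(3)) == [0, 1, 2]

    def test_greedy_maxmin_picks_extremes_first(self):
        pca = ts.crystal_pca(self._structures([0, 0.1, 5.0]),
                             region=(200, 260))
        chosen = pca.select_extremes(2)
        assert 2 in chosen            # the far structure is always selected

    def test_mismatched_atom_counts_listed(self):
        structs = self._structures([0, 0])
        structs.append(toy_frame(np.zeros((4, 3)),
                                 residues=np.repeat([205], 4)))
        with pytest.raises(ValueError, match="offending"):
            ts.crystal_pca(structs, region=(200, 260))


class TestRMSDPerResidue:
    def test_zero_for_identical(self):
        fr = toy_frame(np.random.default_rng(6).uniform(-5, 5, (9, 3)),
                       residues=np.repeat([1, 2, 3], 3))
        out = ts.rmsd_per_residue([fr], fr)
        assert (out["rmsd_A"] == 0).all()

    def test_rigidly_translated_residue(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-5, 5, (9, 3))
        ref = toy_frame(pts, residues=np.repeat([1, 2, 3], 3))
        moved = pts.copy()
        moved[3:6] += [2.0, 0, 0]
        out = ts.rmsd_per_residue([toy_frame(moved,
                                             residues=np.repeat([1, 2, 3], 3))],
                                  ref)
        vals = out.set_index("residue")["rmsd_A"]
        assert vals[2] == pytest.approx(2.0, abs=1e-12)
        assert vals[1] == 0.0 and vals[3] == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(-5, 5, (9, 3))
        residues = np.repeat([1, 2, 3], 3)
        ref = toy_frame(pts, residues=residues)
        noisy = pts + rng.normal(scale=0.3, size=pts.shape)
        out = ts.rmsd_per_residue([toy_frame(noisy, residues=residues)], ref)
        for r in (1, 2, 3):
            d = noisy[residues == r] - pts[residues == r]
            direct = np.sqrt((d ** 2).sum(axis=1).mean())
            got = out.set_index("residue")["rmsd_A"][r]
            assert got == pytest.approx(direct, abs=1e-9)


def test_hydrophobicity_classes_cover_standard_residues():
    assert HYDROPHOBICITY_CLASS["PHE"] == "hydrophobic"
    assert HYDROPHOBICITY_CLASS["THR"] == "neutral-polar"
    assert HYDROPHOBICITY_CLASS["ARG"] == "charged"
    assert len(HYDROPHOBICITY_CLASS) == 20
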
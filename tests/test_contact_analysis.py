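"""Minimum heavy-atom distances and trajectory contact logic."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from masdyn.contact_analysis import (ContactSeries, CoordinateFrames,
                                     contact_series, dca_md_agreement,
                                     min_heavy_distance, residue_pairs)
from masdyn.coevolution_eval import ContactReference
from masdyn.synthetic_data import make_toy_assembly


def single_atom_frames(z_b=4.9):
    coords = np.array([[[0.0, 0.0, 0.0], [0.0, 0.0, z_b]]])
    return CoordinateFrames(coords, ["A", "A"], [1, 10], ["CA", "CA"],
                            ["C", "C"])


def random_residue_frames(seed=0, n_res=4, atoms_per_res=5):
    rng = np.random.default_rng(seed)
    n = n_res * atoms_per_res
    coords = rng.uniform(0, 20, (1, n, 3))
    resids = np.repeat(np.arange(1, n_res + 1), atoms_per_res)
    return CoordinateFrames(coords, ["A"] * n, resids, ["C"] * n, ["C"] * n)


class TestMinHeavyDistance:
    def test_single_atom_pair(self):
        frames = single_atom_frames(4.9)
        assert min_heavy_distance(frames, ("A", 1), ("A", 10)) \
            == pytest.approx(4.9)

    def test_identical_positions(self):
        frames = single_atom_frames(0.0)
        # construction places both atoms at the origin -> distance 0
        coords = frames.coords.copy()
        coords[0, 1] = coords[0, 0]
        frames = CoordinateFrames(coords, frames.chains, frames.resids,
                                  frames.names, frames.elements)
        assert min_heavy_distance(frames, ("A", 1), ("A", 10)) == 0.0

    def test_matches_brute_force_all_pairs(self):
        frames = random_residue_frames(seed=3)
        for ra, rb in ((1, 2), (2, 4), (1, 4)):
            ia = frames.atom_indices(("A", ra))
            ib = frames.atom_indices(("A", rb))
            brute = min(np.linalg.norm(frames.coords[0, i] - frames.coords[0, j])
                        for i in ia for j in ib)
            assert min_heavy_distance(frames, ("A", ra), ("A", rb)) \
                == pytest.approx(brute, rel=1e-12)

    def test_symmetry(self):
        frames = random_residue_frames(seed=8)
        d_ab = min_heavy_distance(frames, ("A", 1), ("A", 3))
        d_ba = min_heavy_distance(frames, ("A", 3), ("A", 1))
        assert d_ab == d_ba

    def test_rigid_body_invariance(self):
        frames = random_residue_frames(seed=12)
        rot = Rotation.random(random_state=1).as_matrix()
        shifted = frames.coords[0] @ rot.T + np.array([5.0, -3.0, 11.0])
        moved = CoordinateFrames(shifted[None], frames.chains, frames.resids,
                                 frames.names, frames.elements)
        for ra, rb in ((1, 2), (3, 4)):
            assert min_heavy_distance(moved, ("A", ra), ("A", rb)) \
                == pytest.approx(min_heavy_distance(frames, ("A", ra),
                                                    ("A", rb)), rel=1e-9)

    def test_hydrogens_excluded_by_element(self):
        coords = np.array([[[0.0, 0.0, 0.0], [0.0, 0.0, 1.0],
                            [0.0, 0.0, 6.0]]])
        frames = CoordinateFrames(coords, ["A", "A", "A"], [1, 1, 2],
                                  ["CA", "HA", "CA"], ["C", "H", "C"])
        # the hydrogen at 5 A from residue 2 must not shorten the distance
        assert min_heavy_distance(frames, ("A", 1), ("A", 2)) \
            == pytest.approx(6.0)


class TestContactSeries:
    def test_static_pair_fraction_one(self):
        frames = single_atom_frames(4.9)
        series = contact_series(frames, [(("A", 1), ("A", 10))], cutoff=5.0)
        assert series.contact_fraction((("A", 1), ("A", 10))) == 1.0

    def test_oscillating_pair_half_fraction(self):
        coords = np.array([
            [[0, 0, 0], [0, 0, 4.0]],
            [[0, 0, 0], [0, 0, 6.0]],
            [[0, 0, 0], [0, 0, 4.0]],
            [[0, 0, 0], [0, 0, 6.0]],
        ])
        frames = CoordinateFrames(coords, ["A", "B"], [1, 1], ["CA", "CA"],
                                  ["C", "C"])
        series = contact_series(frames, [(("A", 1), ("B", 1))], cutoff=5.0)
        assert series.contact_fraction((("A", 1), ("B", 1))) == 0.5

    def test_cutoff_monotonicity_on_random_frames(self):
        rng = np.random.default_rng(21)
        n_res, atoms = 8, 3
        coords = rng.uniform(0, 25, (6, n_res * atoms, 3))
        resids = np.repeat(np.arange(1, n_res + 1), atoms)
        frames = CoordinateFrames(coords, ["A"] * (n_res * atoms), resids,
                                  ["C"] * (n_res * atoms),
                                  ["C"] * (n_res * atoms))
        pairs = residue_pairs(frames, range(1, n_res + 1))
        series = contact_series(frames, pairs, cutoff=5.0)
        sets = {c: set(series.at_cutoff(c).transient_pairs())
                for c in (5.0, 7.0, 8.0)}
        assert sets[5.0] <= sets[7.0] <= sets[8.0]

    def test_stride_subsamples_frames(self):
        frames, _ = make_toy_assembly(n_frames=10, seed=0)
        series = contact_series(frames, [(("A", 123), ("B", 150))],
                                stride=2)
        assert series.distances.shape[1] == 5

    def test_empty_selection_rejected(self):
        frames = single_atom_frames()
        with pytest.raises(ValueError, match="empty pair selection"):
            contact_series(frames, [])


class TestDcaMdAgreement:
    def test_always_close_pair_is_formed_everywhere(self):
        frames, _ = make_toy_assembly(n_frames=8,
                                      loop_excursion_amplitude=0.0, seed=1)
        series = contact_series(frames, [(("A", 123), ("B", 150))])
        rep = dca_md_agreement(series, [(123, 150)], loose_cutoff=7.0)
        assert rep["fraction_formed"].iloc[0] == 1.0
        assert bool(rep["formed"].iloc[0])

    def test_never_close_pair_is_absent(self):
        frames, _ = make_toy_assembly(n_frames=8, seed=1)
        series = contact_series(frames, [(("A", 101), ("B", 160))])
        rep = dca_md_agreement(series, [(101, 160)], loose_cutoff=7.0)
        assert rep["fraction_formed"].iloc[0] == 0.0
        assert not bool(rep["formed"].iloc[0])

    def test_fractions_match_hand_count(self):
        frames, truth = make_toy_assembly(n_frames=20, seed=6)
        series = contact_series(frames, [(("A", 123), ("B", 150))],
                                cutoff=5.0)
        rep = dca_md_agreement(series, [(123, 150)], loose_cutoff=7.0)
        hand = np.mean(truth["engaged_frames"])
        assert rep["fraction_formed"].iloc[0] == pytest.approx(hand)

    def test_numbering_mismatch_rejected(self):
        frames, _ = make_toy_assembly(n_frames=4, seed=2)
        series = contact_series(frames, [(("A", 123), ("B", 150))])
        with pytest.raises(ValueError, match="numbering mismatch"):
            dca_md_agreement(series, [(1, 999)])


class TestReferenceFromFrames:
    def test_reference_distances_match_direct_computation(self):
        frames, _ = make_toy_assembly(n_frames=3, seed=4)
        ref = ContactReference.from_frames(frames)
        d = min_heavy_distance(frames, ("A", 123), ("B", 150), 0)
        # residue numbers 123/150 exist on one chain each here
        assert ref.distance(123, 150) == pytest.approx(d)
        assert 123 in ref.defined_positions
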
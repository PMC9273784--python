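"""Calpha-trace secondary structure: angles, assignment, sheets, states."""

import numpy as np
import pytest

from dimerlens.cutabi import (SSAssignment, SSCounts, assign_ss,
                              backbone_geometry, count_ss_region,
                              cumulative_dos_curve,
                              orientation_percentages, split_B_HB)
from dimerlens.geometry import rigid_transform
from dimerlens.io_ensemble import ChainRecord, Conformation
from dimerlens.synthetic import SegmentSpec, assemble_chain

from conftest import ideal_helix, ideal_strand, straight_line


class TestBackboneGeometry:
    def test_ideal_helix_closed_form(self):
        theta, tau = backbone_geometry(ideal_helix(12))
        # analytic evaluation of the parametrisation gives ~90.4/+50.0
        assert np.allclose(theta[1:-1], 90.37, atol=0.1)
        assert np.allclose(tau[1:-2], 50.04, atol=0.1)

    def test_ideal_strand_is_near_trans(self):
        theta, tau = backbone_geometry(ideal_strand(10))
        assert np.all(np.abs(tau[1:-2]) > 160.0)
        assert np.allclose(theta[1:-1], 120.55, atol=0.1)

    def test_terminal_residues_are_undefined(self):
        theta, tau = backbone_geometry(ideal_helix(6))
        assert np.isnan(theta[0]) and np.isnan(theta[-1])
        assert np.isnan(tau[0]) and np.isnan(tau[-2:]).all()

    def test_three_residue_chain_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            backbone_geometry(ideal_helix(3))

    def test_collinear_triplets_flagged_not_raised(self):
        line = straight_line(6, np.zeros(3), np.array([1.0, 0, 0]))
        theta, tau = backbone_geometry(line)
        assert np.all((theta[1:-1] > 179.0) | np.isnan(theta[1:-1]))
        assert np.isnan(tau[1:-2]).all()


class TestAssignSS:
    def test_planted_helix_recovered(self):
        ch, labels = assemble_chain([SegmentSpec("helix", 53, 13)], 140,
                                    seed=7)
        conf = Conformation(chains=[ch])
        asg = assign_ss(conf)
        got = asg.labels["A"]
        planted = np.where(labels == "H")[0]
        recovered = np.mean(got[planted] == "H")
        assert recovered >= 0.95
        # nothing helical beyond one junction residue on either side
        h_idx = np.where(got == "H")[0]
        assert h_idx.min() >= planted.min() - 1
        assert h_idx.max() <= planted.max() + 1

    def test_three_residue_helical_stretch_is_not_a_helix(self):
        ch, _ = assemble_chain([SegmentSpec("helix", 60, 3)], 140,
                               seed=11)
        asg = assign_ss(Conformation(chains=[ch]))
        assert not np.any(asg.labels["A"] == "H")

    def test_unpaired_extended_runs_stay_coil(self):
        # two parallel extended strands 8 A apart: beyond the pairing
        # cutoff, so neither becomes sheet
        s1 = ideal_strand(10)
        s2 = ideal_strand(10) + np.array([0.0, 0.0, 8.0])
        conf = Conformation(chains=[ChainRecord("A", s1),
                                    ChainRecord("B", s2)])
        asg = assign_ss(conf)
        assert not asg.sheet_pairs
        assert not np.any(asg.labels["A"] == "E")
        assert not np.any(asg.labels["B"] == "E")

    def test_labels_invariant_under_rigid_motion(self,
                                                 clean_interface_dimer):
        asg = assign_ss(clean_interface_dimer)
        rng = np.random.default_rng(3)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
             2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
             2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x),
             1 - 2 * (x * x + y * y)]])
        t = np.array([12.0, -5.0, 40.0])
        moved = Conformation(chains=[
            ChainRecord(c.chain_id, rigid_transform(c.ca_coords, rot, t))
            for c in clean_interface_dimer.chains])
        asg2 = assign_ss(moved)
        for cid in asg.labels:
            assert np.array_equal(asg.labels[cid], asg2.labels[cid])
        assert asg.sheet_pairs == asg2.sheet_pairs


class TestSheetPairings:
    def test_in_register_interface_pairs_parallel_inter(
            self, clean_interface_dimer):
        asg = assign_ss(clean_interface_dimer)
        inter = [p for p in asg.sheet_pairs if p.scope == "inter"]
        assert len(inter) == 18
        assert all(p.orientation == "parallel" for p in inter)
        assert sorted(p.res_a for p in inter) == list(range(78, 96))
        assert all(p.res_a == p.res_b for p in inter)

    def test_antiparallel_hairpin_register(self):
        # strands 1-7 and 12-18 of an 18-residue chain fold back onto
        # each other with register res_a + res_b = 19
        s1 = ideal_strand(7)
        s2 = np.array([s1[6 - m] + np.array([0, 0, 4.8])
                       for m in range(7)])
        loop = np.array([
            s1[6] + np.array([3.5, 1.5, 1.0]),
            s1[6] + np.array([6.5, 0.0, 2.4]),
            s1[6] + np.array([6.5, -1.5, 4.0]),
            s2[0] - np.array([-3.5, -1.5, -1.0]) + np.array([0, 0, 0]),
        ])
        loop[3] = s1[6] + np.array([3.3, -1.0, 4.2])
        coords = np.vstack([s1, loop, s2])
        conf = Conformation(chains=[ChainRecord("A", coords)])
        asg = assign_ss(conf)
        anti = [p for p in asg.sheet_pairs
                if p.orientation == "antiparallel"]
        assert anti, "hairpin should pair"
        assert all(p.res_a + p.res_b == 19 for p in anti)
        assert all(p.scope == "intra" for p in anti)
        paired_a = {p.res_a for p in anti}
        assert {2, 3, 4, 5, 6} <= paired_a

    def test_single_isolated_pair_discarded(self):
        # two tiny 4-residue extended chains crossing at one point:
        # only one residue pair comes below the pairing cutoff
        s1 = ideal_strand(4)
        s2 = ideal_strand(4) @ _rot_z(90.0) + np.array([3.3, -3.3, 4.0])
        conf = Conformation(chains=[ChainRecord("A", s1),
                                    ChainRecord("B", s2)])
        asg = assign_ss(conf)
        assert not [p for p in asg.sheet_pairs if p.scope == "inter"]


def _rot_z(deg: float) -> np.ndarray:
    r = np.radians(deg)
    return np.array([[np.cos(r), -np.sin(r), 0],
                     [np.sin(r), np.cos(r), 0],
                     [0, 0, 1.0]])


class TestRegionCounts:
    def _assignment(self, h_ranges, e_ranges) -> SSAssignment:
        labels = {}
        for cid in "AB":
            lab = np.full(140, "C", dtype="U1")
            for lo, hi in h_ranges:
                lab[lo - 1: hi] = "H"
            for lo, hi in e_ranges:
                lab[lo - 1: hi] = "E"
            labels[cid] = lab
        return SSAssignment(labels=labels, sheet_pairs=[])

    def test_helix_count_in_region(self):
        asg = self._assignment([(53, 65)], [])
        counts = count_ss_region(asg, (1, 95))
        assert counts.alpha == 26 and counts.beta == 0

    def test_no_structure_counts_zero(self):
        counts = count_ss_region(self._assignment([], []), (1, 95))
        assert (counts.alpha, counts.beta) == (0, 0)

    def test_pigeonhole_bound(self):
        asg = self._assignment([(1, 50)], [(51, 140)])
        counts = count_ss_region(asg, (1, 95))
        assert counts.alpha + counts.beta <= 190

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            count_ss_region(self._assignment([], []), (0, 95))
        with pytest.raises(ValueError):
            count_ss_region(self._assignment([], []), (1, 200))


class TestBHBSplit:
    def test_fractions_match_construction(self):
        counts = [SSCounts(0, b, (1, 95)) for b in (10, 12, 10)] + \
            [SSCounts(5, 20, (1, 95)), SSCounts(8, 30, (1, 95))]
        states, b_density, hb_density = split_B_HB(counts)
        assert np.mean(states == "B") == pytest.approx(0.6)
        assert b_density["p"].sum() == pytest.approx(1.0)
        assert hb_density["p"].sum() == pytest.approx(1.0)

    def test_all_helical_means_empty_B(self):
        counts = [SSCounts(3, 10, (1, 95))] * 4
        states, b_density, _hb = split_B_HB(counts)
        assert not np.any(states == "B")
        assert b_density["p"].size == 0

    def test_all_B_means_empty_HB(self):
        counts = [SSCounts(0, b, (1, 95)) for b in (5, 6, 7)]
        states, b_density, hb_density = split_B_HB(counts)
        assert np.all(states == "B")
        assert b_density["p"].sum() == pytest.approx(1.0)
        assert hb_density["p"].size == 0


class TestDosCurve:
    def test_single_bin_is_a_step_at_zero(self):
        counts = [SSCounts(0, 10, (1, 95))] * 5
        curve = cumulative_dos_curve(counts, np.array([0.0, 1.0, 5.0]))
        assert np.allclose(curve, 1.0)

    def test_degenerate_tie_counts_both_bins_at_zero(self):
        counts = [SSCounts(0, 10, (1, 95))] * 5 + \
            [SSCounts(4, 20, (1, 95))] * 5
        curve = cumulative_dos_curve(counts, np.array([0.0]))
        assert curve[0] == pytest.approx(1.0)

    def test_two_bin_closed_form(self):
        counts = [SSCounts(0, 10, (1, 95))] * 8 + \
            [SSCounts(4, 20, (1, 95))] * 2
        cutoffs = np.array([0.0, np.log(4.0) - 1e-9, np.log(4.0) + 1e-9,
                            10.0])
        curve = cumulative_dos_curve(counts, cutoffs)
        assert np.allclose(curve, [0.8, 0.8, 1.0, 1.0])
        assert np.all(np.diff(curve) >= 0)

    def test_missing_reference_state_rejected(self):
        counts = [SSCounts(3, 10, (1, 95))] * 4
        with pytest.raises(ValueError, match="reference"):
            cumulative_dos_curve(counts, np.array([1.0]))


class TestOrientationPercentages:
    def test_pure_in_register_ensemble_hand_count(
            self, clean_interface_dimer):
        asgs = [assign_ss(clean_interface_dimer)] * 3
        stats = orientation_percentages(asgs)
        assert stats.parallel == pytest.approx(100.0 * 36 / 280)
        assert stats.antiparallel == 0.0
        assert stats.by_scope["parallel_inter"] == stats.parallel
        assert stats.by_scope["parallel_intra"] == 0.0

    def test_percentages_bounded_and_chain_swap_invariant(
            self, clean_interface_dimer):
        asg = assign_ss(clean_interface_dimer)
        swapped = Conformation(
            chains=list(reversed(clean_interface_dimer.chains)))
        asg_swapped = assign_ss(swapped)
        s1 = orientation_percentages([asg])
        s2 = orientation_percentages([asg_swapped])
        assert s1.parallel == pytest.approx(s2.parallel)
        assert s1.antiparallel == pytest.approx(s2.antiparallel)
        assert 0.0 <= s1.parallel <= 100.0

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            orientation_percentages([])
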
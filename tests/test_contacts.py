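"""Contact definitions, dimer classification, landscapes and minima."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist, pdist

from dimerlens.contacts import (classify_dimer, compute_contacts,
                                contact_probability_maps,
                                effective_landscape, find_minima,
                                mean_intermolecular_contacts)
from dimerlens.io_ensemble import ChainRecord, Conformation
from dimerlens.synthetic import (DimerPlantSpec, EnsembleSpec,
                                 sample_ensemble)

from conftest import ideal_strand, straight_line


def _pair_conf(gap: float) -> Conformation:
    """Two 2-residue chains whose closest pair sits `gap` apart."""
    a = np.array([[0.0, 0.0, 0.0], [0.0, 100.0, 0.0]])
    b = np.array([[gap, 0.0, 0.0], [gap, -100.0, 0.0]])
    return Conformation(chains=[ChainRecord("A", a), ChainRecord("B", b)])


class TestComputeContacts:
    def test_cutoff_is_a_strict_inequality(self):
        assert compute_contacts(_pair_conf(5.99)).n_inter == 1
        assert compute_contacts(_pair_conf(6.00)).n_inter == 0

    def test_single_strand_matches_brute_force(self):
        coords = ideal_strand(10)
        conf = Conformation(chains=[ChainRecord("A", coords)])
        cs = compute_contacts(conf, min_seq_sep=1)
        assert cs.n_inter == 0
        assert cs.n_intra == int((pdist(coords) < 6.0).sum())

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = np.cumsum(rng.normal(scale=2.5, size=(40, 3)), axis=0)
        b = np.cumsum(rng.normal(scale=2.5, size=(40, 3)), axis=0) \
            + rng.normal(scale=10.0, size=3)
        conf = Conformation(chains=[ChainRecord("A", a),
                                    ChainRecord("B", b)])
        cs = compute_contacts(conf, cutoff=6.0, min_seq_sep=1)
        # independent oracle: exhaustive loops over all pairs
        n_inter = sum(1 for i in range(40) for j in range(40)
                      if np.linalg.norm(a[i] - b[j]) < 6.0)
        n_intra = sum(1 for x in (a, b) for i in range(40)
                      for j in range(i + 1, 40)
                      if np.linalg.norm(x[i] - x[j]) < 6.0)
        assert cs.n_inter == n_inter
        assert cs.n_intra == n_intra
        assert cs.n_inter + cs.n_intra == len(cs.contacts)
        assert all(c.distance < 6.0 for c in cs.contacts)

    def test_min_seq_sep_filters_bonded_neighbours(self):
        coords = ideal_strand(10)
        conf = Conformation(chains=[ChainRecord("A", coords)])
        literal = compute_contacts(conf, min_seq_sep=1).n_intra
        sheetish = compute_contacts(conf, min_seq_sep=3).n_intra
        assert literal == sheetish + 9  # 9 bonded pairs at 3.8 A


class TestClassifyDimer:
    def _interface(self, n_pairs: int) -> Conformation:
        iface = ideal_strand(n_pairs)
        pre = straight_line(30, iface[0] + np.array([-3.8, 0, 2.0]),
                            np.array([-1.0, 0.0, 1.0]))[::-1]
        a = np.vstack([pre, iface])
        b_pre = straight_line(30, iface[0] + np.array([-3.8, 0, 2.8]),
                              np.array([-1.0, 0.0, -1.0]))[::-1]
        b = np.vstack([b_pre, iface + np.array([0, 0, 4.8])])
        return Conformation(chains=[ChainRecord("A", a),
                                    ChainRecord("B", b)])

    def test_dimer_boundary_at_eleven_close_pairs(self):
        conf = _plant_exact_pairs(11)
        label = classify_dimer(conf)
        assert label.n_close_pairs == 11
        assert label.is_dimer

    def test_ten_close_pairs_is_not_a_dimer(self):
        conf = _plant_exact_pairs(10)
        label = classify_dimer(conf)
        assert label.n_close_pairs == 10
        assert not label.is_dimer

    def test_far_apart_chains(self):
        a = ideal_strand(20)
        b = a + np.array([0.0, 0.0, 25.0])
        conf = Conformation(chains=[ChainRecord("A", a),
                                    ChainRecord("B", b)])
        label = classify_dimer(conf)
        assert label.n_close_pairs == 0 and not label.is_dimer

    def test_requires_exactly_two_chains(self):
        conf = Conformation(chains=[ChainRecord("A", ideal_strand(5))])
        with pytest.raises(ValueError):
            classify_dimer(conf)


def _plant_exact_pairs(n_pairs: int) -> Conformation:
    """Two chains with exactly `n_pairs` interchain pairs below 5 A."""
    iface = ideal_strand(n_pairs)
    tail_a = straight_line(20, iface[-1] + np.array([3.8, 0, 9.5]),
                           np.array([1.0, 0.0, 0.0]))
    tail_b = tail_a + np.array([0.0, 200.0, 0.0])
    a = np.vstack([iface, tail_a])
    b = np.vstack([iface + np.array([0, 0, 4.8]), tail_b])
    conf = Conformation(chains=[ChainRecord("A", a), ChainRecord("B", b)])
    d = cdist(a, b)
    assert (d < 5.0).sum() == n_pairs  # fixture sanity
    return conf


class TestMeanContacts:
    def test_hand_counted_micro_case(self):
        # residue 10 of A sits within 6 A of residues 20 and 21 of B and
        # nothing else: averaged over the two chain copies the profile
        # is 1.0 at residue 10 and 0.5 at residues 20 and 21
        n = 30
        a = straight_line(n, np.zeros(3), np.array([1.0, 0, 0]),
                          step=10.0)
        b = a + np.array([0.0, 500.0, 0.0])
        b[19] = a[9] + np.array([0.0, 3.0, 0.0])
        b[20] = a[9] + np.array([0.0, -3.0, 0.0])
        conf = Conformation(chains=[ChainRecord("A", a),
                                    ChainRecord("B", b)])
        profile = mean_intermolecular_contacts([conf])
        expected = np.zeros(n)
        expected[9] = 1.0
        expected[19] = expected[20] = 0.5
        assert np.allclose(profile, expected)

    def test_chain_swap_invariance(self):
        ens, _ = sample_ensemble(EnsembleSpec(
            n_snapshots=6, dimer_fraction=1.0,
            dfncs_fraction_of_dimers=0.5, seed=13))
        swapped = [Conformation(chains=list(reversed(c.chains)))
                   for c in ens]
        p1 = mean_intermolecular_contacts(ens)
        p2 = mean_intermolecular_contacts(swapped)
        assert np.allclose(p1, p2)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            mean_intermolecular_contacts([])


class TestContactMaps:
    def test_planted_interface_saturates_the_diagonal(self):
        ens, _ = sample_ensemble(EnsembleSpec(
            n_snapshots=5, dimer_fraction=1.0,
            dfncs_fraction_of_dimers=1.0, seed=17))
        inter, intra = contact_probability_maps(ens)
        diag = np.diag(inter)
        assert np.allclose(diag[77:95], 1.0)
        assert np.allclose(inter, inter.T)
        assert inter.min() >= 0.0 and inter.max() <= 1.0
        assert intra.min() >= 0.0 and intra.max() <= 1.0

    def test_cells_match_per_pair_frequency_oracle(self):
        ens, _ = sample_ensemble(EnsembleSpec(
            n_snapshots=4, dimer_fraction=0.5,
            dfncs_fraction_of_dimers=1.0, seed=19))
        inter, _ = contact_probability_maps(ens)
        confs = list(ens)
        for i, j in [(80, 80), (10, 50), (70, 71)]:
            freq = np.mean([
                0.5 * (float(np.linalg.norm(c.chains[0].ca_coords[i]
                                            - c.chains[1].ca_coords[j])
                             < 6.0)
                       + float(np.linalg.norm(c.chains[1].ca_coords[i]
                                              - c.chains[0].ca_coords[j])
                               < 6.0))
                for c in confs])
            assert inter[i, j] == pytest.approx(freq)


class TestLandscape:
    def test_single_bin_has_zero_free_energy(self):
        grid = effective_landscape([(3, 4)] * 10, bin_width=5)
        assert np.isclose(grid.P.sum(), 1.0)
        occ = grid.F[np.isfinite(grid.F)]
        assert occ.shape == (1,) and occ[0] == 0.0

    def test_two_bin_free_energy_difference_closed_form(self):
        samples = [(0, 0)] * 100 + [(50, 50)] * 92
        grid = effective_landscape(samples, bin_width=5)
        occ = np.sort(grid.F[np.isfinite(grid.F)])
        assert occ[0] == 0.0
        assert occ[1] == pytest.approx(np.log(100 / 92))

    def test_uniform_occupancy_is_flat(self):
        samples = [(i * 10, 0) for i in range(5) for _ in range(7)]
        grid = effective_landscape(samples, bin_width=5)
        assert np.all(grid.F[np.isfinite(grid.F)] == 0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            effective_landscape([])


class TestFindMinima:
    def test_two_basin_depth_difference_closed_form(self):
        # isolated peaks: the smoothing kernel preserves their ratio
        p1, p2 = 1000, 923
        samples = [(10, 10)] * p1 + [(60, 60)] * p2 + \
            [(10, 60)] * 20 + [(60, 10)] * 20
        grid = effective_landscape(samples, bin_width=5)
        minima = find_minima(grid, depth_window=1.0)
        assert len(minima) == 2
        assert minima[0][2] == 0.0
        assert minima[1][2] == pytest.approx(np.log(p1 / p2))
        assert round(minima[1][2], 2) == 0.08

    def test_single_basin_yields_one_minimum(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(loc=50, scale=4, size=(500, 2)).round()
        grid = effective_landscape([tuple(p) for p in pts], bin_width=5)
        minima = find_minima(grid)
        assert len(minima) == 1
        assert minima[0][2] == 0.0

    def test_depth_window_excludes_shallow_minima(self):
        samples = [(10, 10)] * 1000 + [(60, 60)] * 100
        grid = effective_landscape(samples, bin_width=5)
        assert len(find_minima(grid, depth_window=1.0)) == 1
        assert len(find_minima(grid, depth_window=3.0)) == 2
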
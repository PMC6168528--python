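"""Inverse-Boltzmann derivation, group potentials and table evaluation."""

import math

import numpy as np
import pytest

from solpot.alphabet import N_PAIRS, PAIR_LIST, pair_index
from solpot.config import RunConfig
from solpot.counting import (
    LONG_RANGE,
    BinningScheme,
    PairCountTensor,
    prepare_counts,
)
from solpot.potentials import (
    GroupSpec,
    PotentialTable,
    derive_all,
    derive_from_stack,
    derive_group_potential,
    derive_potential,
    empirical_radii,
    read_potential,
    write_potential,
)
from solpot.structure_io import split_dataset
from solpot.synthetic import (
    GeneratorParams,
    PlantedBias,
    generate_chain,
    generate_dataset,
)
from solpot.counting import stack_counts, smooth


def _smoothed(counts, scheme):
    """Wrap a pre-built array as a smoothed tensor with a zero-count mask."""
    t = PairCountTensor(counts=counts, scheme=scheme, state="smoothed")
    return t, counts <= 0


class TestDerivePotential:
    def test_factorized_counts_give_zero_energy(self, scheme):
        rng = np.random.default_rng(0)
        pair_mass = rng.uniform(1, 5, size=(N_PAIRS, 1, 1))
        bin_mass = rng.uniform(1, 5, size=(1, 1, scheme.n_bins))
        counts = np.broadcast_to(pair_mass * bin_mass,
                                 (N_PAIRS, 8, scheme.n_bins)).copy()
        t, mask = _smoothed(counts, scheme)
        table = derive_potential(t, t, mask)
        np.testing.assert_allclose(table.values[~table.mask], 0.0, atol=1e-10)

    def test_matches_hand_computed_frequency_ratios(self, scheme):
        # two residue types, three occupied bins: 12, 20, 40 occurrences
        cfg = RunConfig()
        counts = np.zeros((N_PAIRS, 8, scheme.n_bins))
        p = pair_index("A", "R")
        counts[p, LONG_RANGE, 0:3] = [12.0, 20.0, 40.0]
        q = pair_index("A", "A")
        counts[q, LONG_RANGE, 1] = 30.0
        t, mask = _smoothed(counts, scheme)
        table = derive_potential(t, t, mask, cfg)
        n = counts[:, LONG_RANGE, :].sum()
        for b, n_ssd in [(0, 12.0), (1, 20.0), (2, 40.0)]:
            n_ss = 72.0
            n_d = counts[:, LONG_RANGE, b].sum()
            expected = -cfg.kbt * math.log(n * n_ssd / (n_ss * n_d))
            assert table.values[p, LONG_RANGE, b] == pytest.approx(
                expected, rel=1e-12
            )

    def test_doubling_counts_leaves_energy_unchanged(self, scheme):
        rng = np.random.default_rng(1)
        counts = rng.poisson(20.0, size=(N_PAIRS, 8, scheme.n_bins)).astype(float)
        t1, m1 = _smoothed(counts, scheme)
        t2, m2 = _smoothed(2.0 * counts, scheme)
        w1 = derive_potential(t1, t1, m1)
        w2 = derive_potential(t2, t2, m2)
        np.testing.assert_allclose(w1.values, w2.values, rtol=1e-12)

    def test_converges_to_analytic_ratio_with_sample_size(self, scheme):
        # draw (pair, bin) samples from a known joint law and check the
        # derived energy approaches -kBT ln of the analytic ratio
        cfg = RunConfig()
        rng = np.random.default_rng(2)
        n_bins = scheme.n_bins
        joint = rng.uniform(0.5, 2.0, size=(N_PAIRS, n_bins))
        joint /= joint.sum()
        errors = []
        for n_samples in (20_000, 2_000_000):
            flat = rng.multinomial(n_samples, joint.ravel()).astype(float)
            counts = np.zeros((N_PAIRS, 8, n_bins))
            counts[:, LONG_RANGE, :] = flat.reshape(N_PAIRS, n_bins)
            t, mask = _smoothed(counts, scheme)
            table = derive_potential(t, t, mask, cfg)
            marg_pair = joint.sum(axis=1, keepdims=True)
            marg_bin = joint.sum(axis=0, keepdims=True)
            analytic = -cfg.kbt * np.log(joint / (marg_pair * marg_bin))
            sel = ~table.mask[:, LONG_RANGE, :]
            errors.append(
                np.abs(table.values[:, LONG_RANGE, :] - analytic)[sel].mean()
            )
        assert errors[1] < errors[0] / 3

    def test_scheme_mismatch_rejected(self, scheme):
        other = BinningScheme(separate_overflow=False)
        t1, m1 = _smoothed(np.ones((N_PAIRS, 8, scheme.n_bins)), scheme)
        t2, _ = _smoothed(np.ones((N_PAIRS, 8, other.n_bins)), other)
        with pytest.raises(Exception):
            derive_potential(t1, t2, m1)


class TestDeriveAll:
    def test_degenerate_split_reduces_to_total(self, scheme, default_config):
        # joint == composition dataset: the solubility-conditioned form
        # collapses to the classical potential, bin for bin
        rng = np.random.default_rng(3)
        counts = rng.poisson(15.0, size=(N_PAIRS, 8, scheme.n_bins)).astype(float)
        raw = PairCountTensor(counts=counts, scheme=scheme)
        sm, mask = prepare_counts(raw, default_config)
        w_cond = derive_potential(sm, sm, mask, default_config)
        w_tot = derive_potential(sm, sm, mask, default_config)
        np.testing.assert_array_equal(w_cond.values, w_tot.values)

    def test_label_swap_swaps_tables_exactly(self, planted_dataset,
                                             planted_stack, default_config):
        dataset, _, _ = planted_dataset
        w_sol, w_insol, w_tot = derive_from_stack(
            planted_stack, dataset.sol_indices, dataset.insol_indices,
            default_config,
        )
        s_sol, s_insol, s_tot = derive_from_stack(
            planted_stack, dataset.insol_indices, dataset.sol_indices,
            default_config,
        )
        np.testing.assert_array_equal(w_sol.values, s_insol.values)
        np.testing.assert_array_equal(w_insol.values, s_sol.values)
        np.testing.assert_array_equal(w_tot.values, s_tot.values)

    def test_planted_salt_bridge_deepens_soluble_potential(
        self, planted_dataset, planted_stack, default_config
    ):
        dataset, _, _ = planted_dataset
        w_sol, w_insol, _ = derive_from_stack(
            planted_stack, dataset.sol_indices, dataset.insol_indices,
            default_config,
        )
        from solpot.counting import bin_index

        b = bin_index(4.0, w_sol.scheme)
        p = pair_index("K", "E")
        assert w_sol.values[p, LONG_RANGE, b] < w_insol.values[p, LONG_RANGE, b]

    def test_empty_subset_rejected(self, planted_stack, default_config):
        with pytest.raises(ValueError):
            derive_from_stack(planted_stack, [], [0, 1], default_config)

    def test_derive_all_matches_stack_path(self, default_config):
        dataset, _, _ = generate_dataset(
            GeneratorParams(n_per_class=(5, 5), length_range=(30, 50), seed=21)
        )
        scheme = BinningScheme.from_config(default_config)
        stack = stack_counts(dataset.records, scheme)
        via_stack = derive_from_stack(
            stack, dataset.sol_indices, dataset.insol_indices, default_config
        )
        via_dataset = derive_all(dataset, default_config)
        for a, b in zip(via_stack, via_dataset):
            np.testing.assert_array_equal(a.values, b.values)


class TestEvaluate:
    def _table(self, scheme):
        values = np.zeros((N_PAIRS, 8, scheme.n_bins))
        mask = np.ones_like(values, dtype=bool)
        p = pair_index("F", "W")
        values[p, LONG_RANGE, 16] = -0.25
        mask[p, LONG_RANGE, 16] = False
        values[p, LONG_RANGE, scheme.overflow_bin] = 0.05
        mask[p, LONG_RANGE, scheme.overflow_bin] = False
        return PotentialTable(values=values, mask=mask, scheme=scheme)

    def test_masked_bin_scores_zero(self, scheme):
        table = self._table(scheme)
        assert table.evaluate("A", "A", 10, 5.0) == 0.0

    def test_symmetric_and_piecewise_constant(self, scheme):
        table = self._table(scheme)
        # bin 16 covers [6.2, 6.4)
        assert table.evaluate("F", "W", 12, 6.25) == -0.25
        assert table.evaluate("W", "F", 12, 6.35) == -0.25
        assert table.evaluate("F", "W", 12, 11.0) == 0.05

    def test_separation_below_two_rejected(self, scheme):
        with pytest.raises(ValueError):
            self._table(scheme).evaluate("F", "W", 1, 6.25)

    def test_masked_bins_must_store_zero(self, scheme):
        values = np.ones((N_PAIRS, 8, scheme.n_bins))
        mask = np.ones_like(values, dtype=bool)
        with pytest.raises(ValueError):
            PotentialTable(values=values, mask=mask, scheme=scheme)


class TestGroupPotentials:
    def test_single_pair_zero_shift_matches_pair_potential(self, default_config):
        cfg = default_config.replace(group_min_occurrences=10.0)
        dataset, _, _ = generate_dataset(
            GeneratorParams(n_per_class=(8, 8), length_range=(60, 80), seed=13)
        )
        scheme = BinningScheme.from_config(cfg)
        stack = stack_counts(dataset.records, scheme)
        tot_raw = PairCountTensor(counts=stack.sum(axis=0), scheme=scheme)
        tot_s, tot_m = prepare_counts(tot_raw, cfg)
        w_tot = derive_potential(tot_s, tot_s, tot_m, cfg)
        spec = GroupSpec(
            name="single", member_pairs=(("L", "L"),),
            radius_by_aa={}, reference_aa="L",
            min_occurrences=cfg.min_occurrences,
        )
        group = derive_group_potential(dataset.records, tot_s, tot_s, spec, cfg)
        p = pair_index("L", "L")
        sel = ~group.mask
        np.testing.assert_allclose(
            group.values[sel], w_tot.values[p, LONG_RANGE, sel], rtol=1e-9
        )

    def test_zero_shift_pooling_sums_member_counts(self, default_config):
        dataset, _, _ = generate_dataset(
            GeneratorParams(n_per_class=(6, 6), length_range=(50, 70), seed=14)
        )
        scheme = BinningScheme.from_config(default_config)
        stack = stack_counts(dataset.records, scheme)
        tot_raw = PairCountTensor(counts=stack.sum(axis=0), scheme=scheme)
        tot_s, _ = prepare_counts(tot_raw, default_config)
        spec = GroupSpec(
            name="pool", member_pairs=(("A", "L"), ("V", "V")),
            radius_by_aa={}, reference_aa="A",
        )
        group = derive_group_potential(
            dataset.records, tot_s, tot_s, spec, default_config
        )
        expected = (
            tot_s.counts[pair_index("A", "L"), LONG_RANGE, :]
            + tot_s.counts[pair_index("V", "V"), LONG_RANGE, :]
        )
        np.testing.assert_allclose(group.pooled_counts, expected, rtol=1e-9)

    def test_planted_aromatic_bias_separates_group_profiles(self, default_config):
        # strong aromatic enrichment in the insoluble class, weak in the
        # soluble class so both pooled profiles clear the 20-count threshold
        biases = (
            PlantedBias(pair=("W", "W"), distance=6.3, enrichment=8.0,
                        enrich_class="insol"),
            PlantedBias(pair=("F", "W"), distance=6.3, enrichment=8.0,
                        enrich_class="insol"),
            PlantedBias(pair=("W", "W"), distance=6.3, enrichment=2.0,
                        enrich_class="sol"),
            PlantedBias(pair=("F", "W"), distance=6.3, enrichment=2.0,
                        enrich_class="sol"),
        )
        dataset, _, _ = generate_dataset(
            GeneratorParams(seed=15, planted_biases=biases)
        )
        cfg = default_config
        scheme = BinningScheme.from_config(cfg)
        stack = stack_counts(dataset.records, scheme)
        sol_raw = PairCountTensor(
            counts=stack[list(dataset.sol_indices)].sum(axis=0), scheme=scheme
        )
        insol_raw = PairCountTensor(
            counts=stack[list(dataset.insol_indices)].sum(axis=0), scheme=scheme
        )
        tot_raw = PairCountTensor(counts=stack.sum(axis=0), scheme=scheme)
        sol_s, _ = prepare_counts(sol_raw, cfg)
        insol_s, _ = prepare_counts(insol_raw, cfg)
        tot_s, _ = prepare_counts(tot_raw, cfg)
        radii = empirical_radii(dataset.records)
        spec = GroupSpec(
            name="aromatic",
            member_pairs=(("F", "F"), ("F", "W"), ("W", "W")),
            radius_by_aa=radii, reference_aa="F",
        )
        g_sol = derive_group_potential(
            dataset.subset("sol"), sol_s, tot_s, spec, cfg
        )
        g_insol = derive_group_potential(
            dataset.subset("insol"), insol_s, tot_s, spec, cfg
        )
        from solpot.counting import bin_index

        b = bin_index(6.3, scheme)
        window = slice(max(b - 2, 0), b + 3)
        ok = ~(g_sol.mask[window] | g_insol.mask[window])
        assert ok.any()
        assert (g_insol.values[window][ok] < g_sol.values[window][ok]).all()

    def test_radius_below_reference_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec(
                name="bad", member_pairs=(("F", "W"),),
                radius_by_aa={"F": 1.0, "W": 0.5}, reference_aa="F",
            )


class TestSerialization:
    def test_potential_round_trip_bit_exact(self, tmp_path, planted_dataset,
                                            planted_stack, default_config):
        dataset, _, _ = planted_dataset
        w_sol, _, _ = derive_from_stack(
            planted_stack, dataset.sol_indices, dataset.insol_indices,
            default_config,
        )
        path = tmp_path / "w_sol.tsv"
        write_potential(w_sol, path, {"dataset_hash": "abc"})
        back = read_potential(path)
        np.testing.assert_array_equal(back.values, w_sol.values)
        np.testing.assert_array_equal(back.mask, w_sol.mask)
        assert back.kbt == w_sol.kbt and back.scheme == w_sol.scheme
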
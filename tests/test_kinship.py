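"""Inbreeding, relatedness, and coancestry against dense-matrix oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pedkit as pk
from pedkit.kinship import (
    inbreeding_array,
    founder_proportions,
    relationship_matvec,
    tabular_relationship_matrix,
)
from pedkit.simulate import simulate_wright_fisher_pedigree

from conftest import random_pedigree


class TestMeuwissenLuo:
    def test_outbred_offspring(self, trio):
        assert pk.inbreeding_meuwissen_luo(trio)["C"] == 0.0

    def test_fullsib_offspring_quarter(self, fullsib_mating):
        assert pk.inbreeding_meuwissen_luo(fullsib_mating)["X"] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_tabular_diagonal(self, seed):
        ped = random_pedigree(seed, n=200)
        F = inbreeding_array(ped)
        A = tabular_relationship_matrix(ped)
        assert np.max(np.abs(np.diag(A) - 1.0 - F)) < 1e-12


class TestRecursiveInbreeding:
    def test_identity_when_only_base_founders(self, small_registry):
        # complete parentage back to the pre-registry base: no imputation
        _, truth = small_registry
        res = pk.inbreeding_recursive(truth.full_pedigree)
        assert res.f_recursive == res.f_classical

    def test_lone_animal_with_unknown_parents(self):
        ped = pk.Pedigree.from_records([pk.PedigreeRecord("A", None, None, "male", 1990)])
        res = pk.inbreeding_recursive(ped)
        assert res.f_recursive["A"] == 0.0

    def test_never_below_classical_and_mean_strictly_above(self, small_registry):
        ped, _ = small_registry
        res = pk.inbreeding_recursive(ped)
        fc = np.array([res.f_classical[a] for a in ped.ids])
        fr = np.array([res.f_recursive[a] for a in ped.ids])
        assert np.all(fr >= fc - 1e-12)
        assert fr.mean() > fc.mean()
        assert res.converged


class TestRelatednessAndCoancestry:
    def test_two_unrelated_founders_ar_half(self):
        ped = pk.Pedigree.from_records([
            pk.PedigreeRecord("A", None, None, "male", 1980),
            pk.PedigreeRecord("B", None, None, "female", 1980)])
        ar = pk.average_relatedness(ped)
        assert ar["A"] == pytest.approx(0.5) and ar["B"] == pytest.approx(0.5)

    def test_singleton_ar_is_one(self):
        ped = pk.Pedigree.from_records([pk.PedigreeRecord("A")])
        assert pk.average_relatedness(ped)["A"] == pytest.approx(1.0)

    def test_ar_matches_dense_row_means(self):
        ped = random_pedigree(5, n=150)
        A = tabular_relationship_matrix(ped)
        members = ped.ids[40:120]
        idx = np.sort(ped.indices(members))
        ar = pk.average_relatedness(ped, members)
        dense = A[:, idx].mean(axis=1)
        assert max(abs(ar[ped.ids[i]] - dense[i]) for i in idx) < 1e-10

    def test_matvec_matches_dense(self):
        ped = random_pedigree(8, n=150)
        A = tabular_relationship_matrix(ped)
        x = np.random.default_rng(0).normal(size=len(ped))
        assert np.max(np.abs(relationship_matvec(ped, x) - A @ x)) < 1e-10

    def test_coancestry_textbook_values(self, trio):
        assert pk.mean_coancestry(trio, ["A", "B"]) == pytest.approx(0.0)
        assert pk.mean_coancestry(trio, ["A", "C"]) == pytest.approx(0.25)

    def test_coancestry_matches_dense_pair_mean(self):
        ped = random_pedigree(4, n=150)
        A = tabular_relationship_matrix(ped)
        members = ped.ids[30:140]
        idx = np.sort(ped.indices(members))
        sub = A[np.ix_(idx, idx)]
        n = len(idx)
        dense = (sub.sum() - np.trace(sub)) / (2 * n * (n - 1))
        assert pk.mean_coancestry(ped, members) == pytest.approx(dense, abs=1e-10)
        dense_self = sub.sum() / (2 * n * n)
        assert pk.mean_coancestry(ped, members, include_self=True) == \
            pytest.approx(dense_self, abs=1e-10)

    def test_singleton_pairwise_mean_errors(self, trio):
        with pytest.raises(ValueError):
            pk.mean_coancestry(trio, ["A"])


class TestAlpha:
    def test_random_mating_identity(self):
        assert pk.non_random_mating_alpha(0.02, 0.02) == pytest.approx(0.0)

    @given(st.floats(0, 0.5), st.floats(0, 0.5))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_wright_identity_roundtrip(self, f, c):
        alpha = pk.non_random_mating_alpha(f, c)
        assert (1 - f) == pytest.approx((1 - c) * (1 - alpha))

    def test_degenerate_coancestry_errors(self):
        with pytest.raises(ValueError):
            pk.non_random_mating_alpha(0.5, 1.0)

    def test_random_mating_population_alpha_near_zero(self):
        # Wright-Fisher: mates are drawn at random, so F tracks parent
        # coancestry and alpha stays at zero up to Mendelian noise
        alphas = []
        for seed in range(5):
            ped = simulate_wright_fisher_pedigree(80, 8, seed)
            f = inbreeding_array(ped)
            sl = pk.slice_by_birth_years(ped, 2008, 2008)
            idx = sl.member_indices
            parents = [ped.ids[i] for i in np.unique(np.concatenate(
                [ped.sire[idx], ped.dam[idx]]))]
            c = pk.mean_coancestry(ped, parents)
            alphas.append(pk.non_random_mating_alpha(float(f[idx].mean()), c))
        assert abs(np.mean(alphas)) < 3 * np.std(alphas) / np.sqrt(len(alphas)) + 0.01


class TestGci:
    def test_founder_is_one(self, trio):
        assert pk.gci(trio, "A") == pytest.approx(1.0)

    def test_two_founder_offspring(self, trio):
        assert pk.gci(trio, "C") == pytest.approx(2.0)

    def test_unbalanced_three_founders(self):
        ped = pk.Pedigree.from_records([
            pk.PedigreeRecord("F1", None, None, "male", 1980),
            pk.PedigreeRecord("F2", None, None, "female", 1980),
            pk.PedigreeRecord("F3", None, None, "female", 1981),
            pk.PedigreeRecord("P", "F1", "F2", "male", 1990),
            pk.PedigreeRecord("X", "P", "F3", "female", 2000)])
        # contributions (0.5, 0.25, 0.25)
        assert pk.gci(ped, "X") == pytest.approx(1 / (0.25 + 0.0625 + 0.0625))

    @pytest.mark.parametrize("seed", [2, 7])
    def test_proportions_conserved(self, seed):
        ped = random_pedigree(seed, n=120)
        for aid in ped.ids[::11]:
            assert sum(founder_proportions(ped, aid).values()) == pytest.approx(1.0)

    def test_anonymous_slot_counts_as_distinct_founder(self):
        ped = pk.Pedigree.from_records([
            pk.PedigreeRecord("A", None, None, "male", 1980),
            pk.PedigreeRecord("C", "A", None, "female", 1990)])
        p = founder_proportions(ped, "C")
        assert p == {"A": 0.5, "@dam:C": 0.5}
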
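"""Founder/ancestor accounting against a path-enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pedkit as pk
from pedkit.gene_origin import gene_origin_report
from pedkit.kinship import mean_coancestry

from conftest import random_pedigree


def path_oracle_contributions(ped, members):
    """Exhaustive path enumeration: founder shares of the pooled genome."""
    out = {}

    def walk(i, weight):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            out[ped.ids[i]] = out.get(ped.ids[i], 0.0) + weight
            return
        for par, slot in ((s, "sire"), (d, "dam")):
            if par >= 0:
                walk(par, weight / 2)
            else:
                key = f"@{slot}:{ped.ids[i]}"
                out[key] = out.get(key, 0.0) + weight / 2

    n = len(members)
    for aid in members:
        walk(ped.index[aid], 1.0 / n)
    return out


class TestFounderContributions:
    def test_founder_member_is_its_own_pool(self, trio):
        assert pk.founder_gene_contributions(trio, ["A"]) == {"A": 1.0}

    def test_offspring_splits_between_founders(self, trio):
        q = pk.founder_gene_contributions(trio, ["C"])
        assert q == {"A": 0.5, "B": 0.5}

    @pytest.mark.parametrize("seed", [0, 3, 12])
    def test_matches_path_enumeration(self, seed):
        ped = random_pedigree(seed, n=45)
        members = ped.ids[20:45]
        q = pk.founder_gene_contributions(ped, members)
        oracle = path_oracle_contributions(ped, members)
        assert set(q) == set(oracle)
        for k in q:
            assert q[k] == pytest.approx(oracle[k], abs=1e-12)
        assert sum(q.values()) == pytest.approx(1.0)


class TestEffectiveFounders:
    def test_two_equal(self):
        assert pk.effective_founders_fe({"a": 0.5, "b": 0.5}) == pytest.approx(2.0)

    def test_unbalanced(self):
        assert pk.effective_founders_fe({"a": 0.75, "b": 0.25}) == pytest.approx(1.6)

    @given(st.integers(1, 50))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_uniform_contributions_count_founders(self, n):
        q = {f"f{i}": 1.0 / n for i in range(n)}
        assert pk.effective_founders_fe(q) == pytest.approx(n)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pk.effective_founders_fe({})


class TestEffectiveAncestors:
    def test_single_ancestor_explains_all(self, trio):
        fa, marg = pk.effective_ancestors_fa(trio, ["C"])
        assert fa == pytest.approx(1.0)
        assert marg == [("C", 1.0)]

    def test_two_independent_lines(self):
        recs = [pk.PedigreeRecord(x, None, None, "unknown", 1980)
                for x in ("A", "B", "D", "E")]
        recs += [pk.PedigreeRecord("C1", "A", "B", "male", 1990),
                 pk.PedigreeRecord("C2", "D", "E", "female", 1990)]
        ped = pk.Pedigree.from_records(recs)
        fa, marg = pk.effective_ancestors_fa(ped, ["C1", "C2"])
        assert fa == pytest.approx(2.0)
        assert sorted(p for _, p in marg) == [0.5, 0.5]

    @pytest.mark.parametrize("seed", [1, 9])
    def test_conservation_and_bottleneck_ordering(self, seed, small_registry_pedigree):
        ped = small_registry_pedigree
        rng = np.random.default_rng(seed)
        members = list(rng.choice(ped.ids[-800:], size=150, replace=False))
        fa, marg = pk.effective_ancestors_fa(ped, members)
        assert sum(p for _, p in marg) == pytest.approx(1.0, abs=1e-9)
        fe = pk.effective_founders_fe(pk.founder_gene_contributions(ped, members))
        assert fa <= fe + 1e-9

    def test_marginals_non_increasing(self, small_registry_pedigree):
        sl = pk.slice_by_birth_years(small_registry_pedigree, 2015, 2024)
        ref = pk.reference_slice(sl)
        _, marg = pk.effective_ancestors_fa(small_registry_pedigree, ref)
        vals = [p for _, p in marg]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestPoolCounts:
    def test_majority_ancestor(self):
        assert pk.ancestors_for_pool([("a", 0.6), ("b", 0.4)], 50) == 1

    def test_cumulative_prefix(self):
        marg = [("a", 0.3), ("b", 0.3), ("c", 0.2), ("d", 0.2)]
        assert pk.ancestors_for_pool(marg, 75) == 3

    def test_full_pool_counts_positive_marginals(self):
        marg = [("a", 0.5), ("b", 0.5), ("c", 0.0)]
        assert pk.ancestors_for_pool(marg, 100) == 2

    def test_monotone_in_percentage(self, small_registry_pedigree):
        sl = pk.slice_by_birth_years(small_registry_pedigree, 2010, 2024)
        _, marg = pk.effective_ancestors_fa(small_registry_pedigree, sl)
        counts = [pk.ancestors_for_pool(marg, pct) for pct in (25, 50, 75, 100)]
        assert counts == sorted(counts)


class TestFgNenfLoss:
    def test_fg_from_mean_kinship(self):
        assert pk.founder_genome_equivalents(0.25) == pytest.approx(2.0)
        assert pk.founder_genome_equivalents(0.01802) == pytest.approx(27.74, abs=0.01)

    def test_fg_unrelated_flagged_infinite(self):
        assert np.isinf(pk.founder_genome_equivalents(0.0))

    def test_nenf_equal_fe_fg_infinite(self):
        assert np.isinf(pk.effective_nonfounders(30.0, 30.0))

    def test_nenf_variant_differs_by_factor_two(self):
        base = pk.effective_nonfounders(58.69, 27.74)
        halved = pk.effective_nonfounders(58.69, 27.74, caballero_toro=True)
        assert halved == pytest.approx(base / 2)

    @given(st.floats(0.6, 200), st.floats(0.6, 200))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_loss_partition_identity(self, fe, fg):
        fe, fg = max(fe, fg), min(fe, fg)
        rep = pk.diversity_loss(fe, fg)
        assert rep.loss_total == pytest.approx(
            rep.loss_unequal_founders + rep.loss_drift, abs=1e-12)
        assert 0 <= rep.gd <= rep.gd_star <= 100

    def test_no_drift_when_fg_equals_fe(self):
        rep = pk.diversity_loss(40.0, 40.0)
        assert rep.loss_drift == pytest.approx(0.0)


class TestAssembledReport:
    def test_registry_report_is_internally_consistent(self, small_registry_pedigree):
        ped = small_registry_pedigree
        ref = pk.reference_slice(pk.slice_by_birth_years(ped, 2015, 2024))
        rep = gene_origin_report(ped, ref)
        assert rep.fa <= rep.fe + 1e-9
        assert rep.fg <= rep.fe + 1e-9
        assert rep.ratio_fe_fa == pytest.approx(rep.fe / rep.fa)
        assert rep.n_ancestors_contributing == rep.pool_counts[100]
        assert rep.fa_int == round(rep.fa)
        # the self-inclusive mean kinship is what backs fg
        fbar = mean_coancestry(ped, ref, include_self=True)
        assert rep.fg == pytest.approx(1 / (2 * fbar))

    def test_half_founder_accounting(self):
        ped = pk.Pedigree.from_records([
            pk.PedigreeRecord("A", None, None, "male", 1980),
            pk.PedigreeRecord("C", "A", None, "female", 1990),
            pk.PedigreeRecord("B", None, None, "female", 1980),
            pk.PedigreeRecord("D", "A", "B", "male", 1991)])
        rep = gene_origin_report(ped, ["C", "D"])
        # pool: A (real founder), B (real founder), @dam:C (anonymous)
        assert rep.n_founders_contributing == 2
        assert rep.n_founders_f == 3
        assert rep.n_half_founder_adjusted == pytest.approx(2.5)
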
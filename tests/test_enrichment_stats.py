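"""Contingency statistics: chi2, Fisher, BH, screens, folds, assortativity."""

import math

import networkx as nx
import numpy as np
import pytest

from aarcode.alphabet import AMINO_ACIDS
from aarcode.enrichment_stats import (
    CombinationGroup,
    bh_fdr,
    build_combination_group,
    chi2_2x2,
    cross_species_trend,
    fisher_exact_2x2,
    fold_enrichment,
    interactome_assortativity,
    pairwise_cooccurrence_screen,
    set_enrichment_screen,
)
from aarcode.repeat_core import RepeatProfile
from aarcode.synthetic_data import ProteomeSpec, gen_presence_profile
from aarcode.workflows import UNIFORM_P_INSERT


def profile_from_presence(presence_sets, species="x"):
    mat = np.zeros((len(presence_sets), 20), dtype=bool)
    for i, s in enumerate(presence_sets):
        for aa in s:
            mat[i, AMINO_ACIDS.index(aa)] = True
    return RepeatProfile(species, tuple(f"p{i}" for i in range(len(presence_sets))),
                         AMINO_ACIDS, mat)


class TestChi2:
    def test_closed_form_without_correction(self):
        res = chi2_2x2([[10, 90], [30, 870]], yates=False)
        assert res.statistic == pytest.approx(10.4167, abs=1e-3)

    def test_closed_form_with_yates(self):
        res = chi2_2x2([[10, 90], [30, 870]], yates=True)
        assert res.statistic == pytest.approx(8.7529, abs=1e-3)

    def test_proportional_table_is_null(self):
        res = chi2_2x2([[10, 90], [20, 180]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2([[0, 0], [5, 5]])

    def test_fold_and_direction(self):
        res = chi2_2x2([[10, 90], [30, 870]])
        # expected a-cell: 100*40/1000 = 4 -> fold 2.5, over
        assert res.fold == pytest.approx(2.5)
        assert res.direction == "over"


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_uniform_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        """Full hypergeometric enumeration for all tables with N <= 40."""

        def oracle(t):
            (a, b), (c, d) = t
            r1, r2 = a + b, c + d
            c1 = a + c
            n = r1 + r2
            denom = math.comb(n, c1)
            pmf = lambda k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom
            p_obs = pmf(a)
            lo, hi = max(0, c1 - r2), min(r1, c1)
            return sum(
                pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-7)
            )

        for _ in range(200):
            a, b, c, d = rng.integers(0, 11, size=4)
            t = [[int(a), int(b)], [int(c), int(d)]]
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(oracle(t), abs=1e-9)


class TestBH:
    def test_hand_worked_stepup(self):
        reject, _ = bh_fdr([0.001, 0.01, 0.02, 0.04, 0.5], q=0.05)
        assert list(reject) == [True, True, True, True, False]

    def test_all_ones_none_rejected(self):
        reject, _ = bh_fdr([1.0] * 10, q=0.05)
        assert not reject.any()

    def test_single_small_p_rejected(self):
        reject, _ = bh_fdr([0.01], q=0.05)
        assert reject.all()

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_adjusted_p_reimplementation(self, rng):
        """Independent oracle: sorted p * m/i, monotone min from the right."""

        def oracle(pvals, q):
            p = np.asarray(pvals)
            m = p.size
            order = np.argsort(p, kind="mergesort")
            adj = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            out = np.empty(m)
            out[order] = np.minimum(adj, 1.0)
            return out <= q, out

        for _ in range(300):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            if rng.random() < 0.3:  # inject ties
                p = np.round(p, 1)
            rej, adj = bh_fdr(p, 0.05)
            orej, oadj = oracle(p, 0.05)
            assert (rej == orej).all()
            np.testing.assert_allclose(adj, oadj, atol=1e-12)


class TestPairwiseScreen:
    def test_all_190_pairs_tested_when_margins_valid(self):
        spec = ProteomeSpec(n_proteins=2000, p_insert=UNIFORM_P_INSERT, seed=8)
        screen = pairwise_cooccurrence_screen(gen_presence_profile(spec))
        assert screen.n_tested == 190
        assert not screen.excluded

    def test_absent_aar_pairs_excluded(self):
        prof = profile_from_presence([{"A", "Q"}, {"A"}, {"Q"}, set()] * 5)
        screen = pairwise_cooccurrence_screen(prof)
        # only the A,Q pair has both margins nonzero
        assert screen.n_tested == 1
        assert len(screen.excluded) == 189

    def test_planted_association_detected(self):
        spec = ProteomeSpec(
            n_proteins=5000,
            p_insert=UNIFORM_P_INSERT,
            pair_boost={("A", "G"): 5.0},
            seed=17,
        )
        screen = pairwise_cooccurrence_screen(gen_presence_profile(spec))
        row = screen.results.set_index("unit_id").loc["A+G"]
        assert row["q_reject"]
        assert row["direction"] == "over"


class TestCombinationGroups:
    presence = [{"A", "G"}, {"A"}, {"G"}]

    def test_both(self):
        g = build_combination_group(profile_from_presence(self.presence), "A+G")
        assert g.members == {"p0"}

    def test_without(self):
        g = build_combination_group(profile_from_presence(self.presence), "A-G")
        assert g.members == {"p1"}

    def test_star_is_partition_union(self):
        prof = profile_from_presence(self.presence)
        star = build_combination_group(prof, "A*")
        both = build_combination_group(prof, "A+G")
        without = build_combination_group(prof, "A-G")
        assert star.members == both.members | without.members
        assert not (both.members & without.members)

    def test_unknown_letter_errors(self):
        with pytest.raises(ValueError):
            build_combination_group(profile_from_presence(self.presence), "B+G")


class TestSetEnrichment:
    def test_identical_group_and_set_maximal_fold(self):
        ids = [f"p{i}" for i in range(1000)]
        members = frozenset(ids[:50])
        screen, chi2m = set_enrichment_screen(
            [CombinationGroup("A*", members)], {"t": set(members)}, ids
        )
        row = screen.results.iloc[0]
        assert row["direction"] == "over"
        assert row["a"] == 50
        assert fold_enrichment(members, members, ids) == pytest.approx(20.0)
        assert chi2m.at["A*", "t"] == pytest.approx(row["statistic"])

    def test_empty_set_skipped_and_flagged(self):
        ids = [f"p{i}" for i in range(100)]
        screen, _ = set_enrichment_screen(
            [CombinationGroup("A*", frozenset(ids[:10]))], {"t": set()}, ids
        )
        assert screen.n_tested == 0
        assert screen.excluded


class TestFold:
    def test_arithmetic(self):
        ids = [f"p{i}" for i in range(10000)]
        group = ids[:100]
        aset = set(ids[:20]) | set(ids[100:580])  # overlap 20, |set| 500
        assert fold_enrichment(group, aset, ids) == pytest.approx(4.0)

    def test_zero_overlap(self):
        ids = [f"p{i}" for i in range(100)]
        assert fold_enrichment(ids[:10], ids[50:60], ids) == 0.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            fold_enrichment([], ["p1"], ["p1", "p2"])

    def test_invariant_under_relabeling_and_duplication(self):
        ids = [f"p{i}" for i in range(200)]
        group, aset = ids[:40], set(ids[20:80])
        base = fold_enrichment(group, aset, ids)
        relabeled = fold_enrichment(
            [f"x{g}" for g in group], {f"x{a}" for a in aset}, [f"x{i}" for i in ids]
        )
        assert relabeled == pytest.approx(base)
        dup_ids = ids + [f"{i}_b" for i in ids]
        dup_group = list(group) + [f"{g}_b" for g in group]
        dup_set = set(aset) | {f"{a}_b" for a in aset}
        assert fold_enrichment(dup_group, dup_set, dup_ids) == pytest.approx(base)


class TestCrossSpeciesTrend:
    def _species(self, seed, species):
        spec = ProteomeSpec(n_proteins=1500, p_insert=UNIFORM_P_INSERT, seed=seed)
        prof = gen_presence_profile(spec, species_id=species)
        bearers = sorted(prof.bearing("A"))
        others = sorted(set(prof.protein_ids) - set(bearers))
        term = set(bearers[: len(bearers) // 2]) | set(others[:100])
        return prof, {"t": term}

    def test_identical_species_flat_trend(self):
        one = self._species(5, "s1")
        per_species = [one, (gen_presence_profile(
            ProteomeSpec(n_proteins=1500, p_insert=UNIFORM_P_INSERT, seed=5), "s2"),
            one[1])]
        df = cross_species_trend(per_species, "A*", "t")
        assert df["fold"].iloc[0] == pytest.approx(df["fold"].iloc[1])

    def test_normalization_to_reference(self):
        per_species = [self._species(s, f"s{s}") for s in range(3)]
        df = cross_species_trend(per_species, "A*", "t", normalize_to="s0")
        assert df["fold_normalized"].iloc[0] == pytest.approx(1.0)

    def test_missing_term_flagged(self):
        per_species = [self._species(s, f"s{s}") for s in range(2)]
        per_species[1] = (per_species[1][0], {})
        df = cross_species_trend(per_species, "A*", "t")
        assert not df["missing"].iloc[0]
        assert df["missing"].iloc[1]

    def test_needs_two_species(self):
        with pytest.raises(ValueError):
            cross_species_trend([self._species(1, "s1")], "A*", "t")


class TestAssortativity:
    def test_star_normalized_proportion(self):
        """Center bears A, all 4 leaves bear A, proteome-wide A fraction is
        0.5 -> normalized interactor proportion 2.0."""
        g = nx.star_graph(["c", "l1", "l2", "l3", "l4"])
        presence = {"c": {"A"}, "l1": {"A"}, "l2": {"A"}, "l3": {"A"}, "l4": {"A"}}
        presence.update({f"bg{i}": set() for i in range(5)})  # baseline 5/10
        rep = interactome_assortativity(g, presence, ["c"], ["A"])
        row = rep.per_aar.set_index("aar").loc["A"]
        assert row["normalized_proportion"] == pytest.approx(2.0)
        assert rep.mean_degree == pytest.approx(4.0)

    def test_no_interactor_bears_x(self):
        g = nx.star_graph(["c", "l1", "l2"])
        presence = {"c": {"A"}, "l1": set(), "l2": set(), "bg": {"A"}}
        rep = interactome_assortativity(g, presence, ["c"], ["A"])
        row = rep.per_aar.set_index("aar").loc["A"]
        assert row["frac_bearing"] == 0.0

    def test_missing_focal_excluded(self):
        g = nx.path_graph(["a", "b"])
        presence = {"a": {"A"}, "b": {"A"}}
        rep = interactome_assortativity(g, presence, ["a", "ghost"], ["A"])
        assert rep.n_focal_missing == 1
        assert rep.n_focal_used == 1
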
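import itertools

import numpy as np
import pytest

from panelkit import (
    greedy_core_snps,
    pair_guarantee_stats,
    pairwise_diff,
    saturation_curve,
    select_core_lines,
)
from panelkit.io_formats import MISSING, GenotypeMatrix, SampleMeta
import pandas as pd

from conftest import gm


def random_instance(rng, n_samples, n_loci, missing_rate=0.05):
    codes = np.array(["AA", "AG", "GG", MISSING])
    probs = np.array([(1 - missing_rate) * p for p in (0.45, 0.10, 0.45)]
                     + [missing_rate])
    data = codes[rng.choice(4, size=(n_samples, n_loci), p=probs)]
    df = pd.DataFrame(data, index=[f"s{i:02d}" for i in range(n_samples)],
                      columns=[f"L{j:02d}" for j in range(n_loci)])
    df.index.name = "sample_id"
    return GenotypeMatrix(df)


def resolution_sets(matrix):
    vals = matrix.values()
    n = matrix.n_samples
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    per_locus = []
    for jcol in range(vals.shape[1]):
        col = vals[:, jcol]
        per_locus.append(
            {
                b for b, (i, k) in enumerate(pairs)
                if col[i] != MISSING and col[k] != MISSING
                and col[i] != col[k]
            }
        )
    return per_locus, len(pairs)


def exhaustive_minimum(matrix, cap=7):
    """Smallest locus subset resolving all resolvable pairs, by direct
    subset enumeration (test instances only)."""
    per_locus, _ = resolution_sets(matrix)
    full = set().union(*per_locus) if per_locus else set()
    if not full:
        return 0
    L = len(per_locus)
    for k in range(1, min(cap, L) + 1):
        for combo in itertools.combinations(range(L), k):
            covered = set().union(*(per_locus[j] for j in combo))
            if covered == full:
                return k
    return None


class TestGreedyCoreSnps:
    def test_two_locus_minimal_pair(self):
        m = gm({"s1": ["AA", "AA"], "s2": ["AA", "GG"], "s3": ["GG", "GG"]})
        res = greedy_core_snps(m)
        assert len(res.selected) == 2
        assert res.n_resolvable == 3
        assert res.cumulative_fraction[-1] == 1.0
        assert exhaustive_minimum(m) == 2

    def test_identical_samples_unresolvable(self):
        m = gm({"s1": ["AA", "GG"], "s2": ["AA", "GG"]})
        res = greedy_core_snps(m)
        assert res.selected == []
        assert res.unresolved_pairs == [("s1", "s2")]

    def test_newly_resolved_positive_and_fraction_monotone(self, truth_matrix):
        res = greedy_core_snps(truth_matrix)
        assert all(k > 0 for k in res.newly_resolved)
        assert res.cumulative_fraction == sorted(res.cumulative_fraction)
        assert res.cumulative_fraction[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_near_optimal_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = random_instance(rng, n_samples=rng.integers(6, 11),
                            n_loci=rng.integers(8, 14))
        res = greedy_core_snps(m)
        per_locus, n_pairs = resolution_sets(m)
        full = set().union(*per_locus)
        assert res.n_resolvable == len(full)
        # completeness: greedy resolves everything the panel can
        covered = set().union(
            *(per_locus[m.loci.index(l)] for l in res.selected)
        ) if res.selected else set()
        assert covered == full
        opt = exhaustive_minimum(m)
        assert len(res.selected) <= opt + 1


class TestSaturationCurve:
    def test_prefix_zero(self, truth_matrix):
        res = greedy_core_snps(truth_matrix)
        curve = saturation_curve(truth_matrix, res.selected)
        assert curve.loc[0, "resolved_pairs"] == 0
        assert curve.loc[0, "distinct_combinations"] == 1

    def test_monotone_and_complete(self):
        rng = np.random.default_rng(2)
        m = random_instance(rng, 10, 12)
        res = greedy_core_snps(m)
        curve = saturation_curve(m, res.selected)
        assert (np.diff(curve["resolved_pairs"]) >= 0).all()
        assert (np.diff(curve["distinct_combinations"]) >= 0).all()
        assert curve["resolved_pairs"].iloc[-1] == res.n_resolvable


class TestPairGuarantee:
    def test_hand_counted_fraction(self):
        # pairwise diff counts {s1-s2: 3, s1-s3: 2, s2-s3: 1}
        m = gm({
            "s1": ["AA", "AA", "AA", "AA"],
            "s2": ["GG", "GG", "GG", "AA"],
            "s3": ["GG", "GG", "AA", "AA"],
        })
        assert pair_guarantee_stats(m, m.loci, k=2) == pytest.approx(2 / 3)
        assert pair_guarantee_stats(m, m.loci, k=1) == 1.0

    def test_duplicate_samples_cap_fraction(self):
        m = gm({"s1": ["AA", "GG"], "s2": ["AA", "GG"], "s3": ["GG", "AA"]})
        assert pair_guarantee_stats(m, m.loci, k=1) < 1.0

    def test_adding_locus_never_decreases_fraction(self):
        rng = np.random.default_rng(5)
        m = random_instance(rng, 8, 10, missing_rate=0.0)
        loci = m.loci
        for k in (1, 2):
            prev = 0.0
            for upto in range(1, len(loci) + 1):
                frac = pair_guarantee_stats(m, loci[:upto], k=k)
                assert frac >= prev - 1e-12
                prev = frac


class TestCoreLines:
    def _meta(self, ids, labels):
        return [SampleMeta(s, population=l[:4], subpopulation=l)
                for s, l in zip(ids, labels)]

    def test_identical_lines_pick_first_by_label(self):
        m = gm({f"s{i:02d}": ["AA", "GG"] for i in range(10)})
        meta = self._meta(m.samples, ["POP1A"] * 10)
        res = select_core_lines(pairwise_diff(m), meta)
        assert res.selected["POP1A"] == ["s00"]

    def test_round_half_up_with_floor(self, truth_matrix, fixture_meta):
        # subpopulation sizes (46, 42, 30, 8) at 10% -> 5, 4, 3, 1
        res = select_core_lines(pairwise_diff(truth_matrix), fixture_meta)
        sizes = {k: len(v) for k, v in res.selected.items()}
        assert sizes == {"POP1A": 5, "POP1B": 4, "POP2A": 3, "POP2B": 1}

    def test_eleven_members_select_one(self):
        m = gm({f"s{i:02d}": ["AA" if i % 2 else "GG", "AA"]
                for i in range(11)})
        meta = self._meta(m.samples, ["POP2B"] * 11)
        res = select_core_lines(pairwise_diff(m), meta)
        assert len(res.selected["POP2B"]) == 1  # round_half_up(1.1) == 1

    def test_invariant_to_input_ordering(self, truth_matrix, fixture_meta):
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(truth_matrix.samples))
        r1 = select_core_lines(pairwise_diff(truth_matrix), fixture_meta)
        r2 = select_core_lines(
            pairwise_diff(truth_matrix.subset_samples(perm)), fixture_meta
        )
        assert r1.selected == r2.selected
        assert r1.ranking == r2.ranking

    def test_selected_are_most_central(self, truth_matrix, fixture_meta):
        diff = pairwise_diff(truth_matrix)
        res = select_core_lines(diff, fixture_meta)
        by_id = {m.sample_id: m.subpopulation for m in fixture_meta}
        idx = {s: i for i, s in enumerate(diff.sample_ids)}
        for lab, ranked in res.ranking.items():
            members = [s for s in diff.sample_ids if by_id[s] == lab]
            rows = [idx[s] for s in members]
            means = {
                s: diff.n_diff[np.ix_([idx[s]], rows)].sum() / (len(rows) - 1)
                for s in members
            }
            assert means[ranked[0]] == min(means.values())
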
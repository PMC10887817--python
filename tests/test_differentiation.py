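import itertools

import numpy as np
import pandas as pd
import pytest

from panelkit import GenotypeMatrix, amova, pairwise_fst, wc_theta
from panelkit.io_formats import MISSING, SampleMeta
from panelkit.synthetic_data import (
    SimulationConfig,
    SubpopSpec,
    simulate_dataset,
)

from conftest import gm


def two_group_meta(ids, split):
    return [
        SampleMeta(s, population="P", subpopulation="A" if i < split else "B")
        for i, s in enumerate(ids)
    ]


class TestWcTheta:
    def test_complete_fixation_gives_one(self):
        rows = {f"a{i}": ["AA", "CC"] for i in range(4)}
        rows.update({f"b{i}": ["GG", "TT"] for i in range(4)})
        m = gm(rows)
        assert wc_theta(m, two_group_meta(m.samples, 4)) == pytest.approx(1.0)

    def test_null_split_of_panmictic_pool_near_zero(self):
        config = SimulationConfig(
            n_loci=200,
            subpop_specs=(SubpopSpec("POOL", 100, 0.001, 0.0),),
            seed=7,
        )
        _, truth = simulate_dataset(config)
        ids = truth.genotypes.samples
        meta = two_group_meta(ids, 50)
        theta = wc_theta(truth.genotypes, meta)
        assert abs(theta) < 0.02

    def test_divergence_recovery(self):
        config = SimulationConfig(
            n_loci=200,
            subpop_specs=(
                SubpopSpec("A", 60, 0.30, 0.97),
                SubpopSpec("B", 60, 0.30, 0.97),
            ),
            seed=1,
        )
        _, truth = simulate_dataset(config)
        theta = wc_theta(truth.genotypes, truth.meta)
        assert theta == pytest.approx(0.30, abs=0.05)

    def test_group_order_invariance(self, truth_matrix, fixture_meta):
        t1 = wc_theta(truth_matrix, fixture_meta, groups=["POP1A", "POP1B"])
        t2 = wc_theta(truth_matrix, fixture_meta, groups=["POP1B", "POP1A"])
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_pairwise_matrix_symmetric(self, truth_matrix, fixture_meta):
        f = pairwise_fst(truth_matrix, fixture_meta)
        v = f.values
        off = ~np.eye(len(f.group_labels), dtype=bool)
        assert np.allclose(v[off], v.T[off])
        assert np.isnan(np.diag(v)).all()


def brute_force_ss(matrix, groups):
    """Oracle: SS within groups from explicit pairwise 0/1 allele
    distances, SS_W = sum_g (1/n_g) sum_{i<j in g} d_ij over allele
    vectors.  Depends only on allele multisets, so the arbitrary split of
    a genotype into two allele draws does not matter."""
    vals = matrix.values()
    total = 0.0
    for members in groups:
        for j in range(vals.shape[1]):
            alleles = []
            for i in members:
                c = vals[i, j]
                if c != MISSING:
                    alleles.extend([c[0], c[1]])
            n = len(alleles)
            if n == 0:
                continue
            diffs = sum(
                1 for a, b in itertools.combinations(alleles, 2) if a != b
            )
            total += diffs / n
    return total


class TestAmova:
    def _toy(self):
        # 8 individuals x 3 loci, 2 pops x 2 subpops x 2 individuals
        rows = {
            "p1a1": ["AA", "AG", "CC"],
            "p1a2": ["AA", "GG", "CC"],
            "p1b1": ["AG", "GG", "CT"],
            "p1b2": ["GG", "GG", "TT"],
            "p2a1": ["GG", "AA", "TT"],
            "p2a2": ["GG", "AA", "CT"],
            "p2b1": ["AG", "AA", "TT"],
            "p2b2": ["GG", "AG", "TT"],
        }
        m = gm(rows)
        meta = [
            SampleMeta(s, population=s[:2].upper(),
                       subpopulation=s[:3].upper())
            for s in rows
        ]
        return m, meta

    def test_matches_hand_oracle(self):
        """SS strata match a brute-force pairwise-distance computation and
        variance components match the balanced nested-design closed form."""
        m, meta = self._toy()
        res = amova(m, meta).table
        n = 8
        idx = {s: i for i, s in enumerate(m.samples)}
        pops = [[idx[s] for s in m.samples if s.startswith(p)]
                for p in ("p1", "p2")]
        subs = [[idx[s] for s in m.samples if s.startswith(q)]
                for q in ("p1a", "p1b", "p2a", "p2b")]
        inds = [[i] for i in range(n)]
        ss_tot = brute_force_ss(m, [list(range(n))])
        ss_pop = brute_force_ss(m, pops)
        ss_sub = brute_force_ss(m, subs)
        ss_ind = brute_force_ss(m, inds)
        expected_ss = [ss_tot - ss_pop, ss_pop - ss_sub, ss_sub - ss_ind,
                       ss_ind]
        assert res["sum_sq"][:4].to_numpy() == pytest.approx(expected_ss)
        # balanced design (2 x 2 x 2 x 2 alleles): closed-form EMS
        ms = [expected_ss[0] / 1, expected_ss[1] / 2, expected_ss[2] / 4,
              expected_ss[3] / 8]
        sig_e = ms[3]
        sig_c = (ms[2] - sig_e) / 2
        sig_b = (ms[1] - sig_e - 2 * sig_c) / 4
        sig_a = (ms[0] - sig_e - 2 * sig_c - 4 * sig_b) / 8
        assert res["variance_component"][:4].to_numpy() == pytest.approx(
            [sig_a, sig_b, sig_c, sig_e]
        )

    def test_df_and_percentage_integrity(self, truth_matrix, fixture_meta):
        res = amova(truth_matrix, fixture_meta).table
        n = truth_matrix.n_samples
        assert res["df"][:4].tolist() == [1, 2, n - 4, n]
        assert res.loc["Total", "df"] == 2 * n - 1
        comps = res["variance_component"][:4].to_numpy()
        assert comps.sum() == pytest.approx(
            res.loc["Total", "variance_component"]
        )
        assert res["pct_variation"][:4].sum() == pytest.approx(100, abs=0.1)

    def test_fixed_alternate_alleles_all_between_populations(self):
        rows = {f"a{i}": ["AA", "CC"] for i in range(4)}
        rows.update({f"b{i}": ["GG", "TT"] for i in range(4)})
        m = gm(rows)
        meta = [
            SampleMeta(s, population=s[0].upper(),
                       subpopulation=s[0].upper() + "s")
            for s in rows
        ]
        res = amova(m, meta).table
        assert res.loc["Between populations", "pct_variation"] == (
            pytest.approx(100, abs=1e-9)
        )

    def test_all_identical_is_degenerate(self):
        rows = {f"s{i}": ["AA", "GG"] for i in range(4)}
        meta = [
            SampleMeta(f"s{i}", population="P1" if i < 2 else "P2",
                       subpopulation="P1a" if i < 2 else "P2a")
            for i in range(4)
        ]
        res = amova(gm(rows), meta)
        assert res.degenerate
        assert (res.table["sum_sq"] == 0).all()

    def test_collapsing_subpop_level_preserves_total_variance(self):
        rng = np.random.default_rng(3)
        codes = np.array(["AA", "AG", "GG"])
        rows = {
            f"s{i:02d}": list(codes[rng.integers(0, 3, size=10)])
            for i in range(16)
        }
        m = gm(rows)
        pops = ["P1"] * 8 + ["P2"] * 8
        subs = ["P1a"] * 4 + ["P1b"] * 4 + ["P2a"] * 4 + ["P2b"] * 4
        nested = [SampleMeta(s, population=p, subpopulation=q)
                  for s, p, q in zip(m.samples, pops, subs)]
        collapsed = [SampleMeta(s, population=p, subpopulation=p + "x")
                     for s, p in zip(m.samples, pops)]
        t1 = amova(m, nested).table
        t2 = amova(m, collapsed).table
        assert t1.loc["Total", "variance_component"] == pytest.approx(
            t2.loc["Total", "variance_component"], abs=1e-9
        )
        assert t2.loc[
            "Between subpopulations within populations", "variance_component"
        ] == 0.0

    def test_monotone_in_simulated_divergence(self):
        thetas = []
        for f in (0.05, 0.15, 0.3, 0.5):
            config = SimulationConfig(
                n_loci=120,
                subpop_specs=(
                    SubpopSpec("A", 40, f, 0.97),
                    SubpopSpec("B", 40, f, 0.97),
                ),
                seed=11,
            )
            _, truth = simulate_dataset(config)
            thetas.append(wc_theta(truth.genotypes, truth.meta))
        assert thetas == sorted(thetas)
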
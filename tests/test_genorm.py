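import itertools

import numpy as np
import pandas as pd
import pytest

from refstab.genorm import genorm_rank, m_value, pairwise_variation
from refstab.preprocess import QMatrix, q_transform
from refstab.synthetic_data import SimConfig, simulate_ct

from .conftest import make_ct


def brute_force_m(q: QMatrix, gene: str, active: list[str]) -> float:
    """Independent oracle: average pairwise log-ratio SD, pair by pair."""
    vs = [
        pairwise_variation(q.values.loc[gene], q.values.loc[other])
        for other in active
        if other != gene
    ]
    return float(np.mean(vs))


class TestPairwiseVariation:
    def test_proportional_vectors_give_zero(self):
        assert pairwise_variation([1, 0.5, 0.25], [0.8, 0.4, 0.2]) == pytest.approx(0)

    def test_hand_example_v_equals_one(self):
        """log2 ratios (0, -1, -2) against a flat partner: sd (n-1) = 1."""
        assert pairwise_variation([1, 0.5, 0.25], [1, 1, 1]) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0.1, 1, 5), rng.uniform(0.1, 1, 5)
        assert pairwise_variation(a, b) == pairwise_variation(b, a)

    def test_scale_invariance(self):
        a, b = np.array([1, 0.5, 0.25]), np.array([0.9, 0.7, 0.5])
        assert pairwise_variation(a, b) == pytest.approx(
            pairwise_variation(3.7 * a, b), abs=1e-12
        )

    def test_nonpositive_fatal(self):
        with pytest.raises(ValueError):
            pairwise_variation([1, 0.0, 0.5], [1, 1, 1])


class TestMValue:
    def test_two_proportional_genes(self, hand_q):
        ct = make_ct([[20, 21, 23], [22, 23, 25], [15, 15, 15]])
        q = q_transform(ct)
        assert m_value(q, "g0", ["g0", "g1"]) == pytest.approx(0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        ct = make_ct(rng.uniform(15, 30, size=(5, 6)))
        q = q_transform(ct)
        active = q.gene_ids
        for gene in active:
            assert m_value(q, gene, active) == pytest.approx(
                brute_force_m(q, gene, active), abs=1e-12
            )

    def test_duplicated_stable_partner_lowers_m(self):
        """Adding a co-regulated copy of a gene pulls its M down."""
        rng = np.random.default_rng(8)
        vals = rng.uniform(15, 30, size=(4, 6))
        vals = np.vstack([vals, vals[0] + 1.0])  # g4 proportional to g0
        q = q_transform(make_ct(vals))
        m_without = m_value(q, "g0", ["g0", "g1", "g2", "g3"])
        m_with = m_value(q, "g0", ["g0", "g1", "g2", "g3", "g4"])
        assert m_with < m_without


class TestGenormRank:
    def test_three_genes_structure(self):
        rng = np.random.default_rng(2)
        q = q_transform(make_ct(rng.uniform(15, 30, size=(3, 5))))
        res = genorm_rank(q)
        assert len(res.exclusion_order) == 1
        assert sorted(res.ranks.tolist()) == [1, 1, 3]

    def test_rank_pattern_competition(self):
        rng = np.random.default_rng(9)
        q = q_transform(make_ct(rng.uniform(12, 35, size=(8, 6))))
        ranks = sorted(genorm_rank(q).ranks.tolist())
        assert ranks == [1, 1] + list(range(3, 9))

    def test_iterative_equals_brute_force_at_every_step(self):
        """Replay the exclusion loop with the pair-by-pair oracle."""
        rng = np.random.default_rng(4)
        q = q_transform(make_ct(rng.uniform(15, 30, size=(6, 5))))
        res = genorm_rank(q)
        active = list(q.gene_ids)
        for step, trace in enumerate(res.m_trace):
            assert sorted(trace) == sorted(active)
            for gene in active:
                assert trace[gene] == pytest.approx(
                    brute_force_m(q, gene, active), abs=1e-12
                )
            if len(active) > 2:
                worst = max(active, key=lambda g: (trace[g], -active.index(g)))
                assert worst == res.exclusion_order[step]
                active.remove(worst)

    def test_planted_noise_recovery_majority(self):
        """Low-noise genes win rank 1; the noisiest gene lands last (majority of 100 seeds)."""
        genes = ["a", "b", "c", "d"]
        sigma = np.array([0.05, 0.05, 0.5, 1.0])
        top_hits = last_hits = 0
        for seed in range(100):
            cfg = SimConfig(
                gene_ids=genes,
                baselines=np.full(4, 20.0),
                noise_sd=sigma,
                group_shift=np.zeros(4),
                sample_effect_sd=0.5,
                group_sizes=(6, 0),
                seed=seed,
            )
            ct, _ = simulate_ct(cfg)
            res = genorm_rank(q_transform(ct))
            if res.ranks["a"] == 1 and res.ranks["b"] == 1:
                top_hits += 1
            if res.ranks["d"] == 4:
                last_hits += 1
        assert top_hits > 50
        assert last_hits > 50

    def test_gene_scale_invariance(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(15, 30, size=(5, 6))
        q0 = q_transform(make_ct(vals))
        shifted = vals.copy()
        shifted[2] += 4.0  # Ct shift == scaling Q by a positive constant
        q1 = q_transform(make_ct(shifted))
        r0, r1 = genorm_rank(q0), genorm_rank(q1)
        pd.testing.assert_series_equal(r0.ranks, r1.ranks)
        pd.testing.assert_series_equal(r0.m_initial, r1.m_initial)

    def test_sample_scale_invariance(self):
        """A per-sample loading shift cancels in every log ratio."""
        rng = np.random.default_rng(10)
        vals = rng.uniform(15, 30, size=(5, 6))
        shifted = vals + rng.normal(0, 2, size=(1, 6))  # same shift for all genes
        r0 = genorm_rank(q_transform(make_ct(vals)))
        r1 = genorm_rank(q_transform(make_ct(shifted)))
        pd.testing.assert_series_equal(r0.ranks, r1.ranks)
        np.testing.assert_allclose(r0.m_initial, r1.m_initial, atol=1e-9)

    def test_flagging_against_threshold(self):
        rng = np.random.default_rng(12)
        vals = np.vstack(
            [
                20 + rng.normal(0, 0.05, size=(3, 8)),
                25 + rng.normal(0, 4.0, size=(1, 8)),  # wildly unstable
            ]
        )
        vals = np.clip(vals, 10, 40)
        res = genorm_rank(q_transform(make_ct(vals)))
        assert "g3" in res.flagged_unstable
        assert "g0" not in res.flagged_unstable

    def test_fewer_than_three_genes_fatal(self):
        q = QMatrix(pd.DataFrame([[1.0, 0.5], [1.0, 0.7]], index=["a", "b"]))
        with pytest.raises(ValueError):
            genorm_rank(q)
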
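"""Unit, oracle and property tests for the four stability algorithms.

The geNorm oracles here are written from first principles (explicit Python
loops over gene pairs and statistics.stdev) and never call the package's own
linear-algebra path.
"""

import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest

from refstab.stability import (
    bestkeeper_stats,
    delta_ct_stability,
    genorm_m,
    genorm_rank,
    normfinder_stability,
    pairwise_variation,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def quantities_oracle(ct_rows):
    """Q = 2**(min - ct), computed cell by cell."""
    out = []
    for row in ct_rows:
        m = min(row)
        out.append([2.0 ** (m - v) for v in row])
    return out


def genorm_m_oracle(ct_rows):
    q = quantities_oracle(ct_rows)
    logs = [[math.log2(v) for v in row] for row in q]
    k = len(logs)
    ms = []
    for i in range(k):
        sds = []
        for j in range(k):
            if j == i:
                continue
            diffs = [a - b for a, b in zip(logs[i], logs[j])]
            sds.append(statistics.stdev(diffs))
        ms.append(sum(sds) / len(sds))
    return ms


def pairwise_variation_oracle(ct_rows):
    """V_n for the genes in the given (already ranked) row order."""
    q = quantities_oracle(ct_rows)
    k = len(q)
    n_samples = len(q[0])
    vs = []
    for n in range(2, k):
        ratios = []
        for s in range(n_samples):
            nf_n = math.prod(q[g][s] for g in range(n)) ** (1.0 / n)
            nf_n1 = math.prod(q[g][s] for g in range(n + 1)) ** (1.0 / (n + 1))
            ratios.append(math.log2(nf_n / nf_n1))
        vs.append(statistics.stdev(ratios))
    return vs


# ---------------------------------------------------------------------------
# Delta-Ct
# ---------------------------------------------------------------------------

class TestDeltaCt:
    def test_constant_offset_pair_is_perfectly_stable(self):
        t = make_table([[20, 21, 22], [23, 24, 25]])
        st = delta_ct_stability(t)
        assert st.values.tolist() == pytest.approx([0.0, 0.0])

    def test_hand_computed_three_genes(self, tiny_table):
        st = delta_ct_stability(tiny_table)
        sd12 = statistics.stdev([-1, -2, -3])
        sd13 = statistics.stdev([-5, -5, -6])
        sd23 = statistics.stdev([-4, -3, -3])
        expected = [
            (sd12 + sd13) / 2,
            (sd12 + sd23) / 2,
            (sd13 + sd23) / 2,
        ]
        assert st.values.tolist() == pytest.approx(expected)
        assert st.values.iloc[0] == pytest.approx((1 + 1 / math.sqrt(3)) / 2)

    def test_sample_shift_invariance(self, rng):
        ct = 20 + 3 * rng.random((4, 5))
        shifted = ct.copy()
        shifted[:, 2] += 5.0
        a = delta_ct_stability(make_table(ct)).values
        b = delta_ct_stability(make_table(shifted)).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="samples"):
            delta_ct_stability(make_table([[20, 21], [22, 23]]))

    def test_gene_permutation_equivariance(self, rng):
        ct = 20 + 3 * rng.random((5, 6))
        genes = [f"g{i}" for i in range(5)]
        a = delta_ct_stability(make_table(ct, genes=genes)).values
        perm = [3, 0, 4, 1, 2]
        b = delta_ct_stability(
            make_table(ct[perm], genes=[genes[i] for i in perm])
        ).values
        for g in genes:
            assert a[g] == pytest.approx(b[g], abs=1e-12)


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

class TestGenormM:
    def test_scalar_multiples_give_zero_m(self):
        t = make_table([[20, 21, 23], [22, 23, 25], [18.5, 19.5, 21.5]])
        m = genorm_m(t)
        np.testing.assert_allclose(m.to_numpy(), 0.0, atol=1e-12)

    def test_matches_brute_force(self, rng):
        ct = 20 + 4 * rng.random((4, 6))
        t = make_table(ct)
        np.testing.assert_allclose(
            genorm_m(t).to_numpy(), genorm_m_oracle(ct.tolist()), atol=1e-12
        )

    def test_sample_shift_invariance(self, rng):
        ct = 20 + 3 * rng.random((4, 5))
        shifted = ct.copy()
        shifted[:, 0] += 3.0
        np.testing.assert_allclose(
            genorm_m(make_table(ct)).to_numpy(),
            genorm_m(make_table(shifted)).to_numpy(),
            atol=1e-9,
        )

    def test_subset_of_one_is_error(self, tiny_table):
        with pytest.raises(ValueError):
            genorm_m(tiny_table, subset=["g1"])


class TestGenormRank:
    def test_noisy_gene_removed_first(self, rng):
        base = 20 + rng.random(8) * 2
        ct = np.tile(base, (5, 1)) + rng.normal(0, 0.05, (5, 8))
        ct[2] += rng.normal(0, 2.0, 8)  # one gene with large independent noise
        trace, st = genorm_rank(make_table(ct))
        assert trace.removal_order[0] == "g3"
        assert st.ranks["g3"] == 5.0

    def test_trace_covers_all_genes(self, rng):
        ct = 20 + 4 * rng.random((6, 7))
        trace, _ = genorm_rank(make_table(ct))
        assert trace.all_genes() == {f"g{i+1}" for i in range(6)}
        assert len(trace.removal_order) == 4

    def test_duplicated_gene_is_final_pair(self, rng):
        ct = 20 + 2 * rng.random((5, 6))
        ct[3] = ct[0] + 1.5  # identical profile, constant offset
        trace, st = genorm_rank(make_table(ct))
        assert set(trace.final_pair) == {"g1", "g4"}
        assert sorted([st.ranks["g1"], st.ranks["g4"]]) == [1.0, 2.0]

    def test_two_genes_warns(self):
        t = make_table([[20, 21, 22], [25, 26, 28]])
        with pytest.warns(UserWarning):
            trace, st = genorm_rank(t)
        assert sorted(st.ranks.tolist()) == [1.0, 2.0]

    def test_values_are_removal_step_m(self, rng):
        ct = 20 + 4 * rng.random((5, 6))
        t = make_table(ct)
        trace, st = genorm_rank(t)
        # first removed gene's value equals its M in the full set
        first = trace.removal_order[0]
        assert st.values[first] == pytest.approx(genorm_m(t)[first])


class TestPairwiseVariation:
    def test_identical_profiles_give_zero_v(self):
        ct = [[20, 21, 23], [22, 23, 25], [19, 20, 22], [24, 25, 27]]
        v = pairwise_variation(make_table(ct), ranking=["g1", "g2", "g3", "g4"])
        np.testing.assert_allclose(v.v.to_numpy(), 0.0, atol=1e-12)

    def test_matches_brute_force(self, rng):
        ct = 20 + 4 * rng.random((6, 8))
        ranking = [f"g{i+1}" for i in range(6)]
        v = pairwise_variation(make_table(ct), ranking=ranking)
        np.testing.assert_allclose(
            v.v.to_numpy(), pairwise_variation_oracle(ct.tolist()), atol=1e-12
        )
        assert list(v.v.index) == list(range(2, 6))

    def test_v2_depends_only_on_top_three(self, rng):
        ct = 20 + 4 * rng.random((5, 6))
        ranking = [f"g{i+1}" for i in range(5)]
        v_a = pairwise_variation(make_table(ct), ranking=ranking).v.loc[2]
        ct_b = ct.copy()
        ct_b[4] += rng.normal(0, 1, 6)  # perturb the worst-ranked gene only
        v_b = pairwise_variation(make_table(ct_b), ranking=ranking).v.loc[2]
        assert v_a == pytest.approx(v_b, abs=1e-12)


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

class TestNormFinder:
    def test_pure_sample_effects_give_zero(self):
        loading = np.array([0.0, 0.7, -0.3, 1.1, 0.2])
        ct = np.vstack([20 + loading, 24 + loading, 28 + loading])
        st = normfinder_stability(make_table(ct))
        np.testing.assert_allclose(st.values.to_numpy(), 0.0, atol=1e-9)

    def test_variance_total_self_consistency(self, rng):
        ct = 20 + 4 * rng.random((5, 8))
        t = make_table(ct)
        z = np.log2(2.0 ** (ct.min(axis=1, keepdims=True) - ct))
        x = z - z.mean(axis=0, keepdims=True)
        r = x - x.mean(axis=1, keepdims=True)
        v = (r**2).sum(axis=1) / (x.shape[1] - 1)
        k = 5
        total = v.sum() / (1 - 1 / k)
        sigma2 = normfinder_stability(t).values.to_numpy() ** 2
        # reconstruct the raw variances from the bias-corrected estimates
        v_back = (1 - 2 / k) * sigma2 + total / k**2
        np.testing.assert_allclose(v_back, v, atol=1e-9)

    def test_group_effect_ranked_least_stable(self, rng):
        k, per_group = 5, 6
        groups = ["a"] * per_group + ["b"] * per_group + ["c"] * per_group
        ct = 20 + np.zeros((k, 3 * per_group)) + rng.normal(0, 0.2, (k, 3 * per_group))
        for i in range(k):
            ct[i] += i  # distinct baselines
        effect = {"a": 0.0, "b": 2.0, "c": -2.0}
        for s, g in enumerate(groups):
            ct[2, s] += effect[g]  # inject a 2-cycle group effect in gene 3
        st = normfinder_stability(make_table(ct, groups=groups), groups=groups)
        assert st.values.idxmax() == "g3"
        assert st.ranks["g3"] == 5.0

    def test_sample_shift_invariance(self, rng):
        ct = 20 + 3 * rng.random((4, 6))
        shifted = ct.copy()
        shifted[:, 1] += 4.0
        groups = ["a", "a", "a", "b", "b", "b"]
        a = normfinder_stability(make_table(ct, groups=groups), groups=groups).values
        b = normfinder_stability(
            make_table(shifted, groups=groups), groups=groups
        ).values
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_group_of_one_is_error(self):
        t = make_table([[20, 21, 22], [23, 24, 25], [26, 27, 28]],
                       groups=["a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            normfinder_stability(t, groups=["a", "a", "b"])

    def test_needs_three_genes(self):
        with pytest.raises(ValueError, match=">=3"):
            normfinder_stability(make_table([[20, 21, 22], [23, 24, 25]]))


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

class TestBestKeeper:
    def test_constant_gene_rank_one(self, rng):
        ct = 22 + rng.random((3, 5))
        ct[1] = 25.0
        st = bestkeeper_stats(make_table(ct))
        assert st.table.at["g2", "value"] == 0.0
        assert st.table.at["g2", "cv_pct"] == 0.0
        assert st.ranks["g2"] == 1.0

    def test_hand_computed_sd_cv(self):
        t = make_table([[20, 21, 22], [25, 25, 25], [30, 29, 31]])
        st = bestkeeper_stats(t)
        assert st.table.at["g1", "value"] == pytest.approx(1.0)
        assert st.table.at["g1", "cv_pct"] == pytest.approx(100 / 21)

    def test_mad_deviation(self):
        t = make_table([[20, 21, 22], [25, 25, 25], [30, 29, 31]])
        st = bestkeeper_stats(t, deviation="mad")
        assert st.table.at["g1", "value"] == pytest.approx(2 / 3)

    def test_gene_identical_to_index_has_r_one(self, rng):
        ct = 20 + 2 * rng.random((3, 6))
        # log g1 = mean(log g2, log g3) makes the 3-gene geometric mean
        # exactly equal to g1, so g1 *is* the BestKeeper index
        ct[0] = np.exp((np.log(ct[1]) + np.log(ct[2])) / 2)
        st = bestkeeper_stats(make_table(ct))
        assert st.table.at["g1", "r_index"] == pytest.approx(1.0, abs=1e-12)

    def test_descriptives(self, rng):
        ct = 18 + 6 * rng.random((4, 7))
        st = bestkeeper_stats(make_table(ct))
        for g in st.table.index:
            row = st.table.loc[g]
            assert row["min"] <= row["geo_mean_ct"] <= row["mean_ct"] <= row["max"]

    def test_loading_offsets_inflate_bestkeeper_only(self, rng):
        # large per-sample loading, no condition effects: log-ratio methods
        # stay near zero while BestKeeper SD grows with the loading SD
        n = 12
        loading = rng.normal(0, 1.5, n)
        ct = np.vstack([20 + loading, 24 + loading, 27 + loading, 30 + loading])
        ct += rng.normal(0, 0.02, ct.shape)
        t = make_table(ct)
        assert delta_ct_stability(t).values.max() < 0.1
        assert genorm_m(t).max() < 0.1
        assert normfinder_stability(t).values.max() < 0.1
        assert bestkeeper_stats(t).values.min() > 0.5


# ---------------------------------------------------------------------------
# cross-method properties
# ---------------------------------------------------------------------------

def test_noise_scale_monotonicity():
    """Doubling a gene's condition noise does not decrease its stability value."""
    from refstab.synthetic import GeneSpec, GroupSpec, SimulationSpec, simulate_ct
    from refstab.ct_data import aggregate_technical_replicates

    def run(sd, seed):
        spec = SimulationSpec(
            genes=[GeneSpec(f"g{i+1}", 18.0 + 2 * i) for i in range(4)]
            + [GeneSpec("g5", 28.0, condition_sd=sd)],
            groups=[GroupSpec(l) for l in ["a", "b", "c"]],
            tech_sd=0.2,
            seed=seed,
        )
        t, _ = simulate_ct(spec)
        agg, _ = aggregate_technical_replicates(t)
        return {
            "delta_ct": delta_ct_stability(agg).values["g5"],
            "genorm": genorm_m(agg)["g5"],
            "normfinder": normfinder_stability(agg).values["g5"],
            "bestkeeper": bestkeeper_stats(agg).values["g5"],
        }

    wins = {m: 0 for m in ["delta_ct", "genorm", "normfinder", "bestkeeper"]}
    n_rep = 25
    for seed in range(n_rep):
        lo = run(0.5, seed)
        hi = run(2.0, seed)
        for m in wins:
            wins[m] += hi[m] >= lo[m]
    for m, w in wins.items():
        assert w >= 0.8 * n_rep, f"{m}: larger noise lowered stability value too often"
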
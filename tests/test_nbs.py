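"""Tests for the Network-Based Statistic implementation."""

import numpy as np
import pytest

from conntopo import nbs as N
from conntopo.synthetic import SyntheticConfig, generate_cohort


def _union_find_components(edges):
    """Brute-force component oracle over an edge list."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for a, b in edges:
        union(a, b)
    groups = {}
    for a, b in edges:
        groups.setdefault(find(a), []).append((a, b))
    return sorted(
        (sorted(e) for e in groups.values()),
        key=lambda e: (-len(e), min(min(p) for p in e)),
    )


def _cohort(seed=0, n_regions=30, n_per_group=(10, 10), **kw):
    cfg = SyntheticConfig(
        n_regions=n_regions, n_per_group=n_per_group, lattice_neighbors=3,
        subject_noise_cv=0.3, seed=seed, **kw,
    )
    subjects, parts, _ = generate_cohort(cfg)
    W = np.stack([s.weights for s in subjects])
    is_patient = (parts["group"] == "patient").to_numpy()
    cov = parts[["age", "sex", "education"]].to_numpy(dtype=float)
    return W, is_patient, cov


class TestComponents:
    def test_component_arithmetic(self):
        rows = np.array([1, 2, 4])
        cols = np.array([2, 3, 5])
        t = np.array([3.0, 3.0, 3.0])
        comps = N.suprathreshold_components(rows, cols, t, 2.0, 6)
        assert [c.size for c in comps] == [2, 1]
        assert comps[0].edges == [(1, 2), (2, 3)]

    def test_no_suprathreshold_edges(self):
        comps = N.suprathreshold_components(
            np.array([0]), np.array([1]), np.array([1.0]), 2.0, 3
        )
        assert comps == []

    def test_complete_graph_single_component(self):
        iu, ju = np.triu_indices(5, k=1)
        t = np.full(iu.size, 5.0)
        comps = N.suprathreshold_components(iu, ju, t, 2.0, 5)
        assert len(comps) == 1
        assert comps[0].size == 10

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            iu, ju = np.triu_indices(n, k=1)
            t = rng.normal(size=iu.size)
            thr = 0.8
            comps = N.suprathreshold_components(iu, ju, t, thr, n)
            keep = t >= thr
            oracle = _union_find_components(list(zip(iu[keep], ju[keep])))
            assert [sorted(c.edges) for c in comps] == [
                [tuple(e) for e in grp] for grp in oracle
            ]

    def test_threshold_monotone_nesting(self):
        rng = np.random.default_rng(1)
        iu, ju = np.triu_indices(12, k=1)
        t = rng.normal(1.0, 1.0, iu.size)
        sizes = []
        for thr in (0.5, 1.0, 1.5, 2.0):
            comps = N.suprathreshold_components(iu, ju, t, thr, 12)
            sizes.append(max((c.size for c in comps), default=0))
        assert sizes == sorted(sizes, reverse=True)


class TestEdgeStats:
    def test_mask_rule_full_presence(self):
        # the mask keeps a pair present in >= rule fraction of either group;
        # at rule 1.0 an absence in each group excludes the pair
        W, is_patient, cov = _cohort(seed=3)
        es_before = N.edge_group_stats(W, is_patient, cov, mask_rule=1.0)
        a, b = int(es_before.rows[0]), int(es_before.cols[0])
        W2 = W.copy()
        i_pat = int(np.flatnonzero(is_patient)[0])
        i_con = int(np.flatnonzero(~is_patient)[0])
        for i in (i_pat, i_con):
            W2[i, a, b] = W2[i, b, a] = 0.0
        es_after = N.edge_group_stats(W2, is_patient, cov, mask_rule=1.0)
        pairs = set(zip(es_after.rows.tolist(), es_after.cols.tolist()))
        assert (a, b) not in pairs
        # absent in one group only: the other group keeps it masked
        W3 = W.copy()
        W3[i_pat, a, b] = W3[i_pat, b, a] = 0.0
        es_one = N.edge_group_stats(W3, is_patient, cov, mask_rule=1.0)
        assert (a, b) in set(zip(es_one.rows.tolist(), es_one.cols.tolist()))

    def test_planted_edge_attains_max_t(self):
        planted = ((0, 1),)
        W, is_patient, cov = _cohort(
            seed=4, n_per_group=(20, 20),
            planted_edge_set=planted, planted_factor=0.3,
        )
        es = N.edge_group_stats(W, is_patient, cov)
        idx = int(np.argmax(np.abs(es.t)))
        assert (int(es.rows[idx]), int(es.cols[idx])) == (0, 1)
        assert es.t[idx] < 0  # patients weakened

    def test_empty_groups_error(self):
        W, is_patient, cov = _cohort(seed=5)
        with pytest.raises(ValueError, match="two subjects"):
            N.edge_group_stats(W, np.zeros_like(is_patient), cov)


class TestNbsTest:
    def test_deterministic_given_seed(self):
        W, is_patient, cov = _cohort(seed=6)
        r1 = N.nbs_test(W, is_patient, cov, n_perm=150,
                        rng=np.random.default_rng(9))
        r2 = N.nbs_test(W, is_patient, cov, n_perm=150,
                        rng=np.random.default_rng(9))
        assert np.array_equal(r1.null_max_sizes, r2.null_max_sizes)
        assert [(c.size, c.p) for c in r1.components] == [
            (c.size, c.p) for c in r2.components
        ]

    def test_planted_component_recovered_single_seed(self):
        planted = tuple((i, i + 1) for i in range(8))
        W, is_patient, cov = _cohort(
            seed=7, n_per_group=(20, 20),
            planted_edge_set=planted, planted_factor=0.5,
        )
        res = N.nbs_test(W, is_patient, cov, n_perm=200,
                         corrected_p=0.05, rng=np.random.default_rng(1))
        sig = [c for c in res.components
               if c.direction == "patient<control" and c.p <= 0.05]
        assert sig, "planted weakened subnetwork not detected"
        best = max(sig, key=lambda c: len(set(c.edges) & set(planted)))
        overlap = len(set(best.edges) & set(planted)) / len(
            set(best.edges) | set(planted)
        )
        assert overlap >= 0.5

    def test_n_perm_floor(self):
        W, is_patient, cov = _cohort(seed=8)
        with pytest.raises(ValueError, match="n_perm"):
            N.nbs_test(W, is_patient, cov, n_perm=10)
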
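"""Rank-based similarity, network summaries, stability and identification."""

import numpy as np
import pytest

from bgconn.comparison import (
    collapse_networks,
    connectionwise_stability,
    fingerprint_similarity,
    identify_subjects,
    motion_association,
    network_stability,
    spearman,
    within_between,
)
from bgconn.connectivity import matrix_from_upper, vectorize_upper
from bgconn.types import AtlasLabels, ConnectivityMatrix


def spearman_oracle(x, y):
    """Brute force: explicit average-rank assignment, then Pearson."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = np.asarray(v)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    return np.corrcoef(rx, ry)[0, 1]


def conn(z, subject="sub-01", method="rest"):
    p = z.shape[0]
    return ConnectivityMatrix(
        z=np.asarray(z, dtype=float), method=method, subject_id=subject,
        parcel_ids=tuple(f"p{i}" for i in range(p)),
    )


def random_cohort(n_subjects, n_parcels, seed, base=None, idio_sd=1.0, noise_sd=0.0):
    """Connectivity matrices built directly on the z scale (no simulation)."""
    rng = np.random.default_rng(seed)
    n_conn = n_parcels * (n_parcels - 1) // 2
    base = np.zeros(n_conn) if base is None else base
    mats = []
    truths = []
    for i in range(n_subjects):
        truth = base + idio_sd * rng.normal(size=n_conn)
        vec = truth + noise_sd * rng.normal(size=n_conn)
        mats.append(conn(matrix_from_upper(vec, n_parcels), subject=f"sub-{i:02d}"))
        truths.append(truth)
    return mats, truths


TWO_NET_LABELS = AtlasLabels.from_sequences(
    ["p0", "p1", "p2", "p3"], ["A", "A", "B", "B"]
)

BLOCK_Z = np.array(
    [
        [0.0, 0.5, 0.1, 0.1],
        [0.5, 0.0, 0.1, 0.1],
        [0.1, 0.1, 0.0, 0.5],
        [0.1, 0.1, 0.5, 0.0],
    ]
)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([0.2, 1.5, -0.3, 2.2, 0.9])
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_ties_match_brute_force_oracle(self):
        x = [1, 2, 2, 4]
        y = [3, 1, 4, 4]
        assert spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


class TestFingerprint:
    def test_self_similarity_is_one(self):
        m = conn(BLOCK_Z)
        assert fingerprint_similarity(m, m) == pytest.approx(1.0)

    def test_monotone_entrywise_transform_invariance(self):
        rng = np.random.default_rng(0)
        z = matrix_from_upper(rng.normal(size=6), 4)
        a = conn(z)
        b = conn(np.sign(z) * np.abs(z) ** 3 + 0.1 * z)  # strictly monotone
        assert fingerprint_similarity(a, b) == pytest.approx(1.0)


class TestWithinBetween:
    def test_block_toy_exact(self):
        assert within_between(conn(BLOCK_Z), TWO_NET_LABELS) == (0.5, 0.1)

    def test_whole_network_label_swap_invariance(self):
        swapped = AtlasLabels.from_sequences(
            ["p0", "p1", "p2", "p3"], ["B", "B", "A", "A"]
        )
        assert within_between(conn(BLOCK_Z), swapped) == \
            within_between(conn(BLOCK_Z), TWO_NET_LABELS)

    def test_collapse_toy(self):
        out, order = collapse_networks(conn(BLOCK_Z), TWO_NET_LABELS)
        np.testing.assert_allclose(out, [[0.5, 0.1], [0.1, 0.5]], atol=1e-12)
        assert order == ("A", "B")

    def test_collapsed_weighted_mean_identity(self, cohort20_matrices, atlas100):
        # pair-count-weighted mean of the 28 unique network entries equals
        # the grand mean of the vectorized upper triangle
        mat = cohort20_matrices["rest"][0]
        collapsed, order = collapse_networks(mat, atlas100)
        nets = atlas100.vector_for(mat.parcel_ids)
        k = len(order)
        counts = np.zeros((k, k))
        sizes = {n: (nets == n).sum() for n in order}
        for i, a in enumerate(order):
            counts[i, i] = sizes[a] * (sizes[a] - 1) / 2
            for j in range(i + 1, k):
                counts[i, j] = counts[j, i] = sizes[a] * sizes[order[j]]
        iu = np.triu_indices(k)
        weighted = (collapsed[iu] * counts[iu]).sum() / counts[iu].sum()
        assert weighted == pytest.approx(vectorize_upper(mat).mean(), abs=1e-12)

    def test_seven_networks_give_28_unique_entries(self, cohort20_matrices,
                                                   atlas100):
        collapsed, order = collapse_networks(cohort20_matrices["rest"][0], atlas100)
        assert len(order) == 7
        assert np.isfinite(collapsed[np.triu_indices(7)]).sum() == 28


class TestStability:
    def test_identical_cohorts_give_rho_one(self):
        mats, _ = random_cohort(6, 5, seed=1)
        res = connectionwise_stability(mats, mats)
        np.testing.assert_allclose(res.connection_rho, 1.0, atol=1e-12)

    def test_subject_permutation_destroys_stability(self):
        mats, _ = random_cohort(20, 8, seed=2)
        rng = np.random.default_rng(3)
        perm = rng.permutation(20)
        res = connectionwise_stability(mats, [mats[i] for i in perm])
        assert abs(np.nanmean(res.connection_rho)) < 0.1

    def test_constant_connection_recorded_as_missing(self):
        mats, _ = random_cohort(5, 4, seed=4)
        degenerate = []
        for m in mats:
            z = m.z.copy()
            z[0, 1] = z[1, 0] = 0.42  # same value for every subject
            degenerate.append(conn(z, subject=m.subject_id))
        res = connectionwise_stability(degenerate, degenerate)
        assert res.n_undefined == 1
        assert np.isnan(res.connection_rho[0])

    def test_network_level_matrix_shape(self, cohort20_matrices, atlas100):
        res = network_stability(
            cohort20_matrices["rest"][:8], cohort20_matrices["fir"][:8], atlas100
        )
        assert res.network_rho.shape == (7, 7)
        np.testing.assert_allclose(res.network_rho, res.network_rho.T, atol=1e-12)


class TestIdentification:
    def test_identical_cohorts_identify_perfectly(self):
        mats, _ = random_cohort(10, 6, seed=5)
        assert identify_subjects(mats, mats) == 1.0

    def test_unrelated_matrices_identify_at_chance(self):
        accs = []
        for seed in range(5):
            a, _ = random_cohort(20, 6, seed=100 + seed)
            b, _ = random_cohort(20, 6, seed=200 + seed)
            accs.append(identify_subjects(a, b))
        assert np.mean(accs) < 0.2  # chance is 1/20


class TestMotionAssociation:
    def test_scores_tracking_fd_give_rho_one(self):
        fd = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        out = motion_association(fd.copy(), {"mean_fd": fd})
        assert out["mean_fd"][0] == pytest.approx(1.0)

    def test_four_indices_give_four_results(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=10)
        qc = {k: rng.normal(size=10)
              for k in ("mean_fd", "max_fd", "mean_dvars", "max_dvars")}
        out = motion_association(scores, qc)
        assert set(out) == set(qc)
        for rho, p in out.values():
            assert -1 <= rho <= 1 and 0 <= p <= 1

    def test_independent_scores_rarely_correlate(self):
        # null check at the study's sample size
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            rho, _ = motion_association(
                rng.normal(size=56), {"fd": rng.normal(size=56)}
            )["fd"]
            hits += abs(rho) > 0.5
        assert hits == 0
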
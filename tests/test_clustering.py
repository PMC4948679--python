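"""Cross-RMSD matrix and neighbor-count clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdrscore import (ClusteringParams, ClusterResult, DistanceMatrix,
                      Ensemble, cms_frames, cross_rmsd_matrix, daura_cluster,
                      export_cms, read_multimodel_pdb, significant_clusters)
from cdrscore.structure_io import select_atoms
from cdrscore.superposition import region_rmsd, superpose
from cdrscore.synthetic import (BasinSpec, default_region, make_basin_frames,
                                make_loop_reference, sample_ensemble)


def brute_force_daura(values, cutoff):
    """Independent O(N^3) reference implementation of the greedy algorithm."""
    n = values.shape[0]
    unassigned = set(range(n))
    assignments = {}
    cms = []
    cluster = 0
    while unassigned:
        best_frame, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned
                        if i == j or values[i, j] <= cutoff)
            if count > best_count:  # strict > keeps the lowest-index tie-break
                best_frame, best_count = i, count
        cluster += 1
        members = [j for j in sorted(unassigned)
                   if j == best_frame or values[best_frame, j] <= cutoff]
        for j in members:
            assignments[j] = cluster
            unassigned.remove(j)
        cms.append(best_frame)
    return assignments, cms


def _dm(values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(values, [(0, i) for i in range(values.shape[0])])


def _toy_five_frame_matrix():
    d = np.full((5, 5), 0.6)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.1
    d[0, 2] = d[2, 0] = 0.15
    d[1, 2] = d[2, 1] = 0.1
    d[3, 4] = d[4, 3] = 0.1
    return d


def test_five_frame_toy_clustering():
    cr = daura_cluster(_dm(_toy_five_frame_matrix()),
                       ClusteringParams(cutoff=0.2))
    assert cr.n_clusters == 2
    np.testing.assert_array_equal(cr.assignments, [1, 1, 1, 2, 2])
    assert cr.cms_indices == {1: 0, 2: 3}  # count ties broken to lowest index
    assert cr.populations[1] == pytest.approx(0.6)
    assert cr.populations[2] == pytest.approx(0.4)


def test_all_far_apart_gives_singletons():
    d = np.full((4, 4), 1.0)
    np.fill_diagonal(d, 0.0)
    cr = daura_cluster(_dm(d), ClusteringParams(cutoff=0.2))
    assert cr.n_clusters == 4
    assert all(p == pytest.approx(0.25) for p in cr.populations.values())
    assert sorted(cr.cms_indices.values()) == [0, 1, 2, 3]


def test_all_close_gives_one_cluster():
    d = np.full((6, 6), 0.05)
    np.fill_diagonal(d, 0.0)
    cr = daura_cluster(_dm(d), ClusteringParams(cutoff=0.2))
    assert cr.n_clusters == 1
    assert cr.cms_indices[1] == 0  # full tie -> lowest index
    assert cr.populations[1] == pytest.approx(1.0)


@st.composite
def random_distance_matrices(draw):
    n = draw(st.integers(min_value=2, max_value=40))
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    v = rng.uniform(0.0, 0.5, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return v


@settings(max_examples=120, deadline=None, derandomize=True)
@given(random_distance_matrices())
def test_daura_matches_brute_force(values):
    params = ClusteringParams(cutoff=0.2)
    cr = daura_cluster(_dm(values), params)
    expected_assign, expected_cms = brute_force_daura(values, params.cutoff)
    assert {i: c for i, c in enumerate(cr.assignments)} == expected_assign
    assert [cr.cms_indices[c] for c in sorted(cr.cms_indices)] == expected_cms


@settings(max_examples=40, deadline=None, derandomize=True)
@given(random_distance_matrices())
def test_populations_sum_to_one_and_sizes_non_increasing(values):
    cr = daura_cluster(_dm(values), ClusteringParams(cutoff=0.2))
    assert sum(cr.populations.values()) == pytest.approx(1.0, abs=1e-12)
    sizes = [cr.populations[c] for c in sorted(cr.populations)]
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


def test_permutation_invariance_up_to_relabeling():
    rng = np.random.default_rng(42)
    v = rng.uniform(0.0, 0.5, size=(15, 15))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    base = daura_cluster(_dm(v), ClusteringParams(cutoff=0.25))
    perm = rng.permutation(15)
    permuted = daura_cluster(_dm(v[np.ix_(perm, perm)]),
                             ClusteringParams(cutoff=0.25))
    # same partition of frames, whatever the labels
    def partition(assignments, order):
        groups = {}
        for pos, cid in enumerate(assignments):
            groups.setdefault(cid, set()).add(order[pos])
        return {frozenset(g) for g in groups.values()}
    assert partition(base.assignments, list(range(15))) == \
        partition(permuted.assignments, list(perm))


# ---------------------------------------------------------------------------
# significant clusters
# ---------------------------------------------------------------------------

def _result_with_populations(pops):
    n = 100
    assignments = np.concatenate([
        np.full(int(round(p * n)), i + 1) for i, p in enumerate(pops)])
    return ClusterResult(assignments=assignments,
                         cms_indices={i + 1: i for i in range(len(pops))},
                         populations={i + 1: p for i, p in enumerate(pops)})


def test_dominant_cluster_pattern_selects_single_reference():
    # one 52% cluster, the rest <= 15% -> a single representative structure
    cr = _result_with_populations([0.52, 0.15, 0.12, 0.11, 0.10])
    cr = significant_clusters(cr, ClusteringParams(significance_threshold=0.20))
    assert cr.significant_ids == [1]
    assert cr.a == 1


def test_two_equal_clusters_are_both_significant():
    cr = _result_with_populations([0.5, 0.5])
    cr = significant_clusters(cr, ClusteringParams(significance_threshold=0.20))
    assert cr.a == 2


def test_fallback_keeps_largest_cluster_with_warning():
    cr = _result_with_populations([0.1] * 10)
    with pytest.warns(UserWarning, match="significance"):
        cr = significant_clusters(cr,
                                  ClusteringParams(significance_threshold=0.20))
    assert cr.significant_ids == [1]


# ---------------------------------------------------------------------------
# cross-RMSD matrix
# ---------------------------------------------------------------------------

def test_identical_frames_give_zero_matrix(loop_reference, loop_region):
    ens = Ensemble([loop_reference, loop_reference])
    dm = cross_rmsd_matrix([ens], loop_region)
    assert dm.size == 2
    np.testing.assert_allclose(dm.values, 0.0, atol=1e-9)


def test_offdiagonal_matches_pairwise_superposition(loop_reference,
                                                    loop_region):
    spec = BasinSpec(basin_frames=[loop_reference], weights=(1.0,),
                     region=loop_region, jitter_sigma=0.05, seed=21)
    (ens,), _ = sample_ensemble(spec, m=4)
    dm = cross_rmsd_matrix([ens], loop_region)
    fit_idx = select_atoms(loop_reference, loop_region.fit_region)
    rmsd_idx = select_atoms(loop_reference, loop_region.rmsd_region)
    for i in range(4):
        for j in range(i + 1, 4):
            _, moved = superpose(ens.frames[j], ens.frames[i],
                                 fit_idx, fit_idx)
            d_ij = region_rmsd(moved, ens.frames[i], rmsd_idx, rmsd_idx)
            _, moved = superpose(ens.frames[i], ens.frames[j],
                                 fit_idx, fit_idx)
            d_ji = region_rmsd(moved, ens.frames[j], rmsd_idx, rmsd_idx)
            assert dm.values[i, j] == pytest.approx(0.5 * (d_ij + d_ji),
                                                    rel=1e-9)


def test_two_basin_matrix_separates_within_from_between(loop_reference,
                                                        loop_region):
    basins = make_basin_frames(loop_reference, loop_region, 2,
                               separation=0.6, seed=2)
    spec = BasinSpec(basin_frames=basins, weights=(0.5, 0.5),
                     region=loop_region, jitter_sigma=0.05, seed=3)
    (ens,), labels = sample_ensemble(spec, m=40)
    dm = cross_rmsd_matrix([ens], loop_region)
    same = labels[0][:, None] == labels[0][None, :]
    off = ~np.eye(40, dtype=bool)
    within = dm.values[same & off]
    between = dm.values[~same]
    assert within.max() < between.min()


def test_pooling_respects_window_and_stride(loop_reference, loop_region):
    spec = BasinSpec(basin_frames=[loop_reference], weights=(1.0,),
                     region=loop_region, jitter_sigma=0.02, seed=4)
    (ens,), _ = sample_ensemble(spec, m=10)
    windowed = Ensemble(ens.frames, window=(4, 10))
    dm = cross_rmsd_matrix([windowed], loop_region, stride=2)
    assert dm.size == 3
    assert dm.frame_provenance == [(0, 4), (0, 6), (0, 8)]


def test_single_pooled_frame_errors(loop_reference, loop_region):
    ens = Ensemble([loop_reference])
    with pytest.raises(ValueError):
        cross_rmsd_matrix([ens], loop_region)


# ---------------------------------------------------------------------------
# CMS export
# ---------------------------------------------------------------------------

def test_export_cms_round_trip(tmp_path, loop_reference, loop_region):
    basins = make_basin_frames(loop_reference, loop_region, 2,
                               separation=0.8, seed=5)
    spec = BasinSpec(basin_frames=basins, weights=(0.5, 0.5),
                     region=loop_region, jitter_sigma=0.03, seed=6)
    ensembles, _ = sample_ensemble(spec, m=30, s=2)
    dm = cross_rmsd_matrix(ensembles, loop_region)
    params = ClusteringParams(cutoff=0.2, significance_threshold=0.2)
    cr = significant_clusters(daura_cluster(dm, params), params)
    assert cr.a == 2
    paths = export_cms(cr, ensembles, dm, tmp_path)
    assert len(paths) == 2
    frames = {cid: f for cid, f in cms_frames(cr, ensembles, dm)}
    for cid, path in zip(cr.significant_ids, paths):
        back = read_multimodel_pdb(path).frames[0]
        assert np.abs(back.coordinates - frames[cid].coordinates).max() < 1e-4
    # the two CMS are genuinely different conformations
    a, b = (read_multimodel_pdb(p).frames[0] for p in paths)
    assert np.abs(a.coordinates - b.coordinates).max() > 0.1
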
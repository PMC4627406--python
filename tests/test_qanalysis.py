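import itertools

import numpy as np
import pytest

from neuralhypernet.preprocess import build_incidence
from neuralhypernet.qanalysis import (
    QConnectivitySelector,
    SharedFaceMatrix,
    cluster_shared_faces,
    find_plateau,
    q_components,
    shared_face_matrix,
    split_feature_sets,
    structure_profile,
)

from conftest import make_incidence


def brute_force_components(S, q):
    """Independent oracle: repeated merging over the q-nearness relation."""
    diag = np.diag(S)
    alive = [i for i in range(len(S)) if diag[i] >= q]
    sets = [{i} for i in alive]
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(sets)), 2):
            if any(S[i, j] >= q for i in sets[a] for j in sets[b]):
                sets[a] |= sets[b]
                del sets[b]
                changed = True
                break
    return {frozenset(s) for s in sets}


def random_incidence(rng, max_patients=12, max_descriptors=10):
    n = rng.integers(1, max_patients + 1)
    m = rng.integers(1, max_descriptors + 1)
    density = rng.uniform(0.1, 0.9)
    return make_incidence(rng.random((n, m)) < density)


class TestSharedFaceMatrix:
    def test_toy_matrix_against_set_intersections(self):
        M = np.array(
            [[1, 1, 0, 1], [1, 0, 1, 1], [0, 1, 1, 0], [1, 1, 0, 0]], dtype=bool
        )
        sfm = shared_face_matrix(make_incidence(M))
        for i in range(4):
            for j in range(4):
                shared = len(set(np.where(M[:, i])[0]) & set(np.where(M[:, j])[0]))
                assert sfm.S[i, j] == shared - 1

    def test_simplex_dimension_is_occurrences_minus_one(self):
        col = np.zeros((1427, 2), dtype=bool)
        col[:819, 0] = True
        col[:608, 1] = True
        sfm = shared_face_matrix(make_incidence(col))
        assert sfm.S[0, 0] == 818
        assert sfm.S[1, 1] == 607

    def test_disjoint_descriptors_share_face_minus_one(self):
        M = np.array([[1, 0], [1, 0], [0, 1]], dtype=bool)
        sfm = shared_face_matrix(make_incidence(M))
        assert sfm.S[0, 1] == -1

    def test_shared_face_bounded_by_dimensions(self, small_cohort):
        sfm = shared_face_matrix(build_incidence(small_cohort, include_diagnosis=True))
        diag = np.diag(sfm.S)
        bound = np.minimum.outer(diag, diag)
        assert (sfm.S <= bound).all()
        assert (sfm.S >= -1).all()

    def test_csv_round_trip(self, small_cohort, tmp_path):
        sfm = shared_face_matrix(build_incidence(small_cohort))
        sfm.to_csv(tmp_path / "S.csv")
        back = SharedFaceMatrix.from_csv(tmp_path / "S.csv")
        assert back.descriptors == sfm.descriptors
        assert np.array_equal(back.S, sfm.S)


class TestQComponents:
    def test_hub_connects_everything_at_q_zero(self):
        # one patient exhibits every descriptor -> single 0-component
        M = np.ones((1, 5), dtype=bool)
        sfm = shared_face_matrix(make_incidence(M))
        comps = q_components(sfm, 0)
        assert len(comps) == 1 and len(comps[0]) == 5

    def test_q_above_all_off_diagonals_isolates_survivors(self):
        M = np.array([[1, 1], [1, 0], [1, 0], [0, 1]], dtype=bool)
        sfm = shared_face_matrix(make_incidence(M))  # diag 2,1; shared 0
        comps = q_components(sfm, 1)
        assert sorted(len(c) for c in comps) == [1, 1]

    def test_q_out_of_range_rejected(self):
        sfm = shared_face_matrix(make_incidence(np.ones((3, 2), dtype=bool)))
        with pytest.raises(ValueError, match="q="):
            q_components(sfm, 5)
        with pytest.raises(ValueError, match="q="):
            q_components(sfm, -1)

    def test_matches_bruteforce_closure_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            sfm = shared_face_matrix(random_incidence(rng, 8, 6))
            if sfm.q_max < 0:
                continue
            for q in range(sfm.q_max + 1):
                got = {frozenset(sfm.descriptors.index(d) for d in c) for c in q_components(sfm, q)}
                assert got == brute_force_components(sfm.S, q)


class TestStructureProfile:
    def test_equals_per_level_recomputation(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            sfm = shared_face_matrix(random_incidence(rng))
            if sfm.q_max < 0:
                continue
            profile = structure_profile(sfm)
            assert len(profile.levels) == sfm.q_max + 1
            for lv in profile.levels:
                assert set(lv.components) == set(q_components(sfm, lv.q))

    def test_max_component_size_non_increasing(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            sfm = shared_face_matrix(random_incidence(rng))
            if sfm.q_max < 0:
                continue
            sizes = [lv.max_component_size for lv in structure_profile(sfm).levels]
            assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_descriptor_lives_exactly_up_to_its_dimension(self):
        rng = np.random.default_rng(3)
        sfm = shared_face_matrix(random_incidence(rng))
        profile = structure_profile(sfm)
        for d in sfm.descriptors:
            dim = sfm.dimension(d)
            for lv in profile.levels:
                present = any(d in c for c in lv.components)
                assert present == (dim >= lv.q)

    def test_monotone_coarsening(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            sfm = shared_face_matrix(random_incidence(rng))
            if sfm.q_max < 0:
                continue
            levels = structure_profile(sfm).levels
            for lo, hi in zip(levels, levels[1:]):
                for comp in hi.components:
                    assert any(comp <= parent for parent in lo.components)

    def test_patient_permutation_invariance(self, small_cohort):
        inc = build_incidence(small_cohort, include_diagnosis=True)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(inc.patients))
        shuffled = make_incidence(inc.matrix[perm], descriptors=inc.descriptors)
        a, b = shared_face_matrix(inc), shared_face_matrix(shuffled)
        assert np.array_equal(a.S, b.S)
        pa, pb = structure_profile(a), structure_profile(b)
        assert [lv.components for lv in pa.levels] == [lv.components for lv in pb.levels]


class TestPlateau:
    def _clique_fixture(self):
        # five descriptors share patients 0..99; a sixth shares only 0..49
        M = np.zeros((120, 6), dtype=bool)
        M[:100, :5] = True
        M[:50, 5] = True
        return shared_face_matrix(make_incidence(M, descriptors=list("abcdef")))

    def test_constructed_clique_plateau_interval(self):
        profile = structure_profile(self._clique_fixture())
        report = find_plateau(profile, "a")
        # 'f' (dimension 49) leaves the component above q=49; the clique of
        # five persists alone on [50, 99]
        assert (report.q_lo, report.q_hi) == (50, 99)
        assert report.members == frozenset("abcde")

    def test_everywhere_isolated_anchor_yields_flagged_empty_report(self):
        M = np.zeros((10, 2), dtype=bool)
        M[:6, 0] = True
        M[6:, 1] = True
        profile = structure_profile(shared_face_matrix(make_incidence(M, descriptors=["a", "b"])))
        with pytest.warns(UserWarning, match="never"):
            report = find_plateau(profile, "b")
        assert report.is_empty

    def test_ties_break_toward_higher_q(self):
        # two runs of equal length: anchor with 'b' at low q, with 'c' higher
        S = np.array([[5, 1, 3], [1, 1, 1], [3, 1, 5]])
        profile = structure_profile(SharedFaceMatrix(["a", "b", "c"], S))
        report = find_plateau(profile, "a")
        assert report.members == frozenset({"a", "c"})
        assert report.q_lo == 2 and report.q_hi == 3

    def test_split_feature_sets_partition(self):
        profile = structure_profile(self._clique_fixture())
        report = find_plateau(profile, "a")
        connected, unconnected = split_feature_sets(report, list("abcdef"))
        assert set(connected) | set(unconnected) == set("abcdef")
        assert not set(connected) & set(unconnected)

    def test_split_removes_diagnosis_descriptors(self):
        report_members = frozenset({"Age[1]", "Final diagnosis[1]"})
        from neuralhypernet.qanalysis import PlateauReport

        report = PlateauReport(1, 2, report_members, True)
        descriptors = ["Age[0]", "Age[1]", "Final diagnosis[0]", "Final diagnosis[1]"]
        connected, unconnected = split_feature_sets(report, descriptors)
        assert connected == ["Age[1]"]
        assert unconnected == ["Age[0]"]


class TestClustering:
    def test_identical_rows_merge_first_at_zero_distance(self):
        S = np.array([[3, 1, 0], [1, 3, 0], [3, 1, 0]])  # rows 0 and 2 identical
        res = cluster_shared_faces(SharedFaceMatrix(["x", "y", "z"], S))
        assert res.linkage[0, 2] == 0.0
        assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == {0, 2}

    def test_leaf_order_deterministic(self, small_cohort):
        sfm = shared_face_matrix(build_incidence(small_cohort))
        assert cluster_shared_faces(sfm).leaves == cluster_shared_faces(sfm).leaves

    def test_merge_heights_match_bruteforce_average_linkage(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 10, size=(5, 5)).astype(float)
        X = (X + X.T) / 2
        sfm = SharedFaceMatrix([f"d{i}" for i in range(5)], X.astype(int))
        Z = cluster_shared_faces(sfm).linkage

        # naive agglomeration: clusters merge at mean pairwise point distance
        D = np.sqrt(((sfm.S[:, None, :] - sfm.S[None, :, :]) ** 2).sum(-1))
        clusters = [{i} for i in range(5)]
        heights = []
        while len(clusters) > 1:
            best = min(
                itertools.combinations(range(len(clusters)), 2),
                key=lambda ab: np.mean([D[i, j] for i in clusters[ab[0]] for j in clusters[ab[1]]]),
            )
            a, b = best
            heights.append(
                np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            )
            clusters[a] |= clusters[b]
            del clusters[b]
        assert np.allclose(sorted(Z[:, 2]), sorted(heights))


class TestQConnectivitySelector:
    def test_selected_sets_partition_features(self, small_cohort):
        inc = build_incidence(small_cohort)
        X = inc.to_frame()
        y = inc.labels.astype(int)
        sel = QConnectivitySelector(feature_set="unconnected").fit(X, y)
        assert set(sel.connected_) | set(sel.unconnected_) == set(X.columns)
        assert not set(sel.connected_) & set(sel.unconnected_)
        out = sel.transform(X)
        assert list(out.columns) == sel.unconnected_

    def test_union_keeps_all_feature_descriptors(self, small_cohort):
        inc = build_incidence(small_cohort)
        X = inc.to_frame()
        sel = QConnectivitySelector(feature_set="union").fit(X, inc.labels.astype(int))
        assert sel.selected_ == list(X.columns)

    def test_invalid_feature_set_rejected(self, small_cohort):
        inc = build_incidence(small_cohort)
        with pytest.raises(ValueError, match="feature_set"):
            QConnectivitySelector(feature_set="both").fit(inc.to_frame(), inc.labels.astype(int))


def test_plot_outputs_written(tmp_path, small_cohort):
    from neuralhypernet.qanalysis import plot_profile, plot_shared_face_heatmap

    sfm = shared_face_matrix(build_incidence(small_cohort, include_diagnosis=True))
    profile = structure_profile(sfm)
    plot_profile(profile, tmp_path / "profile.png")
    plot_shared_face_heatmap(sfm, tmp_path / "heatmap.png")
    assert (tmp_path / "profile.png").stat().st_size > 0
    assert (tmp_path / "heatmap.png").stat().st_size > 0
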
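"""Clustering contracts: determinism, nesting, characterization, artifacts."""

import numpy as np
import pandas as pd
import pytest

from spatialplex import clustering, shrinkage, synth

from conftest import three_type_spec


@pytest.fixture(scope="module")
def small_shrunk():
    """3 well-separated types, shrunk log-intensities + ground truth."""
    spec = three_type_spec(n_cells=1500, seed=5)
    t = synth.generate_sample(spec, 5)
    model = shrinkage.fit_shrinkage(t.intensities, g_initial=10, seed=0)
    shr = shrinkage.apply_shrinkage(model, t.intensities, 0.8)
    return t, shr


@pytest.fixture(scope="module")
def small_assignment(small_shrunk):
    _, shr = small_shrunk
    return clustering.embed_and_cluster(shr, min_cluster_size=100, seed=0)


def test_too_few_cells_yield_single_noise_cluster():
    df = pd.DataFrame(np.random.default_rng(0).random((10, 3)), columns=list("abc"))
    with pytest.warns(UserWarning, match="noise"):
        asg = clustering.embed_and_cluster(df, min_cluster_size=100, seed=0)
    assert (asg.labels == clustering.NOISE).all()


def test_min_cluster_size_validated():
    df = pd.DataFrame({"a": [1.0, 2.0]})
    with pytest.raises(ValueError):
        clustering.embed_and_cluster(df, min_cluster_size=1)


def test_same_seed_gives_identical_labels(small_shrunk, small_assignment):
    _, shr = small_shrunk
    again = clustering.embed_and_cluster(shr, min_cluster_size=100, seed=0)
    assert (small_assignment.labels == again.labels).all()


def test_separated_types_recovered_with_high_purity(small_shrunk, small_assignment):
    t, _ = small_shrunk
    labels = small_assignment.labels
    truth = t.data["true_type"]
    non_noise = labels != clustering.NOISE
    assert len(small_assignment.cluster_ids()) >= 3
    correct = 0
    for cid in small_assignment.cluster_ids():
        members = truth[non_noise & (labels == cid)]
        correct += members.value_counts().iloc[0]
    assert correct / non_noise.sum() >= 0.9


def test_label_partition_invariant(small_assignment):
    labels = small_assignment.labels
    ids = set(small_assignment.cluster_ids()) | {clustering.NOISE}
    assert set(labels.tolist()) <= ids


class TestCharacterize:
    def _frames(self, shift_map, n=400, m=5, seed=0):
        rng = np.random.default_rng(seed)
        cols = [f"mk{i}" for i in range(m)]
        out = pd.DataFrame(rng.normal(2.0, 0.5, (n, m)), columns=cols)
        inside = pd.DataFrame(rng.normal(2.0, 0.5, (n, m)), columns=cols)
        for col, shift in shift_map.items():
            inside[col] += shift
        return inside, out

    def test_null_case_has_no_significant_markers(self):
        inside, outside = self._frames({}, seed=1)
        prof = clustering.characterize_cluster(inside, outside)
        assert not prof.effects["significant"].any()
        assert prof.ranked == []

    def test_planted_shift_ranks_first(self):
        inside, outside = self._frames({"mk2": 3.0}, seed=2)
        prof = clustering.characterize_cluster(inside, outside)
        assert prof.ranked[0] == "mk2"

    def test_two_planted_shifts_rank_in_order(self):
        inside, outside = self._frames({"mk1": 3.0, "mk4": 1.5}, seed=3)
        prof = clustering.characterize_cluster(inside, outside)
        assert prof.ranked[:2] == ["mk1", "mk4"]
        assert prof.rank_of("mk1") == 1 and prof.rank_of("mk4") == 2

    def test_ranks_are_a_permutation(self):
        inside, outside = self._frames({"mk0": 2.0, "mk1": 1.0, "mk3": 4.0}, seed=4)
        prof = clustering.characterize_cluster(inside, outside)
        ranks = [prof.rank_of(m) for m in prof.ranked]
        assert ranks == list(range(1, len(prof.ranked) + 1))

    def test_zero_variance_marker_skipped(self):
        inside, outside = self._frames({}, seed=5)
        inside["flat"] = 1.0
        outside["flat"] = 1.0
        prof = clustering.characterize_cluster(inside, outside)
        assert prof.skipped == ["flat"]
        assert "flat" not in prof.effects.index

    def test_empty_groups_rejected(self):
        inside, outside = self._frames({}, seed=6)
        with pytest.raises(ValueError):
            clustering.characterize_cluster(inside.iloc[:0], outside)

    def test_rank_position_scale_equivariant(self):
        """Rescaling one marker's intensities leaves its rank position."""
        rng = np.random.default_rng(7)
        cols = ["u", "v", "w"]
        outside = pd.DataFrame(rng.lognormal(3.0, 0.4, (500, 3)), columns=cols)
        inside = pd.DataFrame(rng.lognormal(3.0, 0.4, (500, 3)), columns=cols)
        inside["v"] *= 8.0
        inside["w"] *= 3.0
        base = clustering.characterize_cluster(
            np.log1p(inside), np.log1p(outside)
        ).ranked
        scaled_in, scaled_out = inside.copy(), outside.copy()
        scaled_in["v"] *= 50.0
        scaled_out["v"] *= 50.0
        scaled = clustering.characterize_cluster(
            np.log1p(scaled_in), np.log1p(scaled_out)
        ).ranked
        assert base.index("v") == scaled.index("v")


class TestNested:
    def test_all_clusters_to_one_type_reduces_to_single_subrun(self, small_shrunk, small_assignment):
        _, shr = small_shrunk
        bmap = {cid: "only" for cid in small_assignment.cluster_ids()}
        subpanel = {"only": ["T_m1", "B_m1", "M_m1"]}
        nested = clustering.nested_classify(
            shr, list(shr.columns), bmap, subpanel, min_cluster_size=100, seed=0
        )
        cells = nested.df.index[
            (nested.df["broad_type"] == "only") & (nested.df["global_label"] != clustering.NOISE)
        ]
        direct = clustering.embed_and_cluster(
            shr.loc[cells, subpanel["only"]], min_cluster_size=100, seed=0
        )
        assert (
            nested.df.loc[cells, "subclass_label"].to_numpy(dtype=int)
            == direct.labels
        ).all()

    def test_global_noise_excluded_from_subclass(self, small_shrunk, small_assignment):
        _, shr = small_shrunk
        bmap = {cid: "only" for cid in small_assignment.cluster_ids()}
        nested = clustering.nested_classify(
            shr, list(shr.columns), bmap, {"only": ["T_m1", "B_m1"]}, min_cluster_size=100, seed=0
        )
        noise = nested.df["global_label"] == clustering.NOISE
        assert nested.df.loc[noise, "subclass_label"].isna().all()
        assert nested.df.loc[noise, "subtype"].isna().all()

    def test_broad_type_without_subpanel_passes_through(self, small_shrunk, small_assignment):
        _, shr = small_shrunk
        bmap = {cid: "plain" for cid in small_assignment.cluster_ids()}
        nested = clustering.nested_classify(
            shr, list(shr.columns), bmap, {}, min_cluster_size=100, seed=0
        )
        assigned = nested.df["broad_type"] == "plain"
        assert (nested.df.loc[assigned, "subtype"] == "plain").all()
        assert nested.df.loc[assigned, "subclass_label"].isna().all()

    def test_unknown_cluster_in_broad_map_rejected(self, small_shrunk):
        _, shr = small_shrunk
        with pytest.raises(ValueError, match="unknown global clusters"):
            clustering.nested_classify(
                shr, list(shr.columns), {999: "x"}, {}, min_cluster_size=100, seed=0
            )


class TestFlagArtifacts:
    def test_empty_junk_list_is_identity(self, small_assignment):
        out = clustering.flag_artifacts(small_assignment, [])
        assert not out.df["excluded"].any()
        assert out.cluster_ids() == small_assignment.cluster_ids()

    def test_unknown_id_rejected(self, small_assignment):
        with pytest.raises(ValueError, match="unknown cluster"):
            clustering.flag_artifacts(small_assignment, [12345])

    def test_junk_cluster_reduces_downstream_count_exactly(self, small_shrunk, small_assignment):
        _, shr = small_shrunk
        cid = small_assignment.cluster_ids()[0]
        n_cid = int((small_assignment.labels == cid).sum())
        flagged = clustering.flag_artifacts(small_assignment, [cid])
        assert small_assignment.active_mask().sum() - flagged.active_mask().sum() == n_cid
        assert cid not in flagged.cluster_ids()

    def test_all_clusters_junked_leaves_nothing_downstream(self, small_shrunk, small_assignment):
        _, shr = small_shrunk
        flagged = clustering.flag_artifacts(small_assignment, small_assignment.cluster_ids())
        assert flagged.cluster_ids() == []
        assert clustering.characterize_all(shr, flagged) == {}
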
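"""Differential calls, biomarker union, clustering and PCA signatures."""

import numpy as np
import pytest

from seroarray.differential import (
    ContrastResult,
    StatsError,
    cluster_purity,
    differential_contrast,
    hierarchical_cluster,
    kmeans_correlation,
    membership_to_union,
    pca_signature,
    union_biomarkers,
)
from seroarray.simulate import load_membership_table

from conftest import make_matrix


def two_group_matrix(effect=1.0, n_a=10, n_b=12, m=30, sd=0.3, seed=0, target=0):
    rng = np.random.default_rng(seed)
    values = rng.lognormal(6, sd, (n_a + n_b, m))
    values[:n_a, target] *= effect
    return make_matrix(values, ["PCa"] * n_a + ["BPH"] * n_b)


class TestContrast:
    def test_constant_identical_groups_all_ns(self):
        m = make_matrix(np.full((8, 10), 250.0), ["PCa"] * 4 + ["BPH"] * 4)
        results, untested = differential_contrast(m, group_a="PCa", group_b="BPH")
        assert untested == []
        assert all(r.call == "NS" and r.p_adj == 1.0 for r in results)

    def test_strong_spike_called_up(self):
        m = two_group_matrix(effect=5.0, seed=1)
        results, _ = differential_contrast(m, group_a="PCa", group_b="BPH")
        by_id = {r.antigen_id: r for r in results}
        assert by_id["AG000"].call == "UP"
        assert by_id["AG000"].sd_units > 2

    def test_antisymmetric_under_group_swap(self):
        m = two_group_matrix(effect=5.0, seed=2)
        fwd, _ = differential_contrast(m, group_a="PCa", group_b="BPH")
        rev, _ = differential_contrast(m, group_a="BPH", group_b="PCa")
        for f, r in zip(fwd, rev):
            assert f.antigen_id == r.antigen_id
            assert f.t_stat == pytest.approx(-r.t_stat, rel=1e-9)
            assert f.sd_units == pytest.approx(-r.sd_units, rel=1e-9)
            assert f.p_raw == pytest.approx(r.p_raw, rel=1e-9)
            swap = {"UP": "DOWN", "DOWN": "UP", "NS": "NS"}
            assert f.call == swap[r.call]

    def test_bonferroni_monotone_in_alpha(self):
        m = two_group_matrix(effect=3.0, seed=3)
        loose, _ = differential_contrast(m, group_a="PCa", group_b="BPH", alpha=0.05)
        strict, _ = differential_contrast(m, group_a="PCa", group_b="BPH", alpha=0.001)
        called_loose = {r.antigen_id for r in loose if r.call != "NS"}
        called_strict = {r.antigen_id for r in strict if r.call != "NS"}
        assert called_strict <= called_loose

    def test_composite_group_label(self):
        rng = np.random.default_rng(4)
        values = rng.lognormal(6, 0.3, (12, 5))
        m = make_matrix(values, ["PCa"] * 4 + ["BPH"] * 4 + ["DC"] * 4)
        results, _ = differential_contrast(m, group_a="PCa", group_b="BPH+DC")
        assert len(results) == 5

    def test_sparse_antigen_reported_untested(self):
        values = np.full((6, 3), 300.0)
        m = make_matrix(values, ["PCa"] * 3 + ["BPH"] * 3)
        m.values.iloc[0:2, 1] = np.nan  # leaves only one PCa value
        m.values.iloc[2, 1] = np.nan
        results, untested = differential_contrast(m, group_a="PCa", group_b="BPH")
        assert untested == ["AG001"]
        assert len(results) == 2

    def test_unknown_group_rejected(self):
        m = two_group_matrix()
        with pytest.raises(StatsError):
            differential_contrast(m, group_a="PCa", group_b="XX")


class TestUnion:
    def test_empty_inputs_empty_union(self):
        assert union_biomarkers().union == set()

    def test_membership_fixture_reproduces_41(self):
        union = membership_to_union(load_membership_table())
        assert len(union.union) == 41
        assert union.tags("FGFR2") == frozenset({"Differential", "Venn", "Shotgun"})
        assert union.direction("FGFR2") == "High"
        assert union.direction("GAGE5") == "Low"

    def test_repeated_antigen_merges_tags(self):
        union = union_biomarkers(
            linear_calls={"PCa": ["X"]},
            top_n_lists={"PCa": ["X"]},
        )
        assert union.entries["X"] == (frozenset({"Linear", "Top20"}), "High")

    def test_differential_direction_wins(self):
        contrasts = [ContrastResult("X", 1, 2, -5, 1e-6, 1e-4, -3, "DOWN")]
        union = union_biomarkers(linear_calls={"PCa": ["X"]}, contrasts=contrasts)
        assert union.direction("X") == "Low"

    @pytest.mark.parametrize("seed", range(10))
    def test_union_is_exact_set_union(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"a{i}" for i in range(30)]
        pick = lambda: set(rng.choice(pool, rng.integers(0, 10), replace=False))
        linear = {"PCa": pick(), "BPH": pick()}
        top = {"PCa": pick(), "DC": pick()}
        venn = {"PCa": pick()}
        shot = pick()
        contrasts = [
            ContrastResult(a, 1, 1, 3, 1e-5, 1e-3, 3, "UP") for a in pick()
        ]
        union = union_biomarkers(linear, top, venn, contrasts, shot)
        expected = (
            set().union(*linear.values()) | set().union(*top.values())
            | set().union(*venn.values()) | {c.antigen_id for c in contrasts} | shot
        )
        assert union.union == expected


class TestClustering:
    def test_duplicated_blocks_split_perfectly(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(6, 0.1, 12)
        b = a * 8
        values = np.vstack([np.tile(a, (4, 1)) * rng.lognormal(0, 0.01, (4, 12)),
                            np.tile(b, (4, 1)) * rng.lognormal(0, 0.01, (4, 12))])
        m = make_matrix(values, ["PCa"] * 4 + ["BPH"] * 4)
        hc = hierarchical_cluster(m, "euclidean", k=2)
        labels = hc.labels
        assert len(set(labels.iloc[:4])) == 1
        assert len(set(labels.iloc[4:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]
        km = kmeans_correlation(m, 2)
        # correlation k-means also splits scaled blocks when profiles differ
        assert km.nunique() == 2

    def test_topology_invariant_to_sample_order(self):
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(1)
        values = rng.lognormal(6, 0.8, (10, 20))
        groups = ["PCa"] * 5 + ["BPH"] * 5
        m1 = make_matrix(values, groups)
        perm = rng.permutation(10)
        m2 = make_matrix(values[perm], [groups[i] for i in perm])
        d1 = squareform(cophenet(hierarchical_cluster(m1).linkage))
        d2 = squareform(cophenet(hierarchical_cluster(m2).linkage))
        inv = np.argsort(perm)
        assert np.allclose(d1, d2[np.ix_(inv, inv)])

    def test_k_larger_than_samples_rejected(self):
        m = make_matrix(np.ones((3, 4)), ["PCa", "BPH", "DC"])
        with pytest.raises(StatsError):
            hierarchical_cluster(m, k=5)

    def test_kmeans_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.lognormal(6, 1, (12, 15)), ["PCa"] * 6 + ["BPH"] * 6)
        l1 = kmeans_correlation(m, 3, seed=77)
        l2 = kmeans_correlation(m, 3, seed=77)
        assert l1.equals(l2)


class TestPca:
    def test_single_axis_data_has_one_component(self):
        t = np.linspace(0, 1, 8)
        values = 100 + np.outer(t, np.ones(6) * np.arange(1, 7))
        m = make_matrix(values, ["PCa"] * 4 + ["BPH"] * 4)
        sig = pca_signature(m, top_k=3, n_clusters=2)
        assert sig.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_components_orthonormal(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.lognormal(6, 1, (10, 12)), ["PCa"] * 5 + ["BPH"] * 5)
        sig = pca_signature(m, top_k=5, n_clusters=2)
        gram = sig.components @ sig.components.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.lognormal(6, 1, (9, 12)), ["PCa"] * 3 + ["BPH"] * 3 + ["DC"] * 3)
        sig = pca_signature(m, top_k=5)
        evr = sig.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_spiked_signature_recovered_and_pure(self):
        rng = np.random.default_rng(5)
        n = (10, 12, 8)
        values = rng.lognormal(6, 0.5, (sum(n), 40))
        spiked = list(range(10, 20))
        values[: n[0], spiked] *= 6.0
        groups = ["PCa"] * n[0] + ["BPH"] * n[1] + ["DC"] * n[2]
        m = make_matrix(values, groups)
        sig = pca_signature(m, top_k=10, n_clusters=3)
        expected = {f"AG{j:03d}" for j in spiked}
        assert len(expected & set(sig.top_antigens)) >= 8
        assert cluster_purity(sig.labels, m.meta, "PCa") >= 0.85
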
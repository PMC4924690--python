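"""Fold-over-cutoff seropositivity, rankings, Venn partition, ethnicity, overlap."""

import numpy as np
import pytest

from seroarray.layout import build_default_panel
from seroarray.serology import (
    AnalysisError,
    cross_platform_overlap,
    ethnicity_profile,
    fold_over_cutoff,
    linear_standouts,
    top_n_by_group,
    venn3_partition,
    venn_top_sets,
)

from conftest import make_matrix


def brute_force_venn(a, b, c):
    """Independent oracle: classify every element by membership tuple."""
    regions = {k: set() for k in
               ("A_only", "B_only", "C_only", "A_B_only", "A_C_only",
                "B_C_only", "all_three")}
    for x in set(a) | set(b) | set(c):
        key = (x in a, x in b, x in c)
        label = {
            (True, False, False): "A_only",
            (False, True, False): "B_only",
            (False, False, True): "C_only",
            (True, True, False): "A_B_only",
            (True, False, True): "A_C_only",
            (False, True, True): "B_C_only",
            (True, True, True): "all_three",
        }[key]
        regions[label].add(x)
    return regions


class TestFoldOverCutoff:
    def test_flat_array_has_unit_folds(self):
        m = make_matrix(np.full((2, 10), 400.0), ["PCa", "BPH"])
        fm = fold_over_cutoff(m, fold_min=2.0)
        assert np.allclose(fm.fold.to_numpy(), 1.0)
        assert not fm.positive.to_numpy().any()

    def test_cutoff_matches_independent_percentile(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(6, 1, (5, 123))
        m = make_matrix(values, ["PCa"] * 5)
        fm = fold_over_cutoff(m)
        for i, sid in enumerate(m.sample_ids):
            # independent sort-and-interpolate 75th percentile
            v = np.sort(values[i])
            h = 0.75 * (v.size - 1)
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            q3 = v[lo] + (h - lo) * (v[hi] - v[lo])
            assert fm.cutoffs[sid] == pytest.approx(q3, rel=1e-12)
            assert fm.fold.loc[sid].to_numpy() == pytest.approx(values[i] / q3)

    def test_zero_fold_min_marks_everything_positive(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.lognormal(6, 1, (3, 20)), ["PCa", "BPH", "DC"])
        fm = fold_over_cutoff(m, fold_min=0.0)
        assert fm.positive.to_numpy().all()

    def test_positivity_monotone_in_value(self):
        values = np.tile(np.arange(1.0, 21.0), (1, 1))
        m = make_matrix(values.copy(), ["PCa"])
        fm = fold_over_cutoff(m)
        cutoff = fm.cutoffs.iloc[0]
        bumped = values.copy()
        j = 0  # below cutoff initially
        bumped[0, j] = cutoff * 3
        fm2 = fold_over_cutoff(make_matrix(bumped, ["PCa"]))
        assert not fm.positive.iloc[0, j]
        assert fm2.positive.iloc[0, j]


class TestTopN:
    def test_dominant_antigen_ranks_first_everywhere(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(5, 0.3, (9, 30))
        values[:, 7] = 5000.0
        m = make_matrix(values, ["PCa"] * 3 + ["BPH"] * 3 + ["DC"] * 3)
        tops = top_n_by_group(m, n=5)
        for g in ("PCa", "BPH", "DC"):
            assert tops[g]["antigen_id"].iloc[0] == "AG007"

    def test_ties_break_lexicographically(self):
        values = np.full((2, 4), 100.0)
        m = make_matrix(values, ["PCa", "BPH"], antigen_ids=["Z", "A", "M", "B"])
        tops = top_n_by_group(m, n=4)
        assert list(tops["PCa"]["antigen_id"]) == ["A", "B", "M", "Z"]

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(5, 1, (6, 15))
        groups = ["PCa", "BPH", "DC"] * 2
        m1 = make_matrix(values, groups)
        perm = rng.permutation(6)
        m2 = make_matrix(values[perm], [groups[i] for i in perm])
        t1 = top_n_by_group(m1, n=10)
        t2 = top_n_by_group(m2, n=10)
        for g in t1:
            assert list(t1[g]["antigen_id"]) == list(t2[g]["antigen_id"])

    def test_unknown_group_structure_rejected(self):
        m = make_matrix(np.ones((2, 3)), ["PCa", "BPH"])
        with pytest.raises(AnalysisError):
            venn_top_sets(m, n=2)  # only two groups present


class TestVenn:
    def test_identical_sets_all_shared(self):
        s = {f"x{i}" for i in range(50)}
        part = venn3_partition({"PCa": s, "BPH": set(s), "DC": set(s)})
        assert part.sizes["all_three"] == 50
        assert part.union_size == 50

    def test_disjoint_sets(self):
        part = venn3_partition(
            {"A": {1, 2}, "B": {3, 4}, "C": {5, 6}}
        )
        assert part.sizes == {
            "A_only": 2, "B_only": 2, "C_only": 2,
            "A_B_only": 0, "A_C_only": 0, "B_C_only": 0, "all_three": 0,
        }

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(trial)
        universe = [f"g{i}" for i in range(40)]
        a, b, c = (
            set(rng.choice(universe, size=rng.integers(0, 30), replace=False))
            for _ in range(3)
        )
        part = venn3_partition({"A": a, "B": b, "C": c})
        oracle = brute_force_venn(a, b, c)
        assert part.regions == oracle
        assert part.union_size == len(a | b | c)

    def test_top_sets_capped_with_warning(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.lognormal(5, 1, (6, 10)), ["PCa", "BPH", "DC"] * 2)
        with pytest.warns(UserWarning, match="capping"):
            part = venn_top_sets(m, n=999)
        assert part.sizes["all_three"] == 10


class TestEthnicity:
    def test_study_strata_sizes(self):
        from seroarray.simulate import load_cohort_table

        meta = load_cohort_table()
        rng = np.random.default_rng(6)
        values = rng.lognormal(5, 1, (len(meta), 12))
        import pandas as pd

        from seroarray.normalize import AntigenMatrix

        sample_ids = [m.sample_id for m in meta]
        vdf = pd.DataFrame(values, index=sample_ids,
                           columns=[f"AG{i}" for i in range(12)])
        fdf = vdf.map(lambda _: frozenset())
        matrix = AntigenMatrix(vdf, fdf, list(meta))
        prof = ethnicity_profile(matrix, meta, "PCa")
        assert prof.stratum_sizes == {"B": 3, "W": 6, "MA": 11}

    def test_flat_matrix_ties_everywhere(self):
        m = make_matrix(
            np.full((6, 5), 50.0), ["PCa"] * 6,
            ethnicities=["B", "B", "W", "W", "MA", "MA"],
        )
        prof = ethnicity_profile(m, group="PCa")
        assert all(v.startswith("tied(") for v in prof.argmax)

    def test_stratum_specific_effect_wins_argmax(self):
        rng = np.random.default_rng(7)
        values = rng.lognormal(5, 0.2, (9, 8))
        eths = ["B", "W", "MA"] * 3
        ma_rows = [i for i, e in enumerate(eths) if e == "MA"]
        values[ma_rows, 3] *= 4.0
        m = make_matrix(values, ["PCa"] * 9, ethnicities=eths)
        prof = ethnicity_profile(m, group="PCa")
        assert prof.argmax["AG003"] == "MA"

    def test_missing_ethnicity_rejected(self):
        m = make_matrix(np.ones((2, 3)), ["PCa", "PCa"])
        with pytest.raises(AnalysisError):
            ethnicity_profile(m, group="PCa")


class TestOverlap:
    def test_empty_protein_list(self):
        panel = build_default_panel()
        assert cross_platform_overlap(panel, []) == set()

    def test_case_insensitive_symbol_match(self):
        panel = build_default_panel()
        hits = cross_platform_overlap(panel, ["fgfr2", "COL6A1", "NOPE"])
        assert hits == {"FGFR2", "COL6A1"}

    def test_shotgun_urine_panel_hits(self):
        """The urinary shotgun identifications that map onto named panel
        antigens (the unnamed panel members carry no gene symbols)."""
        panel = build_default_panel()
        urine = ["FGFR2", "MAPK1", "COL6A1", "SOX1", "CALM1", "SRC", "LIP1",
                 "CEACAM1", "RELT", "EGFR", "ITGB1"]
        hits = cross_platform_overlap(panel, urine)
        assert {"FGFR2", "COL6A1", "CAML1", "CEACAM1_ISOFORM_1", "EGFR"} <= hits


def test_linear_standouts_pick_strongest_fold(small_matrix):
    fm = fold_over_cutoff(small_matrix)
    standouts = linear_standouts(fm, small_matrix, k=4)
    assert set(standouts) == {"PCa", "BPH", "DC"}
    assert all(len(v) == 4 for v in standouts.values())
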
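import numpy as np
import pandas as pd
import pytest

from rbprior.dependency import (
    DependencyError,
    call_essential,
    combine_screens,
    essential_by_subtype,
    intersection_from_counts,
    union_from_counts,
)
from rbprior.synthetic import SimulationConfig, make_truth, simulate_dependency


def matrix_of(scores: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame(scores, index=[f"L{i}" for i in range(len(next(iter(scores.values()))))])


class TestCallEssential:
    def test_strongly_depleted_gene_is_essential(self):
        calls = call_essential(matrix_of({"g": [-1.5, -1.5, -1.5]}))
        assert calls.table.loc[0, "essential"]

    def test_neutral_gene_is_not(self):
        calls = call_essential(matrix_of({"g": [0.0, 0.0]}))
        assert not calls.table.loc[0, "essential"]

    def test_boundary_is_inclusive(self):
        calls = call_essential(matrix_of({"g": [-0.5, -0.5]}))
        assert calls.table.loc[0, "essential"]

    def test_all_missing_gene_is_excluded_and_reported(self):
        mat = matrix_of({"g": [np.nan, np.nan], "h": [-1.0, -1.0]})
        calls = call_essential(mat)
        assert calls.excluded == ("g",)
        assert set(calls.table["gene"]) == {"h"}

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(
            rng.normal(-0.5, 0.5, size=(10, 40)),
            index=[f"L{i}" for i in range(10)],
            columns=[f"g{i}" for i in range(40)],
        )
        loose = call_essential(mat, threshold=0.3).essential_genes
        tight = call_essential(mat, threshold=0.7).essential_genes
        assert tight <= loose

    def test_empty_line_subset_errors(self):
        with pytest.raises(DependencyError):
            call_essential(matrix_of({"g": [0.0]}), lines=[])


class TestCombineScreens:
    def test_inclusion_exclusion_identity(self):
        a = {f"g{i}" for i in range(90)}
        b = {f"g{i}" for i in range(31, 207)}  # overlap of 59
        sets = combine_screens(a, b)
        assert len(sets["union"]) == len(a) + len(b) - len(sets["intersection"])
        assert len(sets["intersection"]) == 59
        assert len(sets["union"]) == 207

    def test_identical_screens(self):
        a = {"x", "y"}
        sets = combine_screens(a, set(a))
        assert sets["union"] == sets["intersection"] == a

    def test_disjoint_screens(self):
        sets = combine_screens({"x"}, {"y"})
        assert sets["intersection"] == set()
        assert len(sets["union"]) == 2

    def test_count_inversion_helpers(self):
        assert intersection_from_counts(90, 176, 207) == 59
        assert union_from_counts(90, 176, 59) == 207
        with pytest.raises(DependencyError):
            intersection_from_counts(5, 5, 100)


class TestBySubtype:
    def test_identical_lines_give_identical_sets(self):
        mat = matrix_of({"g": [-1.0, -1.0, -1.0, -1.0], "h": [0.0, 0.0, 0.0, 0.0]})
        annotations = pd.DataFrame(
            {"cell_line": ["L0", "L1", "L2", "L3"], "subtype": ["A", "A", "B", "B"]}
        )
        by, exclusives, skipped = essential_by_subtype(mat, annotations)
        assert by["A"] == by["B"] == {"g"}
        assert exclusives["A"] == exclusives["B"] == set()
        assert skipped == []

    def test_subtype_specific_gene_is_exclusive(self):
        mat = pd.DataFrame(
            {"g": [-1.5, -1.5, 0.0, 0.0], "h": [-1.0, -1.0, -1.0, -1.0]},
            index=["L0", "L1", "L2", "L3"],
        )
        annotations = pd.DataFrame(
            {"cell_line": ["L0", "L1", "L2", "L3"], "subtype": ["Basal", "Basal", "LumA", "LumA"]}
        )
        by, exclusives, _ = essential_by_subtype(mat, annotations)
        assert "g" in exclusives["Basal"]
        assert "g" not in by["LumA"]
        # exclusives are pairwise disjoint by construction
        assert exclusives["Basal"] & exclusives["LumA"] == set()

    def test_unknown_subtype_lines_are_skipped(self):
        mat = matrix_of({"g": [-1.0]})
        annotations = pd.DataFrame(
            {"cell_line": ["L0", "GHOST"], "subtype": ["A", "B"]}
        )
        by, _, skipped = essential_by_subtype(mat, annotations)
        assert "B" in skipped and "A" in by


class TestParameterRecovery:
    def test_planted_essentials_recovered_with_no_false_positives(self):
        """Sensitivity 1 and false-positive rate <= 1% across repeated draws
        at the planted effect size (mean -1.5, noise sd 0.2, 30 lines)."""
        flags_bg = 0
        n_bg = 0
        for seed in range(50):
            config = SimulationConfig(seed=seed)
            truth = make_truth(config)
            rnai, crispr, _ = simulate_dependency(config, truth)
            planted = truth.planted_progressors | truth.planted_suppressors
            for mat in (rnai, crispr):
                essential = call_essential(mat).essential_genes
                assert planted <= essential  # sensitivity 1.0
                background = set(mat.columns) - planted
                flags_bg += len(essential - planted)
                n_bg += len(background)
        assert flags_bg / n_bg <= 0.01

    def test_null_effect_flags_nothing_in_expectation(self):
        flagged = 0
        total = 0
        for seed in range(50):
            config = SimulationConfig(seed=seed, essential_mean=0.0)
            truth = make_truth(config)
            rnai, _, _ = simulate_dependency(config, truth)
            planted = truth.planted_progressors | truth.planted_suppressors
            essential = call_essential(rnai).essential_genes
            flagged += len(essential & planted)
            total += len(planted)
        assert flagged / total <= 0.01
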
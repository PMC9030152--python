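import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rbprior.alterations import (
    PROGRESSION,
    SUPPRESSION,
    AlterationError,
    burden_by_group,
    burden_per_patient,
    category_breakdown,
    count_per_gene,
    first_quartile_genes,
    mann_whitney,
)
from rbprior.genesets import GeneSet

from _oracles import mann_whitney_enumeration


class TestCountPerGene:
    def test_empty_calls_give_zero_map(self):
        empty = pd.DataFrame(columns=["sample_id", "gene", "category"])
        counts = count_per_gene(empty, PROGRESSION, {"g1", "g2"})
        assert dict(counts) == {"g1": 0, "g2": 0}

    def test_profiles_partition_the_toy_input(self, toy_calls):
        assert count_per_gene(toy_calls, PROGRESSION)["g1"] == 2
        assert count_per_gene(toy_calls, SUPPRESSION)["g1"] == 1

    def test_unknown_category_names_offending_row(self, toy_calls):
        bad = pd.concat(
            [toy_calls, pd.DataFrame([("s3", "g9", "weird")], columns=toy_calls.columns)]
        )
        with pytest.raises(AlterationError, match="weird.*g9"):
            count_per_gene(bad, PROGRESSION)

    def test_both_profiles_cover_all_categories(self, bundle):
        """Mutations and fusions count toward both profiles, so the two
        profile counts together are at least the total event count."""
        genes = set(bundle["genesets"]["rbp"])
        total = count_per_gene(
            bundle["alterations"],
            PROGRESSION.__class__("all", frozenset(PROGRESSION.categories | SUPPRESSION.categories)),
            genes,
        )
        prog = count_per_gene(bundle["alterations"], PROGRESSION, genes)
        supp = count_per_gene(bundle["alterations"], SUPPRESSION, genes)
        assert ((prog + supp) >= total).all()


class TestBurdens:
    def test_per_patient_burden_is_events_over_set_size(self, toy_calls):
        geneset = GeneSet("two", frozenset({"g1", "g2"}))
        burden = burden_per_patient(toy_calls, geneset)
        assert burden["s1"] == pytest.approx(1.0)  # 2 events / 2 genes
        assert burden["s2"] == pytest.approx(0.5)

    def test_patient_without_events_gets_zero(self, toy_calls):
        geneset = GeneSet("two", frozenset({"g1", "g2"}))
        burden = burden_per_patient(toy_calls, geneset, sample_ids=["s1", "s2", "s3"])
        assert burden["s3"] == 0.0

    def test_inert_genes_halve_the_burden(self, toy_calls):
        small = GeneSet("small", frozenset({"g1", "g2"}))
        doubled = GeneSet("big", frozenset({"g1", "g2", "i1", "i2"}))
        b_small = burden_per_patient(toy_calls, small)
        b_big = burden_per_patient(toy_calls, doubled)
        assert np.allclose(b_big.to_numpy(), b_small.to_numpy() / 2)

    def test_row_order_invariance(self, toy_calls):
        geneset = GeneSet("two", frozenset({"g1", "g2"}))
        shuffled = toy_calls.sample(frac=1.0, random_state=1)
        assert burden_per_patient(toy_calls, geneset).equals(
            burden_per_patient(shuffled, geneset).sort_index()
        )

    def test_empty_geneset_errors(self, toy_calls):
        with pytest.raises(AlterationError, match="empty"):
            burden_per_patient(toy_calls, GeneSet("none", frozenset()))

    def test_group_burden_single_group(self, toy_calls):
        samples = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "subtype": ["Basal", "Basal"], "stage": ["I", "I"]}
        )
        burden = burden_by_group(toy_calls, samples, "subtype")
        assert dict(burden) == {"Basal": pytest.approx(3 / 2)}

    def test_boosted_group_has_largest_burden(self):
        rng = np.random.default_rng(0)
        rows = []
        samples = []
        for i in range(60):
            subtype = "Basal" if i < 20 else ("LumA" if i < 40 else "Her2")
            samples.append({"sample_id": f"s{i}", "subtype": subtype})
            n_events = rng.poisson(9 if subtype == "Basal" else 3)
            rows += [
                {"sample_id": f"s{i}", "gene": f"g{j}", "category": "mutation"}
                for j in range(n_events)
            ]
        burden = burden_by_group(pd.DataFrame(rows), pd.DataFrame(samples), "subtype")
        assert burden.idxmax() == "Basal"


class TestMannWhitney:
    def test_textbook_separated_samples(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(2 / 6)

    def test_all_ties_give_half_the_pairs(self):
        res = mann_whitney([5, 5, 5], [5, 5])
        assert res.u_statistic == pytest.approx(3 * 2 / 2)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        x=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=20),
        y=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=20),
    )
    def test_u_statistics_pair_up(self, x, y):
        ux = mann_whitney(x, y).u_statistic
        uy = mann_whitney(y, x).u_statistic
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n1, n2 = rng.integers(1, 7, size=2)
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            res = mann_whitney(x, y)
            u_ref, p_ref = mann_whitney_enumeration(x, y)
            assert res.method == "exact"
            assert res.u_statistic == pytest.approx(u_ref)
            assert res.p_value == pytest.approx(p_ref)

    def test_empty_sample_errors(self):
        with pytest.raises(AlterationError):
            mann_whitney([], [1.0])


class TestFirstQuartile:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"a": 10, "b": 8, "c": 3, "d": 1}, {"a"}),  # 75th pct = 8.5
            ({f"g{i}": i for i in range(1, 9)}, {"g7", "g8"}),  # 75th pct = 6.25
            ({"a": 4, "b": 4, "c": 4}, {"a", "b", "c"}),  # degenerate: all tie
        ],
    )
    def test_percentile_selection(self, counts, expected):
        assert first_quartile_genes(pd.Series(counts)) == expected

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 500), min_size=4, max_size=60))
    def test_result_covers_at_least_a_quarter(self, values):
        counts = pd.Series(values, index=[f"g{i}" for i in range(len(values))])
        selected = first_quartile_genes(counts)
        assert len(selected) >= int(np.ceil(len(values) / 4))


class TestCategoryBreakdown:
    def test_hand_counted_fractions(self):
        calls = pd.DataFrame(
            [("s", f"g{i}", c) for i, c in enumerate(["mrna_up"] * 6 + ["amplification"] * 2 + ["mutation"] * 2)],
            columns=["sample_id", "gene", "category"],
        )
        frac = category_breakdown(calls)
        assert frac["mrna_up"] == pytest.approx(0.6)
        assert frac["amplification"] == pytest.approx(0.2)
        assert frac["mutation"] == pytest.approx(0.2)
        assert frac.sum() == pytest.approx(1.0)

    def test_single_category(self, toy_calls):
        sub = toy_calls[toy_calls["category"] == "mrna_up"]
        frac = category_breakdown(sub)
        assert frac["mrna_up"] == 1.0

    def test_empty_selection_flagged_by_zero_sum(self, toy_calls):
        frac = category_breakdown(toy_calls, GeneSet("none", frozenset({"zz"})))
        assert frac.sum() == 0.0
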
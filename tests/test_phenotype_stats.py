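import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata

from dualscreen.counts_io import CountTable
from dualscreen.library_design import GuideRecord
from dualscreen.phenotype_stats import (
    StatsConfig,
    analyze_screen,
    average_replicates,
    discriminant,
    filter_low_counts,
    gene_phenotype,
    gene_statistics,
    growth_gamma,
    guide_phenotype,
    mw_pvalue,
    normalize_to_controls,
    rank_genes,
    screen_guide_phenotypes,
)


def table_from_pairs(pairs, samples=("s.1.high", "s.1.low")):
    return CountTable(
        elements=[f"e{i}" for i in range(len(pairs))],
        samples=list(samples),
        counts=np.array(pairs),
    )


class TestFilterLowCounts:
    def test_one_sided_dropout_excluded(self):
        table = table_from_pairs([(49, 1000)])
        assert not filter_low_counts(
            table, ("s.1.high", "s.1.low"), 50
        )[0]

    def test_boundary_retained(self):
        table = table_from_pairs([(50, 50)])
        assert filter_low_counts(table, ("s.1.high", "s.1.low"), 50)[0]

    def test_toy_table(self):
        pairs = [(10, 10), (49, 51), (50, 50), (60, 40), (500, 500),
                 (51, 49)]
        table = table_from_pairs(pairs)
        passed = filter_low_counts(table, ("s.1.high", "s.1.low"), 50)
        kept = [e for e, p in zip(table.elements, passed) if p]
        assert kept == ["e2", "e4"]  # (50,50) and (500,500)

    def test_missing_column_error(self):
        table = table_from_pairs([(1, 1)])
        with pytest.raises(KeyError):
            filter_low_counts(table, ("s.1.high", "nope"), 50)


class TestGuidePhenotype:
    def test_balanced_is_zero(self):
        assert guide_phenotype(10, 10, 1000, 1000, 1) == 0.0

    def test_twofold_no_pseudocount(self):
        assert guide_phenotype(20, 10, 1000, 1000, 0) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        got = guide_phenotype(30, 10, 1000, 2000, 1)
        assert got == pytest.approx(math.log2((31 / 1000) / (11 / 2000)))
        assert got == pytest.approx(2.4948, abs=2e-4)

    def test_bad_totals(self):
        with pytest.raises(ValueError):
            guide_phenotype(1, 1, 0, 10, 1)


class TestNormalizeToControls:
    def test_all_nt_median_zero(self):
        raw = np.array([1.0, 2.0, 3.0, 4.0])
        out = normalize_to_controls(raw, np.ones(4, dtype=bool))
        assert np.median(out) == 0.0

    def test_single_nt_maps_to_zero(self):
        raw = np.array([5.0, 1.7])
        out = normalize_to_controls(
            raw, np.array([False, True])
        )
        assert out[1] == 0.0
        assert out[0] == pytest.approx(5.0 - 1.7)

    def test_shift_invariance(self):
        raw = np.array([0.3, -1.2, 2.0, 0.1, np.nan])
        flags = np.array([True, True, False, True, True])
        base = normalize_to_controls(raw, flags)
        shifted = normalize_to_controls(raw + 7.5, flags)
        assert np.allclose(base[:4], shifted[:4], atol=1e-9)

    def test_nan_guides_ignored(self):
        raw = np.array([np.nan, 1.0, 3.0])
        flags = np.array([True, True, True])
        out = normalize_to_controls(raw, flags)
        assert np.isnan(out[0])
        assert np.nanmedian(out[flags]) == 0.0

    def test_no_passing_controls_error(self):
        with pytest.raises(ValueError, match="negative-control"):
            normalize_to_controls(
                np.array([1.0, np.nan]), np.array([False, True])
            )

    @given(
        st.lists(
            st.floats(min_value=-10, max_value=10), min_size=1, max_size=30
        )
    )
    def test_nt_median_exactly_zero(self, values):
        raw = np.asarray(values)
        out = normalize_to_controls(raw, np.ones(len(values), dtype=bool))
        assert np.median(out) == 0.0


class TestAverageReplicates:
    def test_identical_replicates_identity(self):
        rep = np.array([1.0, -2.0, 0.5])
        out = average_replicates([rep, rep.copy()])
        assert np.array_equal(out, rep)

    def test_opposite_replicates_cancel(self):
        out = average_replicates([np.array([1.0]), np.array([-1.0])])
        assert out[0] == 0.0

    def test_single_passing_replicate_used(self):
        out = average_replicates(
            [np.array([np.nan, 2.0]), np.array([3.0, 4.0])]
        )
        assert out[0] == 3.0
        assert out[1] == 3.0

    def test_all_failing_stays_nan(self):
        out = average_replicates(
            [np.array([np.nan, 1.0]), np.array([np.nan, 2.0])]
        )
        assert np.isnan(out[0])

    def test_empty_error(self):
        with pytest.raises(ValueError):
            average_replicates([])
        with pytest.raises(ValueError):
            average_replicates([np.array([np.nan])])


class TestGenePhenotype:
    def test_strongest_three(self):
        assert gene_phenotype([-3, -2, -1, 0, 0.5], 3) == -2.0

    def test_all_zero(self):
        assert gene_phenotype([0.0, 0.0, 0.0], 3) == 0.0

    def test_selection_by_magnitude_not_sign(self):
        got = gene_phenotype([5, -4, 0.1, 0, 0], 3)
        assert got == pytest.approx((5 - 4 + 0.1) / 3)
        assert got == pytest.approx(0.3667, abs=1e-4)

    def test_k_capped_at_available(self):
        assert gene_phenotype([2.0], 3) == 2.0

    def test_tie_broken_by_element_id(self):
        # |1.0| tie between b and c at the 2nd slot: 'b' sorts first
        got = gene_phenotype(
            [2.0, -1.0, 1.0], 2, element_ids=["a", "b", "c"]
        )
        assert got == (2.0 - 1.0) / 2

    def test_no_passing_guides(self):
        with pytest.raises(ValueError):
            gene_phenotype([float("nan")], 3)

    @given(
        st.lists(
            st.floats(min_value=-5, max_value=5), min_size=1, max_size=8
        ),
        st.floats(min_value=0, max_value=3),
        st.integers(min_value=1, max_value=5),
    )
    def test_positive_shift_never_decreases_score(self, values, shift, k):
        base = gene_phenotype(values, k)
        shifted = gene_phenotype([v + shift for v in values], k)
        assert shifted >= base - 1e-9


def enumeration_oracle(x, y):
    """Independent brute force: rank-based U over every labeling."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = np.array(x + y, dtype=float)
    center = n * m / 2.0

    def u_of(indices):
        idx = np.asarray(indices)
        ranks = rankdata(pooled)
        return ranks[idx].sum() - n * (n + 1) / 2.0

    observed = abs(u_of(range(n)) - center)
    hits = total = 0
    for combo in itertools.combinations(range(n + m), n):
        total += 1
        if abs(u_of(combo) - center) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_degenerate_ties(self):
        assert mw_pvalue([3, 3, 3], [3, 3, 3, 3]) == 1.0

    def test_fully_separated_small_samples(self):
        p = mw_pvalue([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert p == pytest.approx(2 / 252)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            mw_pvalue([], [1, 2])

    def test_clamped_to_unit_interval(self):
        p = mw_pvalue([1, 2, 3], [1, 2, 3])
        assert 0 < p <= 1

    @given(
        st.lists(st.integers(min_value=0, max_value=6), min_size=1,
                 max_size=5),
        st.lists(st.integers(min_value=0, max_value=6), min_size=1,
                 max_size=8),
    )
    def test_exact_branch_matches_enumeration_oracle(self, x, y):
        assert mw_pvalue(x, y, exact_max=100) == pytest.approx(
            enumeration_oracle(x, y), abs=1e-12
        )

    def test_asymptotic_branch_reasonable(self, rng):
        x = rng.normal(2, 1, size=5)
        y = rng.normal(0, 1, size=40)  # n*m=200 > exact_max
        p_approx = mw_pvalue(x, y, exact_max=100)
        assert 0 < p_approx < 0.05


class TestDiscriminant:
    def test_zero_phenotype(self):
        assert discriminant(0.0, 0.5) == 0.0

    def test_neglog_product(self):
        assert discriminant(-2.0, 0.01, "neglog_product") == pytest.approx(
            -4.0
        )

    def test_literal_product(self):
        assert discriminant(-2.0, 0.01, "literal_product") == pytest.approx(
            -0.02
        )

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = discriminant(-1.0, 0.0)
        assert np.isfinite(out)

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            discriminant(1.0, 0.5, "geometric")


class TestRankGenes:
    def _frame(self, genes, discs, phens=None):
        return pd.DataFrame(
            {
                "gene": genes,
                "discriminant": discs,
                "phenotype_score": phens or [0.0] * len(genes),
            }
        )

    def test_simple_order(self):
        df = self._frame(["a", "b", "c"], [-4.0, 0.0, 2.0])
        assert rank_genes(df).tolist() == [1, 2, 3]

    def test_all_equal_alphabetical(self):
        df = self._frame(["c", "a", "b"], [1.0, 1.0, 1.0])
        ranks = rank_genes(df)
        assert dict(zip(df["gene"], ranks)) == {"a": 1, "b": 2, "c": 3}

    def test_tie_prefers_larger_effect(self):
        df = self._frame(["a", "b"], [1.0, 1.0], [0.5, -2.0])
        ranks = rank_genes(df)
        assert dict(zip(df["gene"], ranks)) == {"b": 1, "a": 2}

    def test_permutation_invariance(self):
        df = self._frame(["a", "b", "c", "d"], [3.0, -1.0, 0.0, 2.0],
                         [0.1, -0.5, 0.2, 0.9])
        base = dict(zip(df["gene"], rank_genes(df)))
        shuffled = df.iloc[[2, 0, 3, 1]].reset_index(drop=True)
        assert dict(zip(shuffled["gene"], rank_genes(shuffled))) == base

    def test_ranks_are_permutation(self):
        df = self._frame(list("abcdef"), [0.3, -2, 0.3, 5, -2, 0])
        assert sorted(rank_genes(df)) == [1, 2, 3, 4, 5, 6]


class TestGrowthGamma:
    def test_identical_timepoints_zero(self):
        assert growth_gamma(np.zeros(3), 10).tolist() == [0, 0, 0]

    def test_twofold_depletion_over_ten_doublings(self):
        assert growth_gamma(np.array([-1.0]), 10)[0] == pytest.approx(-0.1)

    def test_bad_doublings(self):
        with pytest.raises(ValueError):
            growth_gamma(np.zeros(2), 0)


def _screen_library(n_genes=4, guides=3, n_nt=4):
    records = []
    for g in range(n_genes):
        for k in range(guides):
            records.append(
                GuideRecord(f"G{g}_sg{k}", f"G{g}", "ACGT" * 5)
            )
    for j in range(n_nt):
        records.append(
            GuideRecord(f"NT_sg{j}", "negative_control", "ACGT" * 5,
                        is_negative_control=True)
        )
    # unique protospacers are irrelevant here; ids are what matters
    return records


def _screen_table(records, rng, shift_gene=None, shift=0.0,
                  label="NT", reps=2, base=1000):
    samples, cols = [], []
    for rep in range(1, reps + 1):
        for b in ("high", "low"):
            col = rng.poisson(base, size=len(records))
            if shift_gene is not None:
                mask = np.array([r.gene == shift_gene for r in records])
                factor = 2.0 ** (shift / 2 if b == "high" else -shift / 2)
                col = np.where(mask, (col * factor).astype(int), col)
            samples.append(f"{label}.{rep}.{b}")
            cols.append(col)
    return CountTable(
        elements=[r.element_id for r in records],
        samples=samples,
        counts=np.column_stack(cols),
    )


class TestScreenChain:
    def test_nt_median_zero_and_shift_detected(self, rng):
        records = _screen_library()
        table = _screen_table(records, rng, shift_gene="G1", shift=-2.0)
        guides = screen_guide_phenotypes(table, records, "NT")
        # centering is exact per replicate pair (see
        # TestNormalizeToControls); after replicate averaging the control
        # median only stays near zero
        nt = guides[guides.is_negative_control]["phenotype"]
        assert abs(np.median(nt)) < 0.05
        g1 = guides[guides.gene == "G1"]["phenotype"]
        assert g1.mean() < -1.0

    def test_gene_statistics_fields_and_ranks(self, rng):
        records = _screen_library()
        table = _screen_table(records, rng, shift_gene="G1", shift=-2.0)
        guides, genes = analyze_screen(table, records, "NT")
        assert set(genes.columns) >= {
            "gene", "phenotype_score", "p_value", "discriminant", "rank",
            "n_guides_passing",
        }
        assert sorted(genes["rank"]) == list(range(1, len(genes) + 1))
        assert genes.iloc[0]["gene"] == "G1"  # rank 1 = strongest negative
        assert genes["p_value"].between(0, 1, inclusive="right").all()

    def test_filtered_gene_excluded_from_ranking(self, rng):
        records = _screen_library()
        table = _screen_table(records, rng)
        counts = table.counts.copy()
        mask = np.array([r.gene == "G2" for r in records])
        counts[mask, :] = 5  # below the 50-count filter everywhere
        table = CountTable(table.elements, table.samples, counts)
        _, genes = analyze_screen(table, records, "NT")
        assert "G2" not in set(genes["gene"])
        assert sorted(genes["rank"]) == list(range(1, len(genes) + 1))

    def test_guide_failing_one_replicate_uses_other(self, rng):
        records = _screen_library()
        table = _screen_table(records, rng)
        counts = table.counts.copy()
        target = records[0].element_id
        i = table.elements.index(target)
        counts[i, 0] = 10  # fails replicate 1 pair only
        table = CountTable(table.elements, table.samples, counts)
        guides = screen_guide_phenotypes(table, records, "NT")
        row = guides[guides.element_id == target].iloc[0]
        assert row.n_replicates_passing == 1
        assert np.isfinite(row.phenotype)

    def test_pipeline_determinism_byte_identical(self, rng, tmp_path):
        records = _screen_library()
        table = _screen_table(records, rng, shift_gene="G0", shift=1.0)
        for name in ("a", "b"):
            guides, genes = analyze_screen(table, records, "NT")
            genes.to_csv(tmp_path / f"{name}.tsv", sep="\t", index=False)
        assert (tmp_path / "a.tsv").read_bytes() == (
            tmp_path / "b.tsv"
        ).read_bytes()

    def test_growth_mode_gamma(self, rng):
        records = _screen_library()
        samples, cols = [], []
        for rep in (1, 2):
            day0 = rng.poisson(1000, size=len(records))
            day18 = day0.copy()
            mask = np.array([r.gene == "G3" for r in records])
            day18[mask] = (day18[mask] * 0.5).astype(int)  # 2-fold drop
            samples += [f"NT.{rep}.day0", f"NT.{rep}.day18"]
            cols += [day0, day18]
        table = CountTable(
            [r.element_id for r in records], samples,
            np.column_stack(cols),
        )
        guides, genes = analyze_screen(
            table, records, "NT", mode="growth", doublings=10
        )
        g3 = genes.set_index("gene").loc["G3"]
        assert g3.phenotype_score == pytest.approx(-0.1, abs=0.02)

    def test_missing_pair_column_error(self, rng):
        records = _screen_library()
        table = _screen_table(records, rng)
        partial = CountTable(
            table.elements, table.samples[:1], table.counts[:, :1]
        )
        with pytest.raises(ValueError, match="pair"):
            screen_guide_phenotypes(partial, records, "NT")

    def test_unknown_library_label_error(self, rng):
        records = _screen_library()
        table = _screen_table(records, rng)
        with pytest.raises(ValueError, match="no samples"):
            screen_guide_phenotypes(table, records, "anchor")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            StatsConfig(discriminant_mode="bogus")
        with pytest.raises(ValueError):
            StatsConfig(k_strongest=0)

    def test_literal_product_mode_recorded(self, rng):
        records = _screen_library()
        table = _screen_table(records, rng, shift_gene="G1", shift=-2.0)
        config = StatsConfig(discriminant_mode="literal_product")
        _, genes = analyze_screen(table, records, "NT", config)
        row = genes.set_index("gene").loc["G1"]
        assert row.discriminant == pytest.approx(
            row.phenotype_score * row.p_value
        )
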
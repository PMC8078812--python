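"""Preprocessing operations: QC, OTU filtering, rarefaction, aggregation."""

import numpy as np
import pandas as pd
import pytest

from weanotype import abundance
from weanotype.tables import CountTable, TableValidationError, TaxonomyMap


def _random_table(rng, n_samples=20, n_otus=40, depth_lo=3000, depth_hi=15000):
    depths = rng.integers(depth_lo, depth_hi, size=n_samples)
    probs = rng.dirichlet(np.full(n_otus, 0.3))
    rows = [rng.multinomial(d, probs) for d in depths]
    return CountTable(pd.DataFrame(
        rows, index=[f"s{i}" for i in range(n_samples)],
        columns=[f"o{j}" for j in range(n_otus)],
    ))


def _full_taxonomy(otu_ids, phylum="Firmicutes"):
    return TaxonomyMap(pd.DataFrame({"phylum": phylum}, index=list(otu_ids)))


class TestQcFilterSamples:
    def test_threshold_is_strict_below(self):
        table = CountTable(pd.DataFrame(
            {"o1": [4999, 5000, 12000]}, index=["low", "edge", "high"]
        ))
        kept = abundance.qc_filter_samples(table, 5000)
        assert kept.sample_ids == ["edge", "high"]

    def test_zero_threshold_is_identity(self, toy_counts):
        out = abundance.qc_filter_samples(toy_counts, 0)
        pd.testing.assert_frame_equal(out.data, toy_counts.data)

    def test_survivors_match_brute_force_row_scan(self):
        rng = np.random.default_rng(42)
        table = _random_table(rng)
        kept = abundance.qc_filter_samples(table, 5000)
        expected = [s for s, row in table.data.iterrows() if row.sum() >= 5000]
        assert kept.sample_ids == expected

    def test_all_excluded_raises(self, toy_counts):
        with pytest.raises(ValueError, match="all .* samples"):
            abundance.qc_filter_samples(toy_counts, 10**9)


class TestFilterOtus:
    def test_prevalence_boundary(self):
        data = pd.DataFrame(0, index=[f"s{i}" for i in range(8)],
                            columns=["four", "five"])
        data.iloc[:4, 0] = 500
        data.iloc[:5, 1] = 500
        table = CountTable(data)
        out = abundance.filter_otus(table, _full_taxonomy(data.columns),
                                    min_prevalence=5, min_frac_total=0.0)
        assert out.otu_ids == ["five"]

    def test_abundance_threshold_strictly_greater(self):
        # grand total 1_000_000; an OTU at exactly 0.01% must be removed
        data = pd.DataFrame({"rare": [100], "rest": [999_900]}, index=["s"] * 1)
        table = CountTable(data)
        out = abundance.filter_otus(table, _full_taxonomy(data.columns),
                                    min_prevalence=1, min_frac_total=1e-4)
        assert out.otu_ids == ["rest"]

    def test_unknown_phylum_removed_first(self, toy_counts, toy_taxonomy):
        out = abundance.filter_otus(toy_counts, toy_taxonomy,
                                    min_prevalence=1, min_frac_total=0.0)
        assert "o3" not in out.otu_ids  # unknown phylum
        assert set(out.otu_ids) <= {"o1", "o2"}

    def test_matches_exhaustive_predicate_and_idempotent(self):
        rng = np.random.default_rng(7)
        table = _random_table(rng, n_samples=50, n_otus=200, depth_lo=50, depth_hi=5000)
        phyla = np.where(rng.random(200) < 0.1, "unknown", "Firmicutes")
        tax = TaxonomyMap(pd.DataFrame({"phylum": phyla}, index=table.otu_ids))
        out = abundance.filter_otus(table, tax, 5, 1e-4)
        grand = table.data.to_numpy().sum()
        expected = [
            o for i, o in enumerate(table.otu_ids)
            if phyla[i] != "unknown"
            and (table.data[o] > 0).sum() >= 5
            and table.data[o].sum() / grand > 1e-4
        ]
        assert out.otu_ids == expected
        again = abundance.filter_otus(out, tax, 5, 1e-4)
        pd.testing.assert_frame_equal(again.data, out.data)

    def test_missing_taxonomy_names_otu(self, toy_counts):
        partial = TaxonomyMap(pd.DataFrame({"phylum": ["Firmicutes"]}, index=["o1"]))
        with pytest.raises(TableValidationError, match="o2"):
            abundance.filter_otus(toy_counts, partial)


class TestRarefy:
    def test_row_sums_and_bounds(self):
        rng = np.random.default_rng(3)
        table = _random_table(rng, depth_lo=6000, depth_hi=9000)
        out = abundance.rarefy(table, 4831, seed=5)
        assert (out.data.sum(axis=1) == 4831).all()
        assert (out.data.to_numpy() <= table.data.to_numpy()).all()

    def test_reproducible_and_seed_required(self):
        rng = np.random.default_rng(3)
        table = _random_table(rng, depth_lo=6000, depth_hi=9000)
        a = abundance.rarefy(table, 5000, seed=1)
        b = abundance.rarefy(table, 5000, seed=1)
        pd.testing.assert_frame_equal(a.data, b.data)
        with pytest.raises(ValueError, match="seed"):
            abundance.rarefy(table, 5000)

    def test_exact_depth_row_unchanged(self):
        data = pd.DataFrame({"o1": [3000, 4000], "o2": [2000, 4000]},
                            index=["exact", "other"])
        out = abundance.rarefy(CountTable(data), 5000, seed=0)
        assert out.data.loc["exact"].tolist() == [3000, 2000]

    def test_depth_above_total_names_sample(self):
        data = pd.DataFrame({"o1": [100]}, index=["shallow"])
        with pytest.raises(ValueError, match="shallow"):
            abundance.rarefy(CountTable(data), 5000, seed=0)

    def test_hypergeometric_expectation(self):
        # mean rarefied count of OTU j over many seeds ~ depth * c_j / total
        counts = np.array([[600, 300, 100]])
        table = CountTable(pd.DataFrame(counts, index=["s"], columns=list("abc")))
        depth, n_rep = 200, 400
        draws = np.array([
            abundance.rarefy(table, depth, seed=k).counts[0] for k in range(n_rep)
        ])
        expect = depth * counts[0] / counts.sum()
        # hypergeometric variance for each category
        total = counts.sum()
        var = depth * (counts[0] / total) * (1 - counts[0] / total) * (total - depth) / (total - 1)
        se = np.sqrt(var / n_rep)
        assert (np.abs(draws.mean(axis=0) - expect) < 3 * se + 1e-9).all()


class TestAggregate:
    def test_additivity_and_conservation(self, toy_counts, toy_taxonomy):
        fam = abundance.aggregate(toy_counts, toy_taxonomy, "family")
        # o1 + o2 share a family; o3 goes to the sentinel column
        assert fam.data.loc["s1", "Lachnospiraceae"] == 5
        assert fam.data.loc["s2", "Lachnospiraceae"] == 4
        assert fam.data.loc["s1", "unknown-family"] == 2
        assert fam.data.to_numpy().sum() == toy_counts.data.to_numpy().sum()

    def test_genus_then_family_equals_family(self, small_cohort):
        table, tax = small_cohort.counts, small_cohort.taxonomy
        direct = abundance.aggregate(table, tax, "family")
        genus = abundance.aggregate(table, tax, "genus")
        # map each genus column to its family (unknown genus -> unknown-family
        # is not resolvable, so restrict to named genera)
        g2f = {}
        for _, row in tax.data.iterrows():
            if row["genus"] != "unknown":
                fam_col = row["family"] if row["family"] != "unknown" else "unknown-family"
                g2f.setdefault(row["genus"], fam_col)
        named = [c for c in genus.data.columns if c in g2f]
        regrouped = genus.data[named].T.groupby(
            np.array([g2f[c] for c in named])).sum().T
        for famname in regrouped.columns:
            known_mass = regrouped[famname]
            assert (known_mass <= direct.data[famname]).all()
        # totals conserved at every rank
        assert genus.data.to_numpy().sum() == direct.data.to_numpy().sum()

    def test_phylum_column_count_matches_roster(self, small_cohort):
        phy = abundance.aggregate(small_cohort.counts, small_cohort.taxonomy, "phylum")
        named = [c for c in phy.data.columns if not c.startswith("unknown")]
        assert len(named) == 6
        assert "unknown-phylum" in phy.data.columns

    def test_bad_rank_rejected(self, toy_counts, toy_taxonomy):
        with pytest.raises(ValueError, match="rank"):
            abundance.aggregate(toy_counts, toy_taxonomy, "species")


class TestToRelative:
    def test_normalization_and_zero_rows(self):
        data = pd.DataFrame({"a": [2, 0], "b": [2, 0]}, index=["s1", "z"])
        rel = abundance.to_relative(CountTable(data))
        assert rel.data.loc["s1"].tolist() == [0.5, 0.5]
        assert rel.data.loc["z"].sum() == 0

    def test_random_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        rel = abundance.to_relative(_random_table(rng))
        assert np.allclose(rel.data.sum(axis=1), 1.0)
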
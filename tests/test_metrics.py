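import numpy as np
import pandas as pd
import pytest

from tcsorg.errors import TCSDataError
from tcsorg.metrics import (
    compare_groups,
    complexity_suite,
    correlate_metrics,
    dissemination,
    foci_domain_census,
    gene_type_by_focus_size,
    geometry_census,
    sophistication,
    summarize_replicons,
)
from tcsorg.records import Focus


def F(archs, cats=None, strand="+", rep="rep"):
    cats = cats or tuple(
        "HK" if "T" in a and "R" not in a
        else "hybrid_HK" if "T" in a
        else "RR" if "R" in a
        else "PP"
        for a in archs
    )
    return Focus(
        members=tuple(f"m{i}" for i in range(len(archs))),
        replicon_id=rep,
        strand=strand,
        categories=tuple(cats),
        architectures=tuple(archs),
    )


class TestHeadlineMetrics:
    def test_dissemination(self):
        foci = [1, 1, 1, 1, 2, 2, 2]  # 4 orphans + 3 pair foci
        assert dissemination(foci) == pytest.approx(40.0)
        assert dissemination([1, 1]) == pytest.approx(100.0)
        assert np.isnan(dissemination([]))

    def test_sophistication_bases(self):
        foci = [1, 2, 3]
        assert sophistication(foci) == pytest.approx(50.0)
        assert sophistication(foci, basis="foci") == pytest.approx(100 / 3)
        assert sophistication([1, 2, 2]) == 0.0

    def test_partition_of_percentages(self):
        foci = [1, 1, 2, 2, 3, 4, 5]
        total = dissemination(foci) + sophistication(foci) + \
            100.0 * 4 / sum(foci)  # paired genes
        assert total == pytest.approx(100.0)

    def test_complexity_suite(self):
        foci = [
            F(("T", "R")), F(("T", "R")), F(("R",)),
            F(("T", "R", "R")), F(("R", "T", "R")),
        ]
        comp = complexity_suite(foci)
        assert comp["diversity"] == 4
        assert comp["diversity_gt2"] == 2
        assert comp["n_gt2"] == 2


class TestGeneTypeTable:
    def test_pair_row(self):
        df = gene_type_by_focus_size([F(("T", "R"))])
        assert df.loc["2", "HK"] == 1
        assert df.loc["2", "RR"] == 1
        assert df.loc["2", "PP"] == 0
        assert df.loc["2", "n_foci"] == 1

    def test_hybrids_count_as_hk(self):
        df = gene_type_by_focus_size([F(("TR",))])
        assert df.loc["1", "HK"] == 1

    def test_accepts_bare_category_tuples(self):
        df = gene_type_by_focus_size([("HK", "RR"), ("PP",)])
        assert df.loc["Total", "PP"] == 1


class TestFociDomainCensus:
    def test_hybrid_orphan_is_two_domain_one_gene(self):
        census = foci_domain_census([F(("TR",))])
        assert census.genes_by_domains.loc["2", "1"] == 1

    def test_pair_cell(self):
        census = foci_domain_census([F(("T", "R"))])
        assert census.genes_by_domains.loc["2", "2"] == 1

    def test_gene_totals_match_size_census(self):
        foci = [F(("T", "R")), F(("TR",)), F(("T", "R", "R")), F(("P",))]
        census = foci_domain_census(foci)
        assert census.genes_by_domains["total_genes"].sum() == sum(f.size for f in foci)
        assert census.by_domain_bin["n_foci"].sum() == len(foci)


class TestGeometryCensus:
    def test_counts_distinct_partitions(self):
        foci = [F(("TRP", "R")), F(("TRPR",)), F(("TRP", "R"))]
        df = geometry_census(foci, "TRPR")
        as_dict = dict(zip(df.geometry, df["count"]))
        assert as_dict == {"TRP-R": 2, "TRPR": 1}

    def test_combo_restriction(self):
        foci = [F(("TRP", "R")), F(("T", "R"))]
        df = geometry_census(foci, "TRPR")
        assert df["count"].sum() == 1

    def test_order_free_combo_match(self):
        foci = [F(("R", "TRP"))]  # letters R,T,R,P pooled == TRPR multiset
        assert geometry_census(foci, "RTPR")["count"].sum() == 1


class TestChiSquare:
    def test_closed_form(self):
        obs, exp = [10, 20, 30], [12, 18, 30]
        res = compare_groups(obs, expected=exp)
        manual = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
        assert res.chi2 == pytest.approx(manual)
        assert res.df == 2

    def test_observed_equals_expected(self):
        res = compare_groups([5, 5], expected=[5, 5])
        assert res.chi2 == 0 and res.p == pytest.approx(1.0)

    def test_reference_rescaling(self):
        res = compare_groups([30, 70], reference=[300, 700])
        assert res.chi2 == pytest.approx(0.0)

    def test_single_category_errors(self):
        with pytest.raises(TCSDataError):
            compare_groups([10], expected=[10])

    def test_zero_total_errors(self):
        with pytest.raises(TCSDataError):
            compare_groups([0, 0], expected=[1, 1])

    def test_low_expected_flag(self):
        assert compare_groups([4, 6], expected=[4, 6]).low_expected


class TestCorrelation:
    def test_identical_metrics(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [2, 4, 6, 8]})
        r2, sign = correlate_metrics(df, "a", "b")
        assert r2 == pytest.approx(1.0) and sign == 1

    def test_negative_relation(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [8, 6, 4, 2]})
        r2, sign = correlate_metrics(df, "a", "b")
        assert r2 == pytest.approx(1.0) and sign == -1

    def test_planted_noise(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 200)
        y = -0.8 * x + rng.normal(0, 5, 200)
        df = pd.DataFrame({"x": x, "y": y})
        r2, sign = correlate_metrics(df, "x", "y")
        assert sign == -1 and r2 > 0.9

    def test_zero_variance_is_nan(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1, 2, 3]})
        r2, sign = correlate_metrics(df, "a", "b")
        assert np.isnan(r2)


class TestRepliconSummaries:
    def test_summary_row(self):
        foci = [F(("T", "R"), rep="chr0"), F(("TR",), rep="chr0"), F(("R",), rep="chr0")]
        # distinct member tags per focus
        foci = [
            Focus(tuple(f"m{i}_{j}" for j in range(f.size)), f.replicon_id,
                  f.strand, f.categories, f.architectures)
            for i, f in enumerate(foci)
        ]
        cats, archs = {}, {}
        for f in foci:
            for tag, c, a in zip(f.members, f.categories, f.architectures):
                cats[tag], archs[tag] = c, a
        df = summarize_replicons([], foci, cats, archs)
        row = df.iloc[0]
        assert row["n_genes"] == 4
        assert row["n_HK"] == 2 and row["n_hybrid"] == 1
        assert row["dissemination"] == pytest.approx(50.0)
        assert row["sophistication"] == 0.0
        assert row["avg_genes_per_focus"] == pytest.approx(4 / 3)
        assert row["avg_domains_per_gene"] == pytest.approx(5 / 4)
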
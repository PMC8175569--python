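import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import pirfish as pf
from pirfish.pir import (JunctionCounts, Status, UnsupportedAlignmentError,
                         balance_test, count_junction_reads, estimate_pir,
                         estimate_pir_table, gene_pir_extremes, max_pir_ecdf,
                         percentile_rank, read_junction_counts_tsv,
                         recalc_single_junction)

from conftest import brute_force_junction_counts, random_block_reads


def jc(ei, ie, ee, mid=0, iid="i"):
    return JunctionCounts(iid, ei, ie, ee, mid)


# ---------------------------------------------------------------------------
# counting


class TestCounting:
    def test_spliced_read_with_exact_gap_counts_ee(self):
        model = pf.GeneModel("g", "c", "+", ((900, 1000), (1100, 1300)))
        # 20M100N20M whose gap coincides with the 100-bp intron
        read = [(980, 1000), (1100, 1120)]
        c = count_junction_reads([read], model, min_anchor=8)["g:I1"]
        assert (c.EI, c.IE, c.EE, c.mid_intron) == (0, 0, 1, 0)

    def test_contiguous_read_across_start_counts_ei(self):
        model = pf.GeneModel("g", "c", "+", ((900, 1000), (1100, 1300)))
        read = [(980, 1020)]  # 40M starting 20 bp before the intron start
        c = count_junction_reads([read], model, min_anchor=8)["g:I1"]
        assert (c.EI, c.IE, c.EE, c.mid_intron) == (1, 0, 0, 0)

    def test_read_inside_intron_counts_mid_only(self):
        model = pf.GeneModel("g", "c", "+", ((500, 1000), (1500, 2000)))
        read = [(1100, 1140)]  # 40M well inside the 500-bp intron
        c = count_junction_reads([read], model, min_anchor=8)["g:I1"]
        assert (c.EI, c.IE, c.EE, c.mid_intron) == (0, 0, 0, 1)

    def test_insufficient_anchor_not_counted(self):
        model = pf.GeneModel("g", "c", "+", ((900, 1000), (1100, 1300)))
        c = count_junction_reads([[(995, 1030)]], model, min_anchor=8)["g:I1"]
        assert c.EI == 0  # only 5 bp on the exon side

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_reads(self, strand, seed):
        rng = np.random.default_rng(seed)
        model = pf.GeneModel("g", "c", strand,
                             ((1000, 1200), (1700, 1900), (2500, 2800)))
        reads = random_block_reads(rng, model, n_reads=1000)
        fast = count_junction_reads(reads, model, min_anchor=8)
        slow = brute_force_junction_counts(reads, model, 8)
        for iid, c in fast.items():
            assert (c.EI, c.IE, c.EE, c.mid_intron) == (
                slow[iid]["EI"], slow[iid]["IE"], slow[iid]["EE"],
                slow[iid]["mid_intron"])

    def test_unsupported_cigar_names_read(self, tmp_path, two_exon_model):
        sam = tmp_path / "bad.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrSim\tLN:5000\n"
            "badread\t0\tchrSim\t1001\t60\t20M5I20M\t*\t0\t0\t*\t*\n")
        with pytest.raises(UnsupportedAlignmentError, match="badread"):
            count_junction_reads(sam, two_exon_model)


# ---------------------------------------------------------------------------
# balance test


@pytest.mark.parametrize("ei,ie,expected", [
    (5, 5, 1.0),
    (10, 0, 2 * 0.5 ** 10),          # 0.001953125
    (7, 3, 0.34375),
    (0, 0, 1.0),
])
def test_balance_test_exact_values(ei, ie, expected):
    assert balance_test(ei, ie) == pytest.approx(expected, abs=1e-12)


def test_balance_test_rejects_negative_counts():
    with pytest.raises(ValueError):
        balance_test(-1, 5)


# ---------------------------------------------------------------------------
# estimation


class TestEstimate:
    def test_methods_formula(self):
        est = estimate_pir(jc(30, 30, 70))
        assert est.pir == pytest.approx(30.0)
        assert est.status is Status.OK

    def test_fully_spliced_intron(self):
        est = estimate_pir(jc(0, 0, 50))
        assert est.pir == 0.0
        assert est.status is Status.OK

    def test_imbalanced_junctions_flagged(self):
        est = estimate_pir(jc(20, 2, 30))
        assert est.status is Status.IMBALANCED
        assert est.pir is None
        assert est.balance_p == pytest.approx(1.21116638e-4, rel=1e-6)

    def test_low_coverage_under_fifteen_reads(self):
        est = estimate_pir(jc(3, 4, 5))
        assert est.status is Status.LOW_COVERAGE
        assert est.pir is None and est.n_total == 12

    def test_single_junction_downstream(self):
        est = recalc_single_junction(jc(0, 30, 70), "downstream")
        assert est.pir == pytest.approx(30.0)
        assert est.status is Status.SINGLE_JUNCTION_DOWNSTREAM

    def test_single_junction_upstream(self):
        est = recalc_single_junction(jc(10, 0, 90), "upstream")
        assert est.pir == pytest.approx(10.0)
        assert est.status is Status.SINGLE_JUNCTION_UPSTREAM

    def test_single_junction_no_reads_low_coverage(self):
        for side in ("upstream", "downstream"):
            assert recalc_single_junction(jc(0, 0, 0), side).status \
                is Status.LOW_COVERAGE

    def test_imbalanced_intron_recoverable_single_junction(self):
        counts = jc(60, 4, 40)  # upstream boundary confounded
        assert estimate_pir(counts).status is Status.IMBALANCED
        est = recalc_single_junction(counts, "downstream")
        assert est.pir == pytest.approx(100 * 4 / 44)

    @given(ei=st.integers(0, 200), ie=st.integers(0, 200),
           ee=st.integers(0, 200))
    def test_symmetry_in_junction_counts(self, ei, ie, ee):
        a = estimate_pir(jc(ei, ie, ee), alpha=0.0)  # disable balance filter
        b = estimate_pir(jc(ie, ei, ee), alpha=0.0)
        assert (a.pir is None) == (b.pir is None)
        if a.pir is not None:
            assert a.pir == pytest.approx(b.pir)

    @given(ei=st.integers(5, 100), ee=st.integers(0, 100))
    def test_pir_strictly_decreasing_in_spliced_reads(self, ei, ee):
        lo = estimate_pir(jc(ei, ei, ee + 1), min_total=1)
        hi = estimate_pir(jc(ei, ei, ee), min_total=1)
        assert lo.pir < hi.pir

    @given(ei=st.integers(0, 100), ie=st.integers(0, 100),
           ee=st.integers(0, 100))
    def test_pir_bounded_when_defined(self, ei, ie, ee):
        est = estimate_pir(jc(ei, ie, ee), min_total=1, alpha=0.0)
        if ei + ie + ee == 0:
            assert est.status is Status.LOW_COVERAGE
        else:
            assert est.pir is not None
            assert 0.0 <= est.pir <= 100.0


# ---------------------------------------------------------------------------
# gene summaries


def pir_table(rows):
    return pd.DataFrame(rows, columns=["intron_id", "gene_id", "pir"])


def test_gene_extremes_ignore_undefined():
    tab = pir_table([("a:I1", "a", 30.2), ("a:I2", "a", 31.4),
                     ("a:I3", "a", np.nan)])
    summary = gene_pir_extremes(tab)
    assert summary.loc[0, "max_pir"] == pytest.approx(31.4)
    assert summary.loc[0, "min_pir"] == pytest.approx(30.2)
    assert summary.loc[0, "n_evaluable_introns"] == 2


def test_gene_with_single_defined_pir():
    summary = gene_pir_extremes(pir_table([("a:I1", "a", 12.5)]))
    assert summary.loc[0, "max_pir"] == summary.loc[0, "min_pir"] == 12.5


def test_gene_without_defined_pir_omitted():
    tab = pir_table([("a:I1", "a", np.nan), ("b:I1", "b", 5.0)])
    assert gene_pir_extremes(tab)["gene_id"].tolist() == ["b"]


def test_ecdf_reaches_one_at_class_maximum():
    tab = pir_table([(f"g{i}:I1", f"g{i}", v)
                     for i, v in enumerate([5, 40, 12, 80, 33])])
    ecdf = max_pir_ecdf(gene_pir_extremes(tab))
    top = ecdf.loc[ecdf["max_pir"].idxmax()]
    assert top["ecdf"] == pytest.approx(1.0)
    assert ecdf["ecdf"].is_monotonic_increasing


@pytest.mark.parametrize("value,pop,expected", [
    (31.4, [1, 5, 10, 20, 31.4], 100.0),
    (20, [1, 5, 10, 20, 31.4], 80.0),
    (0.5, [1, 5, 10, 20, 31.4], 0.0),
])
def test_percentile_rank(value, pop, expected):
    assert percentile_rank(value, pop) == pytest.approx(expected)


def test_percentile_rank_empty_population_rejected():
    with pytest.raises(ValueError):
        percentile_rank(1.0, [])


# ---------------------------------------------------------------------------
# table layer


def test_estimate_table_with_single_junction_override(tmp_path):
    counts = {"g:I1": jc(20, 2, 30, iid="g:I1"),
              "g:I2": jc(10, 12, 40, iid="g:I2")}
    table = estimate_pir_table(counts, single_junction={"g:I1": "downstream"})
    by_id = table.set_index("intron_id")
    assert by_id.loc["g:I1", "status"] == "single_junction_downstream"
    assert by_id.loc["g:I1", "pir"] == pytest.approx(100 * 2 / 32)
    assert by_id.loc["g:I2", "status"] == "ok"
    # TSV round trip
    path = tmp_path / "counts.tsv"
    pd.DataFrame([{"intron_id": k, "EI": v.EI, "IE": v.IE, "EE": v.EE,
                   "mid_intron": v.mid_intron} for k, v in counts.items()]
                 ).to_csv(path, sep="\t", index=False)
    assert read_junction_counts_tsv(path) == counts
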
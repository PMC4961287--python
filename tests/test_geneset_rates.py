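"""Per-gene-set rate arithmetic and fold-change contrasts."""

import math

import pytest

from harediff.effect_annotation import Annotation, Effect
from harediff.geneset_rates import (
    RateTable,
    compute_rates,
    contrast_report,
    fold_change,
)
from harediff.reference_data import PUBLISHED_RATES
from harediff.variant_model import Allele, GeneRecord, VariantSite


def _gene(gene_id, n_codons, sets):
    return GeneRecord(gene_id, "ATG" + "GCT" * (n_codons - 2) + "TAA",
                      gene_sets=frozenset(sets))


def _ann(gene_id, pos, effect):
    site = VariantSite(gene_id, pos, Allele("G"), (Allele("C"),))
    return Annotation(site, Allele("C"), effect, None)


class TestComputeRates:
    def test_basic_arithmetic(self):
        genes = {"A": _gene("A", 200, {"s"}), "B": _gene("B", 134, {"s"})}
        # 600 + 402 = 1002 nt... use lengths directly
        denom = genes["A"].length + genes["B"].length
        anns = [
            _ann("A", 10, Effect.SYNONYMOUS),
            _ann("A", 20, Effect.SYNONYMOUS),
            _ann("B", 30, Effect.NONSYNONYMOUS),
            _ann("B", 40, Effect.SYNONYMOUS),
        ]
        table = compute_rates(anns, genes, {"s": ["A", "B"]})
        row = table["s"]
        assert (row.total_sites, row.nonsyn_sites, row.denominator_nt) == (4, 1, denom)
        assert row.total_rate == pytest.approx(4 / denom)
        assert row.nonsyn_rate == pytest.approx(1 / denom)

    def test_no_sites_gives_zero_rates_with_denominator(self):
        genes = {"A": _gene("A", 100, {"s"})}
        row = compute_rates([], genes, {"s": ["A"]})["s"]
        assert row.total_rate == 0.0 and row.denominator_nt == genes["A"].length

    def test_empty_set_is_undefined_not_zero(self):
        row = compute_rates([], {}, {"s": []})["s"]
        assert not row.defined and math.isnan(row.total_rate)

    def test_gene_in_two_sets_counts_in_both(self):
        genes = {"A": _gene("A", 100, {"s", "t"})}
        anns = [_ann("A", 10, Effect.NONSYNONYMOUS)]
        table = compute_rates(anns, genes, {"s": ["A"], "t": ["A"]})
        assert table["s"].total_sites == table["t"].total_sites == 1

    def test_nonsense_counts_as_protein_changing(self):
        genes = {"A": _gene("A", 100, {"s"})}
        table = compute_rates([_ann("A", 10, Effect.NONSENSE)], genes, {"s": ["A"]})
        assert table["s"].nonsyn_sites == 1

    def test_indels_in_total_not_nonsyn_by_default(self):
        genes = {"A": _gene("A", 100, {"s"})}
        anns = [_ann("A", 10, Effect.INDEL_FRAMESHIFT)]
        assert compute_rates(anns, genes, {"s": ["A"]})["s"].nonsyn_sites == 0
        assert compute_rates(anns, genes, {"s": ["A"]})["s"].total_sites == 1
        flipped = compute_rates(anns, genes, {"s": ["A"]}, include_indels_in_nonsyn=True)
        assert flipped["s"].nonsyn_sites == 1

    def test_multiallelic_site_counts_once(self):
        genes = {"A": _gene("A", 100, {"s"})}
        site = VariantSite("A", 10, Allele("G"), (Allele("C"), Allele("T")))
        anns = [
            Annotation(site, Allele("C"), Effect.SYNONYMOUS, None),
            Annotation(site, Allele("T"), Effect.NONSYNONYMOUS, None),
        ]
        row = compute_rates(anns, genes, {"s": ["A"]})["s"]
        assert (row.total_sites, row.nonsyn_sites) == (1, 1)

    def test_scale_invariance(self):
        genes1 = {"A": _gene("A", 100, {"s"})}
        genes3 = {"A": _gene("A", 300, {"s"})}
        anns1 = [_ann("A", 10, Effect.SYNONYMOUS)]
        anns3 = [_ann("A", p, Effect.SYNONYMOUS) for p in (10, 110, 210)]
        r1 = compute_rates(anns1, genes1, {"s": ["A"]})["s"]
        r3 = compute_rates(anns3, genes3, {"s": ["A"]})["s"]
        assert r1.total_rate == pytest.approx(r3.total_rate)

    def test_disjoint_union_additivity(self):
        genes = {
            "A": _gene("A", 100, {"s"}),
            "B": _gene("B", 140, {"t"}),
        }
        anns = [_ann("A", 10, Effect.SYNONYMOUS), _ann("B", 20, Effect.NONSYNONYMOUS)]
        sets = {"s": ["A"], "t": ["B"], "u": ["A", "B"]}
        table = compute_rates(anns, genes, sets)
        assert table["u"].total_sites == table["s"].total_sites + table["t"].total_sites
        assert (
            table["u"].denominator_nt
            == table["s"].denominator_nt + table["t"].denominator_nt
        )


class TestFoldChange:
    def test_published_nuclear_oxphos_vs_glycolysis(self):
        assert fold_change(0.001212, 0.000344) == 3.5

    def test_published_nuclear_oxphos_vs_krebs(self):
        assert fold_change(0.001212, 0.000451) == 2.7

    def test_identity(self):
        assert fold_change(0.123, 0.123) == 1.0

    def test_zero_denominator_undefined(self):
        assert fold_change(0.1, 0.0) is None
        assert fold_change(0.1, math.nan) is None

    def test_half_up_rounding(self):
        assert fold_change(0.35, 1.0) == 0.4
        assert fold_change(0.25, 1.0) == 0.3


@pytest.fixture(scope="module")
def published():
    return RateTable.from_rates(PUBLISHED_RATES)


class TestContrastReport:
    def test_empty_contrasts(self, published):
        assert contrast_report(published, []).empty

    def test_unknown_row_raises(self, published):
        with pytest.raises(KeyError):
            contrast_report(published, [("glycolysis", "nope")])

    def test_self_contrast_is_unity(self, published):
        frame = contrast_report(published, [("krebs", "krebs")])
        assert frame.loc[0, "total_fold"] == frame.loc[0, "nonsyn_fold"] == 1.0

    def test_complex_iv_nuclear_nonsyn_enrichment(self, published):
        frame = contrast_report(
            published,
            [("complex_IV_nuclear", "glycolysis"), ("complex_IV_nuclear", "krebs")],
        ).set_index("denominator")
        assert frame.loc["glycolysis", "nonsyn_fold"] >= 10
        assert frame.loc["krebs", "nonsyn_fold"] >= 8

    def test_from_rates_reproduces_printed_values(self, published):
        row = published["glycolysis"]
        assert row.total_rate == pytest.approx(0.004685, abs=5e-7)
        assert row.nonsyn_rate == pytest.approx(0.000344, abs=5e-7)
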
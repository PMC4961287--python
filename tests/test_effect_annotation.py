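"""Codon-level effect classification against translate-and-compare oracles."""

from itertools import product

import pytest
from Bio.Seq import Seq

from harediff.effect_annotation import (
    Effect,
    annotate_all,
    classify_effect,
    classify_with_context,
    translate_codon,
)
from harediff.variant_model import Allele, GeneRecord, VariantModelError, VariantSite

BASES = "ACGT"


def oracle_translate(codon: str, table_id: int) -> str:
    """Independent single-codon translation via Bio.Seq."""
    return str(Seq(codon).translate(table=table_id))


def oracle_effect(ref_codon: str, alt_codon: str, table_id: int) -> Effect:
    aa_ref = oracle_translate(ref_codon, table_id)
    aa_alt = oracle_translate(alt_codon, table_id)
    if aa_ref == aa_alt:
        return Effect.SYNONYMOUS
    if aa_alt == "*":
        return Effect.NONSENSE
    return Effect.NONSYNONYMOUS


def _gene_with_codon(codon: str, genome: str) -> GeneRecord:
    stop = "TAA"
    return GeneRecord("G", "ATG" + codon + "GCT" + stop, genome=genome)


def _snv(pos: int, ref: str, alt: str) -> VariantSite:
    return VariantSite("G", pos, Allele(ref), (Allele(alt),))


class TestClassifyExamples:
    def test_wobble_position_synonymous(self):
        gene = _gene_with_codon("GGA", "nuclear")
        assert classify_effect(gene, _snv(6, "A", "G"), Allele("G")) == Effect.SYNONYMOUS

    def test_first_position_nonsynonymous(self):
        gene = GeneRecord("G", "ATGGCTTAA", genome="nuclear")
        # ATG -> GTG is Met -> Val
        assert (
            classify_effect(gene, _snv(1, "A", "G"), Allele("G"))
            == Effect.NONSYNONYMOUS
        )

    def test_tga_to_tgg_synonymous_only_in_mt_code(self):
        mito = _gene_with_codon("TGA", "mitochondrial")
        effect = classify_effect(mito, _snv(6, "A", "G"), Allele("G"))
        assert effect == Effect.SYNONYMOUS  # Trp -> Trp
        # the standard code reads TGA as a stop, so the same change there
        # is a stop-loss (protein-changing)
        assert oracle_translate("TGA", 1) == "*" and oracle_translate("TGG", 1) == "W"

    def test_stop_gain_is_nonsense(self):
        gene = _gene_with_codon("TAC", "nuclear")
        assert classify_effect(gene, _snv(6, "C", "A"), Allele("A")) == Effect.NONSENSE

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "AG", Effect.INDEL_FRAMESHIFT),   # +1 nt
            ("A", "AGGG", Effect.INDEL_INFRAME),    # +3 nt
            ("AGG", "A", Effect.INDEL_FRAMESHIFT),  # -2 nt
        ],
    )
    def test_indel_frame_classes(self, ref, alt, expected):
        gene = GeneRecord("G", "ATGAGGGCTGCTTAA", genome="nuclear")
        site = VariantSite("G", 4, Allele(ref), (Allele(alt),))
        assert classify_effect(gene, site, Allele(alt)) == expected

    def test_ref_mismatch_raises_named_error(self):
        gene = _gene_with_codon("GGA", "nuclear")
        with pytest.raises(VariantModelError, match="G:6"):
            classify_effect(gene, _snv(6, "C", "G"), Allele("G"))

    def test_position_beyond_cds_raises(self):
        gene = _gene_with_codon("GGA", "nuclear")
        with pytest.raises(VariantModelError, match="beyond"):
            classify_effect(gene, _snv(99, "A", "G"), Allele("G"))

    def test_codon_context_indexing(self):
        gene = _gene_with_codon("GGA", "nuclear")
        _, ctx = classify_with_context(gene, _snv(6, "A", "G"), Allele("G"))
        assert (ctx.codon_index, ctx.offset_in_codon) == (2, 3)
        assert (ctx.ref_codon, ctx.alt_codon) == ("GGA", "GGG")


class TestExhaustiveOracle:
    @pytest.mark.parametrize("table_id,genome", [(1, "nuclear"), (2, "mitochondrial")])
    def test_all_576_single_base_substitutions(self, table_id, genome):
        """Every codon x every single-base change matches the oracle."""
        checked = 0
        for codon in map("".join, product(BASES, repeat=3)):
            gene = GeneRecord("G", "ATG" + codon + "GCTTAA", genome=genome)
            for offset in range(3):
                ref_base = codon[offset]
                for alt_base in BASES:
                    if alt_base == ref_base:
                        continue
                    alt_codon = codon[:offset] + alt_base + codon[offset + 1 :]
                    site = _snv(4 + offset, ref_base, alt_base)
                    got = classify_effect(gene, site, Allele(alt_base))
                    assert got == oracle_effect(codon, alt_codon, table_id), (
                        codon, alt_codon, genome,
                    )
                    checked += 1
        assert checked == 576

    def test_fourfold_third_positions_always_synonymous(self):
        fourfold_prefixes = [
            p
            for p in map("".join, product(BASES, repeat=2))
            if len({oracle_translate(p + b, 1) for b in BASES}) == 1
        ]
        assert fourfold_prefixes  # e.g. GG, GC, CC ...
        for prefix in fourfold_prefixes:
            gene = GeneRecord("G", "ATG" + prefix + "A" + "GCTTAA", genome="nuclear")
            for alt in BASES:
                if alt == "A":
                    continue
                assert (
                    classify_effect(gene, _snv(6, "A", alt), Allele(alt))
                    == Effect.SYNONYMOUS
                )


class TestAnnotateAll:
    def test_multiallelic_site_fans_out(self):
        gene = _gene_with_codon("GGA", "nuclear")
        site = VariantSite("G", 6, Allele("A"), (Allele("G"), Allele("T")))
        rows = annotate_all([site], {"G": gene})
        assert [str(r.alt) for r in rows] == ["G", "T"]

    def test_empty_input(self):
        assert annotate_all([], {}) == []

    def test_thirty_codon_gene_exhaustive(self):
        """All 270 possible SNVs of a 30-codon gene match the oracle."""
        import numpy as np

        rng = np.random.default_rng(42)
        sense = [
            c
            for c in map("".join, product(BASES, repeat=3))
            if oracle_translate(c, 1) != "*"
        ]
        body = [sense[i] for i in rng.integers(0, len(sense), size=28)]
        cds = "ATG" + "".join(body) + "TAA"
        gene = GeneRecord("G30", cds, genome="nuclear")
        sites = []
        for pos in range(1, 91):
            ref = cds[pos - 1]
            alts = tuple(Allele(b) for b in BASES if b != ref)
            sites.append(VariantSite("G30", pos, Allele(ref), alts))
        rows = annotate_all(sites, {"G30": gene})
        assert len(rows) == 270
        for row in rows:
            pos = row.site.position
            codon_start = (pos - 1) // 3 * 3
            ref_codon = cds[codon_start : codon_start + 3]
            off = (pos - 1) % 3
            alt_codon = ref_codon[:off] + str(row.alt) + ref_codon[off + 1 :]
            assert row.effect == oracle_effect(ref_codon, alt_codon, 1)


def test_translate_codon_rejects_ambiguity():
    with pytest.raises(VariantModelError):
        translate_codon("ANN", 1)
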
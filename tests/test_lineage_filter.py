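"""Five-criterion nomination and the 50%-differentiation call."""

from dataclasses import replace
from itertools import combinations, product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harediff.lineage_filter import (
    FilterParams,
    apply_stringent_filters,
    flag_merged_duplicates,
    genotype_distance,
    is_differentiated,
    nominate_differentiating_sites,
)
from harediff.variant_model import (
    Allele,
    PooledGenotype,
    SiteObservation,
    VariantSite,
)


def brute_force_distance(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    """Oracle: largest sub-multiset of ``a`` contained in ``b`` decides the
    minimum number of slots that must change."""
    from collections import Counter

    cb = Counter(b)
    best_kept = 0
    for k in range(len(a), -1, -1):
        for kept in combinations(a, k):
            ck = Counter(kept)
            if all(cb[x] >= n for x, n in ck.items()):
                best_kept = k
                break
        if best_kept == k:
            break
    return len(a) - best_kept


def _obs(pool, genotype, depths, gq=200.0, qual=300.0, mq=60.0, mq0=0):
    return SiteObservation(
        pool_id=pool,
        genotype=PooledGenotype(genotype),
        allele_depths=depths,
        total_depth=sum(depths.values()),
        site_quality=qual,
        genotype_quality=gq,
        mapping_quality=mq,
        zero_mq_reads=mq0,
    )


def _site(obs_a, obs_b, gene="GENE1", pos=30, ref="A", alts=("G",)):
    return VariantSite(
        gene_id=gene,
        position=pos,
        ref=Allele(ref),
        alts=tuple(Allele(a) for a in alts),
        observations={"european": obs_a, "anatolian": obs_b},
    )


class TestIsDifferentiated:
    def test_half_substituted_hexaploid_is_differentiated(self):
        a = PooledGenotype((0,) * 6)
        b = PooledGenotype((0, 0, 0, 1, 1, 1))
        assert is_differentiated(a, b, 0.5)

    def test_identical_genotypes_are_not(self):
        g = PooledGenotype((0, 0, 1, 1, 2, 2))
        assert not is_differentiated(g, g, 0.5)

    def test_single_slot_below_half_threshold(self):
        a = PooledGenotype((0,) * 6)
        b = PooledGenotype((0, 0, 0, 0, 0, 1))
        assert not is_differentiated(a, b, 0.5)

    def test_unequal_ploidy_raises(self):
        with pytest.raises(ValueError):
            is_differentiated(PooledGenotype((0, 0)), PooledGenotype((0, 0, 0)))

    def test_distance_matches_exhaustive_oracle_small_ploidy(self):
        for ploidy in (2, 3, 4):
            for a in product(range(3), repeat=ploidy):
                for b in product(range(3), repeat=ploidy):
                    assert genotype_distance(
                        PooledGenotype(a), PooledGenotype(b)
                    ) == brute_force_distance(a, b)


genotypes = st.integers(2, 6).flatmap(
    lambda p: st.tuples(
        st.tuples(*[st.integers(0, 3)] * p), st.tuples(*[st.integers(0, 3)] * p)
    )
)


class TestDifferentiationProperties:
    @given(genotypes)
    def test_symmetric(self, pair):
        a, b = (PooledGenotype(g) for g in pair)
        assert genotype_distance(a, b) == genotype_distance(b, a)

    @given(genotypes, st.permutations(list(range(4))))
    def test_invariant_under_joint_allele_relabelling(self, pair, perm):
        a, b = pair
        ra = tuple(perm[i] for i in a)
        rb = tuple(perm[i] for i in b)
        assert genotype_distance(
            PooledGenotype(a), PooledGenotype(b)
        ) == genotype_distance(PooledGenotype(ra), PooledGenotype(rb))

    @given(genotypes)
    def test_disjoint_allele_sets_imply_full_differentiation(self, pair):
        a, b = (PooledGenotype(g) for g in pair)
        if a.allele_set().isdisjoint(b.allele_set()):
            assert is_differentiated(a, b, 1.0)


class TestStringentCriteria:
    def test_clean_fixed_difference_passes_all(self):
        site = _site(
            _obs("european", (0,) * 6, {0: 40}),
            _obs("anatolian", (1,) * 6, {1: 45}),
        )
        v = apply_stringent_filters(site, "european", "anatolian")
        assert v.overall and not v.failing_criteria()

    def test_shared_allele_fails_c1_only(self):
        site = _site(
            _obs("european", (0,) * 6, {0: 40}),
            _obs("anatolian", (0, 0, 0, 1, 1, 1), {0: 33, 1: 35}),
        )
        v = apply_stringent_filters(site, "european", "anatolian")
        assert v.failing_criteria() == ("c1",)

    def test_low_quality_fails_c2_regardless(self):
        site = _site(
            _obs("european", (0,) * 6, {0: 40}, gq=80.0),
            _obs("anatolian", (1,) * 6, {1: 45}),
        )
        v = apply_stringent_filters(site, "european", "anatolian")
        assert not v.c2_quality and not v.overall

    def test_quality_falls_back_to_site_qual_when_gq_absent(self):
        obs = _obs("european", (0,) * 6, {0: 40}, qual=150.0)
        obs.genotype_quality = None
        site = _site(obs, _obs("anatolian", (1,) * 6, {1: 45}))
        assert apply_stringent_filters(site, "european", "anatolian").c2_quality

    def test_depth_29_fails_c3_boundary(self):
        site = _site(
            _obs("european", (0,) * 6, {0: 29}),
            _obs("anatolian", (1,) * 6, {1: 45}),
        )
        v = apply_stringent_filters(site, "european", "anatolian")
        assert v.failing_criteria() == ("c3",)

    def test_two_offcall_reads_fail_c4(self):
        site = _site(
            _obs("european", (0,) * 6, {0: 40, 1: 2}),
            _obs("anatolian", (1,) * 6, {1: 45}),
        )
        v = apply_stringent_filters(site, "european", "anatolian")
        assert v.failing_criteria() == ("c4",)

    def test_duplicate_exclusion_fails_c5(self):
        site = _site(
            _obs("european", (0,) * 6, {0: 40}),
            _obs("anatolian", (1,) * 6, {1: 45}),
        )
        params = FilterParams(duplicate_exclusion=frozenset({"GENE1"}))
        v = apply_stringent_filters(site, "european", "anatolian", params)
        assert v.failing_criteria() == ("c5",)

    def test_missing_pool_marks_not_evaluable(self):
        site = _site(
            _obs("european", (0,) * 6, {0: 40}),
            _obs("anatolian", (1,) * 6, {1: 45}),
        )
        del site.observations["anatolian"]
        v = apply_stringent_filters(site, "european", "anatolian")
        assert not v.evaluable and not v.overall and "anatolian" in v.reason


class TestNomination:
    def test_empty_input(self):
        selected, report = nominate_differentiating_sites([], "european", "anatolian")
        assert selected == [] and report.n_input == report.n_pass == 0

    def test_recovers_exactly_the_planted_sites(self, sim_small):
        params = FilterParams().with_exclusions(sim_small.duplicate_genes)
        selected, report = nominate_differentiating_sites(
            sim_small.sites, "european", "anatolian", params
        )
        got = {s.key() for s, _ in selected}
        planted = {
            (r.gene_id, r.position)
            for r in sim_small.truth.itertuples()
            if r.kind == "differentiating" and r.criterion_path == "strict"
        }
        assert got == planted  # perfect recall, zero false positives
        assert report.reconciles()

    @pytest.mark.parametrize(
        "field,delta",
        [
            ("min_genotype_quality", 300),
            ("min_allele_reads", 20),
            ("min_mapping_quality", 40),
            ("diff_fraction", 0.0),  # unchanged; control row
        ],
    )
    def test_raising_thresholds_never_adds_sites(self, sim_small, field, delta):
        base = FilterParams()
        tightened = replace(base, **{field: getattr(base, field) + delta})
        loose, _ = nominate_differentiating_sites(
            sim_small.sites, "european", "anatolian", base
        )
        tight, _ = nominate_differentiating_sites(
            sim_small.sites, "european", "anatolian", tightened
        )
        assert {s.key() for s, _ in tight} <= {s.key() for s, _ in loose}


class TestMergedDuplicateFlag:
    def test_polyallelic_within_pool_genotype_flags_gene(self):
        site = _site(
            _obs("european", (0, 0, 1, 1, 2, 2), {0: 40, 1: 40, 2: 40}),
            _obs("anatolian", (0,) * 6, {0: 45}),
            gene="TRIALLELIC",
            alts=("G", "T"),
        )
        assert flag_merged_duplicates([site], allele_count_limit=2) == {"TRIALLELIC"}

    def test_uniform_depth_flags_nothing(self):
        sites = [
            _site(
                _obs("european", (0,) * 6, {0: 40}),
                _obs("anatolian", (1,) * 6, {1: 40}),
                gene=f"G{i}",
            )
            for i in range(6)
        ]
        assert flag_merged_duplicates(sites) == set()

    def test_user_list_unioned_in(self):
        assert flag_merged_duplicates([], user_exclusions={"geneX"}) == {"geneX"}

    def test_high_depth_gene_flagged(self):
        normal = [
            _site(
                _obs("european", (0,) * 6, {0: 40}),
                _obs("anatolian", (1,) * 6, {1: 40}),
                gene=f"G{i}",
            )
            for i in range(8)
        ]
        deep = [
            _site(
                _obs("european", (0,) * 6, {0: 400}),
                _obs("anatolian", (1,) * 6, {1: 400}),
                gene="DEEP",
                pos=p,
            )
            for p in (10, 20)
        ]
        assert flag_merged_duplicates(normal + deep, depth_fold=3.0) == {"DEEP"}
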
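"""Seed-variant design: enumeration, exclusion flags, divergence, ranking."""

import numpy as np
import pytest

from seedsafe import Guide
from seedsafe.seqcore import SeedsafeError
from seedsafe.seedmatch import scan_canonical
from seedsafe.profiles import build_profile
from seedsafe import synthgen
from seedsafe.variants import (
    VariantReport,
    apply_exclusion_rules,
    compare_profiles,
    design_variants,
    enumerate_seed_variants,
    opposition_class,
    rank_variants,
    seed_cpg_disrupted,
    variant_position,
)

from conftest import random_rna


class TestEnumeration:
    def test_positions_2_to_7_give_18_variants(self, let7):
        variants = enumerate_seed_variants(let7, range(2, 8))
        assert len(variants) == 18
        assert len({v.sequence for v in variants}) == 18  # duplicate-free

    def test_hamming_distance_one_in_seed(self, let7):
        for v in enumerate_seed_variants(let7, range(2, 8)):
            pos, parent_nt, new_nt = variant_position(let7, v)
            assert 2 <= pos <= 7
            assert parent_nt != new_nt
            assert v.sequence[:1] == let7.sequence[:1]
            assert v.sequence[7:] == let7.sequence[7:]

    def test_naming_convention(self):
        g = Guide("mi", "UCGAAGUAGUGGCUUGUAUAGU")
        # position 5 = A -> variants v5C, v5G, v5U
        variants = enumerate_seed_variants(g, {5})
        assert sorted(v.name for v in variants) == ["miv5C", "miv5G", "miv5U"]

    def test_position_outside_seed_rejected(self, let7):
        with pytest.raises(SeedsafeError):
            enumerate_seed_variants(let7, {12})


class TestExclusionRules:
    def _report(self, parent, variant):
        pos, parent_nt, new_nt = variant_position(parent, variant)
        return VariantReport(
            parent_name=parent.name, variant=variant, position=pos,
            new_nt=new_nt, parent_nt=parent_nt,
            opposition_class=opposition_class(parent_nt, new_nt),
            n_offtargets=0, n_expressed=0, n_shared=0, shared_fraction=None,
            n_shared_sites=0, mean_ddg_shift=None,
        )

    def test_position8_flagged(self, let7):
        v8 = enumerate_seed_variants(let7, set(), include_pos8=True)[0]
        annotated = apply_exclusion_rules([self._report(let7, v8)])
        assert annotated[0].excluded == "position8_overlap"

    def test_cpg_disruption_flagged(self):
        # seed positions 2-7 = ACGUAU: CG dinucleotide at positions 3-4
        g = Guide("cg", "UACGUAUGGCUGGAUGCAUGGC")
        assert seed_cpg_disrupted(g, 3, "A") is True
        v3a = next(v for v in enumerate_seed_variants(g, {3}) if v.name.endswith("3A"))
        annotated = apply_exclusion_rules([self._report(g, v3a)])
        assert annotated[0].excluded == "cpg_disruption"

    def test_cg_free_seed_not_flagged(self, let7):
        # let-7 seed GAGGUA has no CG dinucleotide
        v6 = next(v for v in enumerate_seed_variants(let7, {6}) if v.name.endswith("6A"))
        annotated = apply_exclusion_rules([self._report(let7, v6)])
        assert annotated[0].excluded == "none"


class TestCompareProfiles:
    def test_identity_comparison(self, planted_fixture, let7):
        planted, _, _ = planted_fixture
        profile = build_profile(let7, planted, flank=15)
        utr_seqs = {u.transcript_id: u.sequence for u in planted}
        n_shared, frac, shift, n_shared_sites = compare_profiles(
            profile, profile, let7, let7, utr_seqs
        )
        assert n_shared == len(profile.gene_ids)
        assert frac == 1.0
        assert shift == 0.0
        assert n_shared_sites == len(profile.sites)

    def test_seed_mismatch_breaks_all_planted_sites(self, planted_fixture, let7):
        planted, _, _ = planted_fixture
        utr_seqs = {u.transcript_id: u.sequence for u in planted}
        parent_profile = build_profile(let7, planted, flank=15)
        v6 = next(v for v in enumerate_seed_variants(let7, {6}))
        v6_profile = build_profile(v6, planted, flank=15)
        n_shared, frac, shift, _ = compare_profiles(
            parent_profile, v6_profile, let7, v6, utr_seqs
        )
        # the fixture was decontaminated for the parent seed; the variant seed
        # cannot see the parent's planted sites
        assert n_shared == 0 and frac == 0.0

    def test_mean_ddg_shift_positive_for_seed_mismatch(self, planted_fixture, let7):
        """Any seed mismatch relieves duplex stability on the parent's sites."""
        planted, _, _ = planted_fixture
        utr_seqs = {u.transcript_id: u.sequence for u in planted}
        parent_profile = build_profile(let7, planted, flank=15)
        for v in enumerate_seed_variants(let7, range(2, 8)):
            vprofile = build_profile(v, planted, flank=15)
            _, _, shift, _ = compare_profiles(parent_profile, vprofile, let7, v, utr_seqs)
            assert shift is not None and shift > 0, v.name

    def test_empty_parent_fraction_missing(self, let7):
        empty = build_profile(let7, [])
        n_shared, frac, shift, _ = compare_profiles(empty, empty, let7, let7, {})
        assert frac is None and shift is None


class TestPosition8Superset:
    def test_a1_and_6mer_sites_survive_position8_mutation(self, let7):
        """7mer-A1/6mer recognition depends only on positions 2-7."""
        rng = np.random.default_rng(91)
        v8s = enumerate_seed_variants(let7, set(), include_pos8=True)
        from seedsafe.seqcore import UTRRecord

        for trial in range(30):
            utr = UTRRecord("G", "T", random_rna(rng, 300))
            parent_sites = [
                s.local_span
                for s in scan_canonical(let7, utr, include_6mer=True)
                if s.site_type in ("7mer-A1", "6mer")
            ]
            for v8 in v8s:
                v8_spans = [
                    s.local_span
                    for s in scan_canonical(v8, utr, include_6mer=True)
                ]
                # every parent A1/6mer site is still a site of the variant
                # (possibly upgraded in type when the new position 8 pairs)
                for span in parent_sites:
                    assert any(v[0] <= span[1] and span[0] <= v[1] for v in v8_spans)


class TestCpGStatistics:
    def test_cg_seed_matches_rarer_on_depleted_utromes(self):
        """A CG-containing seed finds fewer sites than its CG-free shuffle."""
        cg_guide = Guide("cg", "UACGUAUGGCUGGAUGCAUGGC")   # seed ACGUAU (has CG)
        free_guide = Guide("fr", "UAGCUAUGGCUGGAUGCAUGGC")  # seed AGCUAU (same letters)
        wins = 0
        trials = 60
        for seed in range(trials):
            utrome, _ = synthgen.generate_utrome(
                50, 600, gc=0.5, cpg_depletion=0.9, rng_seed=1000 + seed
            )
            def count(guide):
                return sum(
                    len(scan_canonical(guide, u, include_6mer=True)) for u in utrome
                )
            if count(cg_guide) < count(free_guide):
                wins += 1
        assert wins >= 0.95 * trials


class TestRanking:
    def _mk(self, parent, name_pos_nt):
        pos, nt = name_pos_nt
        parent_nt = parent.at(pos)
        seq = parent.sequence[: pos - 1] + nt + parent.sequence[pos:]
        v = Guide(f"{parent.name}v{pos}{nt}", seq)
        return VariantReport(
            parent_name=parent.name, variant=v, position=pos, new_nt=nt,
            parent_nt=parent_nt,
            opposition_class=opposition_class(parent_nt, nt),
            n_offtargets=10, n_expressed=5, n_shared=0, shared_fraction=0.0,
            n_shared_sites=0, mean_ddg_shift=1.0,
        )

    def test_tolerated_positions_rank_before_disruptive(self, let7):
        reports = [self._mk(let7, (5, "U")), self._mk(let7, (6, "A")),
                   self._mk(let7, (2, "C"))]
        ranked = rank_variants(apply_exclusion_rules(reports))
        names = [r.variant.name for r in ranked]
        assert names.index("let7v2C") == 2  # positions 5/6 first

    def test_detox_key_prefers_purine_purine(self, let7):
        # v6A creates A:G (pur:pur), v5U creates U:U (pyr:pyr)
        reports = [self._mk(let7, (6, "A")), self._mk(let7, (5, "U"))]
        # force comparable positions: both in the tolerated tier
        ranked = rank_variants(apply_exclusion_rules(reports))
        v6a = next(r for r in ranked if r.variant.name == "let7v6A")
        v5u = next(r for r in ranked if r.variant.name == "let7v5U")
        if v6a.opposition_class == "pur_pur" and v5u.opposition_class == "pyr_pyr":
            assert v6a.detox_rank < v5u.detox_rank

    def test_all_excluded_preserved_but_flagged(self, let7):
        v8s = enumerate_seed_variants(let7, set(), include_pos8=True)
        reports = apply_exclusion_rules([
            self._mk(let7, (8, v.at(8))) for v in v8s
        ])
        ranked = rank_variants(reports)
        assert len(ranked) == len(reports)
        assert all(r.excluded == "position8_overlap" for r in ranked)


class TestDesignVariants:
    def test_end_to_end_table(self, planted_fixture, let7):
        planted, _, genes = planted_fixture
        from seedsafe.seqcore import ExpressionSet

        expr = ExpressionSet("mouse", frozenset(genes[:3]))
        reports, parent_profile = design_variants(
            let7, planted, expr, positions=range(5, 7), flank=15
        )
        assert len(reports) == 6  # 2 positions x 3 substitutions
        assert len(parent_profile.gene_records) == 5
        for r in reports:
            assert r.shared_fraction == 0.0  # decontaminated fixture
            assert r.mean_ddg_shift > 0
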
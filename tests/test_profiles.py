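"""Off-target pipeline: scoring, aggregation, expression, conservation."""

import numpy as np
import pytest

from seedsafe import Guide, UTRRecord
from seedsafe.seqcore import ExpressionSet, OrthologMap
from seedsafe.seedmatch import SiteMatch, scan_canonical
from seedsafe.profiles import (
    build_profile,
    conserved_offtargets,
    context_score,
    profile_summary,
)
from seedsafe import synthgen


def _site(site_type, span, gene="G", tid="T"):
    length = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[site_type]
    return SiteMatch("g", gene, tid, site_type, span, "A" * length)


class TestContextScore:
    def test_type_baseline_ordering(self, let7):
        seq = "C" * 60 + "CUACCUCA" + "C" * 60
        s8 = context_score(_site("8mer", (61, 68)), seq, let7)
        s7a = context_score(_site("7mer-A1", (62, 68)), seq, let7)
        assert s8 < s7a

    def test_au_rich_flanks_score_lower(self, let7):
        au = "AU" * 30 + "CUACCUCA" + "AU" * 30
        gc = "GC" * 30 + "CUACCUCA" + "GC" * 30
        site = _site("8mer", (61, 68))
        assert context_score(site, au, let7) < context_score(site, gc, let7)

    def test_near_end_site_scores_lower(self, let7):
        seq = "C" * 400 + "CUACCUCA" + "C" * 400
        near = "C" * 15 + "CUACCUCA" + "C" * 785
        assert context_score(_site("8mer", (16, 23)), near, let7) < \
            context_score(_site("8mer", (401, 408)), seq, let7)

    def test_3p_pairing_lowers_score(self, let7):
        # upstream flank complementary to guide positions 13-16 vs not
        comp_13_16 = "".join({"A": "U", "C": "G", "G": "C", "U": "A"}[c]
                             for c in let7.sequence[12:16][::-1])
        base = "C" * 52 + "CUACCUCA" + "C" * 60
        paired = "C" * 48 + comp_13_16 + "CUACCUCA" + "C" * 60
        site = _site("8mer", (53, 60))
        assert context_score(site, paired, let7) <= context_score(site, base, let7)


class TestBuildProfile:
    def test_planted_truth_recovered(self, planted_fixture, warm_thermo, let7):
        planted, truth, genes = planted_fixture
        profile = build_profile(let7, planted)
        assert sorted(profile.gene_ids) == sorted(genes)
        assert len(profile.sites) == 5
        spans = {(s.transcript_id, s.site.local_span) for s in profile.sites}
        assert spans == {(t.transcript_id, t.local_span) for t in truth.planted}

    def test_expression_subset(self, planted_fixture, let7):
        planted, _, genes = planted_fixture
        expr = ExpressionSet("mouse", frozenset(genes[:3]))
        profile = build_profile(let7, planted, expr)
        assert profile.expressed_subset == frozenset(genes[:3])

    def test_relaxed_only_sites_never_appear(self, let7):
        utrome, _ = synthgen.generate_utrome(5, 400, rng_seed=19)
        planted, truth = synthgen.plant_sites(
            utrome, let7, [("G0001", ("relaxed", 7, 5))], rng_seed=19
        )
        profile = build_profile(let7, planted)
        assert profile.sites == [] and profile.gene_records == []

    def test_empty_utrome_warns(self, let7, caplog):
        with caplog.at_level("WARNING"):
            profile = build_profile(let7, [])
        assert profile.gene_records == []
        assert "empty UTRome" in caplog.text

    def test_gene_aggregation_minima_exact(self, let7):
        utrome, _ = synthgen.generate_utrome(6, 500, rng_seed=29)
        planted, _ = synthgen.plant_sites(
            utrome, let7,
            [("G0002", "8mer"), ("G0002", "7mer-m8"), ("G0004", "8mer")],
            rng_seed=29,
        )
        profile = build_profile(let7, planted)
        by_gene = {}
        for s in profile.sites:
            by_gene.setdefault(s.gene_id, []).append(s)
        for rec in profile.gene_records:
            sites = by_gene[rec.gene_id]
            assert rec.n_sites == len(sites)
            assert rec.min_ddg == min(s.score.ddg for s in sites)
            assert rec.min_context_score == min(s.context_score for s in sites)

    def test_ranking_ascending_by_min_ddg(self, planted_fixture, let7):
        planted, _, _ = planted_fixture
        profile = build_profile(let7, planted)
        ddgs = [r.min_ddg for r in profile.gene_records]
        assert ddgs == sorted(ddgs)

    def test_expression_changes_membership_not_scores(self, planted_fixture, let7):
        planted, _, genes = planted_fixture
        p_none = build_profile(let7, planted)
        p_expr = build_profile(let7, planted,
                               ExpressionSet("m", frozenset(genes[:2])))
        assert [(s.score.ddg, s.context_score) for s in p_none.sites] == \
            [(s.score.ddg, s.context_score) for s in p_expr.sites]
        assert p_none.expressed_subset == frozenset()
        assert p_expr.expressed_subset == frozenset(genes[:2])

    def test_allowance_monotonicity(self, planted_fixture, let7):
        """Loosening the relaxed budgets never removes a profile site."""
        planted, _, _ = planted_fixture
        default = build_profile(let7, planted)
        tight = build_profile(let7, planted, gu_spec="6;0,7;0,8;0",
                              mm_spec="6;0,7;0,8;0")
        loose = build_profile(let7, planted, gu_spec="6;1,7;2,8;2",
                              mm_spec="6;1,7;2,8;2")
        key = lambda p: {(s.transcript_id, s.site.local_span) for s in p.sites}
        assert key(tight) <= key(default) <= key(loose)

    def test_planted_recovery_many_fixtures(self, let7, warm_thermo):
        """Exact planted-site recovery, no false calls, across random fixtures."""
        rng = np.random.default_rng(55)
        for trial in range(40):
            seed = int(rng.integers(0, 2**31))
            utrome, _ = synthgen.generate_utrome(6, (250, 400), rng_seed=seed)
            genes = [f"G{i:04d}" for i in sorted(rng.choice(6, size=3, replace=False))]
            planted, truth = synthgen.plant_sites(
                utrome, let7, [(g, "8mer") for g in genes], rng_seed=seed
            )
            profile = build_profile(let7, planted, flank=15)
            got = {(s.transcript_id, s.site.local_span) for s in profile.sites}
            want = {(t.transcript_id, t.local_span) for t in truth.planted}
            assert got == want, f"trial {trial} (seed {seed})"


class TestSummary:
    def test_planted_counts(self, planted_fixture, let7):
        planted, _, genes = planted_fixture
        expr = ExpressionSet("mouse", frozenset(genes[:3]))
        summary = profile_summary(build_profile(let7, planted, expr))
        assert summary["n_offtarget_genes"] == 5
        assert summary["n_sites"] == 5
        assert summary["n_offtarget_transcripts"] == 5
        assert summary["n_expressed_genes"] == 3

    def test_empty_profile_zeros(self, let7):
        summary = profile_summary(build_profile(let7, []))
        assert set(summary.values()) == {0}

    def test_two_sites_one_gene(self, let7):
        utrome, _ = synthgen.generate_utrome(3, 500, rng_seed=61)
        planted, _ = synthgen.plant_sites(
            utrome, let7, [("G0001", "8mer"), ("G0001", "7mer-m8")], rng_seed=61
        )
        summary = profile_summary(build_profile(let7, planted))
        assert summary["n_sites"] == 2
        assert summary["n_offtarget_genes"] == 1


class TestConservation:
    def _profile_with_genes(self, let7, species, genes):
        utrome, _ = synthgen.generate_utrome(8, 400, rng_seed=71)
        renamed = [
            UTRRecord(f"{species}:{u.gene_id}", f"{species}:{u.transcript_id}",
                      u.sequence, u.genomic)
            for u in utrome
        ]
        spec = [(g, "8mer") for g in genes]
        planted, _ = synthgen.plant_sites(renamed, let7, spec, rng_seed=71)
        return build_profile(let7, planted, species=species, flank=15)

    def test_disjoint_offtargets_zero_conserved(self, let7):
        pa = self._profile_with_genes(let7, "A", ["A:G0001"])
        pb = self._profile_with_genes(let7, "B", ["B:G0005"])
        omap = OrthologMap({"A:G0001": frozenset({"B:G0002"})})
        rep = conserved_offtargets(pa, pb, omap)
        assert rep.conserved_genes_a == frozenset()
        assert rep.fraction_a == 0.0

    def test_half_conserved_fraction(self, let7):
        pa = self._profile_with_genes(let7, "A", ["A:G0001", "A:G0002"])
        pb = self._profile_with_genes(let7, "B", ["B:G0001"])
        omap = OrthologMap({"A:G0001": frozenset({"B:G0001"})})
        rep = conserved_offtargets(pa, pb, omap)
        assert rep.conserved_genes_a == frozenset({"A:G0001"})
        assert rep.fraction_a == pytest.approx(0.5)
        assert rep.n_unmapped_a == 1

    def test_trio_planted_conservation(self, let7):
        utrome, _ = synthgen.generate_utrome(6, 400, rng_seed=81)
        planted, truth = synthgen.plant_sites(
            utrome, let7, [("G0001", "8mer"), ("G0004", "8mer")], rng_seed=81
        )
        utromes, maps, _ = synthgen.generate_species_trio(
            planted, truth, let7,
            {"G0001": synthgen.SPECIES, "G0004": ("human",)},
            rng_seed=81,
        )
        profiles = {
            sp: build_profile(let7, utromes[sp], species=sp, flank=15)
            for sp in synthgen.SPECIES
        }
        for (a, b), omap in maps.items():
            rep = conserved_offtargets(profiles[a], profiles[b], omap)
            assert f"{a}:G0001" in rep.conserved_genes_a
            assert f"{b}:G0001" in rep.conserved_genes_b
            assert f"{a}:G0004" not in rep.conserved_genes_a
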
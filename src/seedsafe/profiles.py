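"""Per-guide off-target profiling and cross-species conservation.

The pipeline mirrors the two-stage prediction strategy used for artificial
miRNA safety screens: a canonical seed-site scan (TargetScan-style site
types) identifies candidate sites, a relaxed scan (PITA-style wobble and
mismatch budgets) provides the thermodynamic site record, relaxed evidence
without a canonical prediction is discarded, surviving sites are scored with
a ΔΔG (hybridization minus accessibility) and a simplified context-like
score, deduplicated on genomic coordinates, aggregated to genes, intersected
with an expressed-gene set, and ranked by the strongest (minimum) ΔΔG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqcore import (
    COMPLEMENT,
    ExpressionSet,
    Guide,
    OrthologMap,
    SeedsafeError,
    UTRRecord,
    normalize_gene_id,
)
from .seedmatch import (
    DEFAULT_ALLOWANCE_SPEC,
    RelaxedSiteMatch,
    SiteMatch,
    dedupe_genomic,
    scan_canonical,
    scan_relaxed,
)
from . import thermo
from .thermo import DdgScore, EnergyModel, load_energy_model

logger = logging.getLogger("seedsafe")

#: simplified context-like score coefficients (dimensionless; more negative =
#: stronger site).  Baselines preserve the canonical type ordering
#: 8mer < 7mer-m8 < 7mer-A1 < 6mer.
DEFAULT_CONTEXT_COEFFS = {
    "baseline_8mer": -0.31,
    "baseline_7mer-m8": -0.16,
    "baseline_7mer-A1": -0.10,
    "baseline_6mer": -0.04,
    "au_weight": 0.30,       # times (0.5 - AU fraction of 30-nt flanks)
    "au_flank": 30,
    "pairing3p_weight": -0.015,  # per nt of the longest 13-16 pairing run
    "position_weight": 0.10,     # times min(dist-to-UTR-end, cap)/cap
    "position_cap": 1500,
}


@dataclass(frozen=True)
class ScoredSite:
    """A canonical site with its relaxed-scan record and scores."""

    site: SiteMatch
    relaxed: RelaxedSiteMatch
    score: DdgScore
    context_score: float
    expressed: bool = False

    @property
    def gene_id(self) -> str:
        return self.site.gene_id

    @property
    def transcript_id(self) -> str:
        return self.site.transcript_id


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    n_sites: int
    min_context_score: float
    min_ddg: float
    expressed: bool


@dataclass
class OffTargetProfile:
    """Gene-level aggregation of scored sites for one guide on one UTRome."""

    guide_name: str
    species: str
    sites: list[ScoredSite]
    gene_records: list[GeneRecord]
    expressed_subset: frozenset[str]
    parameters: dict

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(g.gene_id for g in self.gene_records)


@dataclass(frozen=True)
class ConservationReport:
    """Pairwise cross-species off-target conservation."""

    species_a: str
    species_b: str
    conserved_genes_a: frozenset[str]   # genes of A with >=1 site in an ortholog's UTR in B
    conserved_genes_b: frozenset[str]
    n_offtargets_a: int
    n_offtargets_b: int
    n_unmapped_a: int
    n_unmapped_b: int
    fraction_a: float   # |conserved_a| / |off-target genes of A|
    fraction_b: float


def context_score(
    site: SiteMatch,
    utr_sequence: str,
    guide: Guide,
    coeffs: Mapping[str, float] | None = None,
) -> float:
    """Simplified context-like score for one canonical site.

    Sum of a site-type baseline, a local-AU term (AU fraction of the 30-nt
    flanks, AU-rich contexts scoring lower), a 3'-pairing term (longest
    complementary run of guide positions 13-16 against the flank upstream of
    the site) and a position term (sites near either UTR end score lower).
    Coefficients are configurable; ranking semantics, not any published
    regression, are what is preserved.
    """
    c = dict(DEFAULT_CONTEXT_COEFFS)
    if coeffs:
        c.update(coeffs)
    s, e = site.local_span
    seq = utr_sequence
    score = c[f"baseline_{site.site_type}"]

    flank_n = int(c["au_flank"])
    flanks = seq[max(0, s - 1 - flank_n) : s - 1] + seq[e : e + flank_n]
    if flanks:
        au = sum(1 for ch in flanks if ch in "AU") / len(flanks)
        score += c["au_weight"] * (0.5 - au)

    # 3'-supplementary pairing: guide 13-16 against the 8 nt upstream of the site
    region = guide.sequence[12:16]
    target_3p = seq[max(0, s - 1 - 8) : s - 1]
    run = 0
    if region and target_3p:
        comp = "".join(COMPLEMENT[ch] for ch in region[::-1])
        best = 0
        for L in range(len(comp), 0, -1):
            for off in range(len(comp) - L + 1):
                if comp[off : off + L] in target_3p:
                    best = L
                    break
            if best:
                break
        run = best
    score += c["pairing3p_weight"] * run

    dist_end = min(s - 1, len(seq) - e)
    cap = c["position_cap"]
    score += c["position_weight"] * min(dist_end, cap) / cap
    return score


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _best_relaxed(canonical: SiteMatch, relaxed: Sequence[RelaxedSiteMatch]) -> RelaxedSiteMatch | None:
    """The overlapping relaxed record with fewest defects, longest seed."""
    candidates = [r for r in relaxed if _overlaps(canonical.local_span, r.local_span)]
    if not candidates:
        return None
    return min(candidates, key=lambda r: (r.n_mismatch + r.n_gu, -r.seed_length, r.local_span))


def build_profile(
    guide: Guide,
    utrome: Sequence[UTRRecord],
    expression: ExpressionSet | None = None,
    species: str = "",
    include_6mer: bool = False,
    gu_spec: str = DEFAULT_ALLOWANCE_SPEC,
    mm_spec: str = DEFAULT_ALLOWANCE_SPEC,
    flank: int = thermo.DEFAULT_FLANK,
    functional_threshold: float = thermo.DEFAULT_FUNCTIONAL_THRESHOLD,
    mismatch_penalty: float = thermo.DEFAULT_MISMATCH_PENALTY,
    context_coeffs: Mapping[str, float] | None = None,
    model: EnergyModel | None = None,
) -> OffTargetProfile:
    """Run the full off-target pipeline for one guide against one UTRome.

    Stages, in order: canonical scan per UTR; relaxed scan per UTR; drop
    relaxed evidence not overlapping a canonical site (and, equivalently,
    canonical sites are the reported entities); ΔΔG + context scoring;
    genomic deduplication; gene aggregation (min = strongest score per
    gene); expression marking; ranking ascending by min ΔΔG with
    (min context score, gene_id) tie-breaks.
    """
    model = model or load_energy_model(mismatch_penalty)
    if not utrome:
        logger.warning("build_profile(%s): empty UTRome", guide.name)
    utr_by_transcript = {u.transcript_id: u for u in utrome}

    kept: list[tuple[SiteMatch, RelaxedSiteMatch]] = []
    n_canonical = n_relaxed = 0
    for utr in utrome:
        canonical = scan_canonical(guide, utr, include_6mer=include_6mer)
        relaxed = scan_relaxed(guide, utr, gu_spec=gu_spec, mm_spec=mm_spec)
        n_canonical += len(canonical)
        n_relaxed += len(relaxed)
        for site in canonical:
            best = _best_relaxed(site, relaxed)
            if best is not None:
                kept.append((site, best))

    n_intersected = len(kept)
    deduped = dedupe_genomic([s for s, _ in kept])
    dedup_keys = {id(s) for s in deduped}
    kept = [(s, r) for s, r in kept if id(s) in dedup_keys]
    logger.info(
        "%s: %d canonical, %d relaxed, %d intersected, %d after dedup",
        guide.name, n_canonical, n_relaxed, n_intersected, len(kept),
    )

    scored: list[ScoredSite] = []
    for site, relaxed_rec in kept:
        utr = utr_by_transcript[site.transcript_id]
        sc = thermo.site_ddg(
            guide, utr.sequence, site.local_span,
            flank=flank, model=model, functional_threshold=functional_threshold,
        )
        ctx = context_score(site, utr.sequence, guide, context_coeffs)
        expressed = (
            expression is not None and normalize_gene_id(site.gene_id) in expression.gene_ids
        )
        scored.append(ScoredSite(site, relaxed_rec, sc, ctx, expressed))

    by_gene: dict[str, list[ScoredSite]] = {}
    for s in scored:
        by_gene.setdefault(s.gene_id, []).append(s)
    gene_records = [
        GeneRecord(
            gene_id=g,
            n_sites=len(ss),
            min_context_score=min(s.context_score for s in ss),
            min_ddg=min(s.score.ddg for s in ss),
            expressed=any(s.expressed for s in ss),
        )
        for g, ss in by_gene.items()
    ]
    gene_records.sort(key=lambda r: (r.min_ddg, r.min_context_score, r.gene_id))
    expressed_subset = frozenset(r.gene_id for r in gene_records if r.expressed)

    params = {
        "guide": guide.sequence,
        "include_6mer": include_6mer,
        "gu_spec": gu_spec,
        "mm_spec": mm_spec,
        "thermo.flank": flank,
        "thermo.threshold": functional_threshold,
        "thermo.mismatch_penalty": mismatch_penalty,
        "context_coeffs": dict(context_coeffs) if context_coeffs else dict(DEFAULT_CONTEXT_COEFFS),
        "energy_model": model.version,
    }
    return OffTargetProfile(
        guide_name=guide.name,
        species=species or (expression.species if expression else ""),
        sites=scored,
        gene_records=gene_records,
        expressed_subset=expressed_subset,
        parameters=params,
    )


def profile_summary(profile: OffTargetProfile) -> dict[str, int]:
    """Site/transcript/gene-granularity counts for one profile."""
    transcripts = {s.transcript_id for s in profile.sites}
    expressed_transcripts = {s.transcript_id for s in profile.sites if s.expressed}
    return {
        "n_sites": len(profile.sites),
        "n_offtarget_transcripts": len(transcripts),
        "n_offtarget_genes": len(profile.gene_records),
        "n_expressed_genes": len(profile.expressed_subset),
        "n_expressed_transcripts": len(expressed_transcripts),
    }


def conserved_offtargets(
    profile_a: OffTargetProfile,
    profile_b: OffTargetProfile,
    orthologs: OrthologMap,
) -> ConservationReport:
    """Pairwise conservation: a gene is conserved iff an ortholog carries a site.

    The headline fraction uses all off-target genes of the species as the
    denominator; genes without an ortholog entry are additionally counted as
    unmapped.  Both directions are reported (the reverse direction uses the
    inverted map).
    """
    if profile_a.guide_name != profile_b.guide_name:
        raise SeedsafeError("conservation profiles must come from the same guide")
    genes_a = {normalize_gene_id(g) for g in profile_a.gene_ids}
    genes_b = {normalize_gene_id(g) for g in profile_b.gene_ids}

    def direction(genes_from: set[str], genes_to: set[str], omap: OrthologMap):
        conserved, unmapped = set(), 0
        for g in sorted(genes_from):
            orth = omap.get(g)
            if not orth:
                unmapped += 1
                continue
            if orth & genes_to:
                conserved.add(g)
        frac = len(conserved) / len(genes_from) if genes_from else 0.0
        return frozenset(conserved), unmapped, frac

    cons_a, unmapped_a, frac_a = direction(genes_a, genes_b, orthologs)
    cons_b, unmapped_b, frac_b = direction(genes_b, genes_a, orthologs.reverse())
    return ConservationReport(
        species_a=profile_a.species,
        species_b=profile_b.species,
        conserved_genes_a=cons_a,
        conserved_genes_b=cons_b,
        n_offtargets_a=len(genes_a),
        n_offtargets_b=len(genes_b),
        n_unmapped_a=unmapped_a,
        n_unmapped_b=unmapped_b,
        fraction_a=frac_a,
        fraction_b=frac_b,
    )


def profile_to_frame(profile: OffTargetProfile) -> pd.DataFrame:
    """Per-site report table (gene, transcript, type, span, scores)."""
    rows = []
    for s in profile.sites:
        rows.append({
            "guide": profile.guide_name,
            "gene_id": s.gene_id,
            "transcript_id": s.transcript_id,
            "site_type": s.site.site_type,
            "start": s.site.local_span[0],
            "end": s.site.local_span[1],
            "seed_len": s.relaxed.seed_length,
            "n_mm": s.relaxed.n_mismatch,
            "n_gu": s.relaxed.n_gu,
            "dg_duplex": round(s.score.dg_duplex, 2),
            "dg_open": round(s.score.dg_open, 2),
            "ddg": round(s.score.ddg, 2),
            "likely_functional": s.score.likely_functional,
            "context_score": round(s.context_score, 4),
            "expressed": s.expressed,
        })
    return pd.DataFrame(rows)


def genes_to_frame(profile: OffTargetProfile) -> pd.DataFrame:
    """Ranked gene-level report table."""
    rows = [
        {
            "rank": i + 1,
            "gene_id": r.gene_id,
            "n_sites": r.n_sites,
            "min_ddg": round(r.min_ddg, 2),
            "min_context_score": round(r.min_context_score, 4),
            "expressed": r.expressed,
        }
        for i, r in enumerate(profile.gene_records)
    ]
    return pd.DataFrame(rows)
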
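"""Seed-detoxification: single-nucleotide seed variants of a toxic guide.

The redesign loop enumerates every single-nucleotide variant of the seed
(positions 2-7 by default, optionally 8), recomputes the off-target profile
of each, applies the two empirical exclusion rules (position-8 variants keep
the parent's profile because 7mer-A1/6mer recognition ignores position 8;
variants that destroy a CG dinucleotide in the seed gain off-targets because
CG is rare in mammalian 3'UTRs), quantifies profile divergence and ΔΔG
relief on the parent's own sites, and ranks variants by predicted on-target
retention.  Ranking rules are data (an editable JSON table) because they
encode empirical findings — mismatches at positions 2/7 disrupt silencing,
positions 5/6 are tolerated, a G:U wobble opposition is the most tolerated
mismatch — that may not generalize to every guide.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .seqcore import COMPLEMENT, Guide, SeedsafeError
from .seedmatch import classify_mismatch
from . import thermo
from .profiles import OffTargetProfile

NUCLEOTIDES = ("A", "C", "G", "U")


def load_retention_rules() -> dict:
    """Load the editable variant-ranking rule table shipped with the package."""
    text = resources.files("seedsafe.data").joinpath("retention_rules.json").read_text()
    return json.loads(text)


@dataclass(frozen=True)
class VariantReport:
    """Figure-table style record for one seed variant vs its parent."""

    parent_name: str
    variant: Guide
    position: int
    new_nt: str
    parent_nt: str
    #: opposition created at the parent's (formerly complementary) target sites
    opposition_class: str
    n_offtargets: int
    n_expressed: int
    n_shared: int
    shared_fraction: float | None
    n_shared_sites: int
    mean_ddg_shift: float | None
    excluded: str = "none"   # none | position8_overlap | cpg_disruption
    retention_rank: int | None = None
    detox_rank: int | None = None


def enumerate_seed_variants(
    guide: Guide,
    positions: Iterable[int] = range(2, 8),
    include_pos8: bool = False,
) -> list[Guide]:
    """All single-nucleotide seed variants of a guide.

    For each position, the three non-identical nucleotides are substituted;
    names follow the v<position><new nt> convention (e.g. v5U, v6A).  The
    non-seed sequence is untouched.
    """
    positions = sorted(set(positions) | ({8} if include_pos8 else set()))
    lo, hi = guide.seed_span[0], guide.extended_seed_span[1]
    out: list[Guide] = []
    for pos in positions:
        if not (1 <= pos <= len(guide)):
            raise SeedsafeError(f"variant position {pos} outside guide {guide.name!r}")
        if not (lo <= pos <= hi):
            raise SeedsafeError(
                f"variant position {pos} outside seed span [{lo}, {hi}]"
            )
        parent_nt = guide.at(pos)
        for nt in NUCLEOTIDES:
            if nt == parent_nt:
                continue
            seq = guide.sequence[: pos - 1] + nt + guide.sequence[pos:]
            out.append(replace(guide, name=f"{guide.name}v{pos}{nt}", sequence=seq))
    return out


def variant_position(parent: Guide, variant: Guide) -> tuple[int, str, str]:
    """(1-based position, parent nt, new nt) of the single difference."""
    diffs = [
        (i + 1, a, b)
        for i, (a, b) in enumerate(zip(parent.sequence, variant.sequence))
        if a != b
    ]
    if len(parent) != len(variant) or len(diffs) != 1:
        raise SeedsafeError(
            f"{variant.name!r} is not a single-nucleotide variant of {parent.name!r}"
        )
    pos, parent_nt, new_nt = diffs[0]
    return pos, parent_nt, new_nt


def opposition_class(parent_nt: str, new_nt: str) -> str:
    """Class of the opposition a variant creates at the parent's target sites.

    At a parent site the target carries the Watson-Crick complement of the
    parent nucleotide; the variant nucleotide now faces that target base.
    """
    target_nt = COMPLEMENT[parent_nt]
    return classify_mismatch(new_nt, target_nt).klass


def seed_cpg_disrupted(parent: Guide, pos: int, new_nt: str) -> bool:
    """True if the substitution removes a CG dinucleotide from the seed region.

    Checked over the extended seed span at any offset: the mutation destroys
    a parent CG either by changing its C or its G (and does not merely move
    it — recreating a CG at the same offset does not count as disruption).
    """
    lo, hi = parent.seed_span[0], parent.extended_seed_span[1]
    seq = parent.sequence
    mutated = seq[: pos - 1] + new_nt + seq[pos:]
    for i in range(lo - 1, hi - 1):  # 0-based start of a dinucleotide in the seed
        if seq[i : i + 2] == "CG" and mutated[i : i + 2] != "CG":
            return True
    return False


def compare_profiles(
    parent_profile: OffTargetProfile,
    variant_profile: OffTargetProfile,
    parent_guide: Guide,
    variant_guide: Guide,
    utr_sequences: dict[str, str],
    model: thermo.EnergyModel | None = None,
) -> tuple[int, float | None, float | None, int]:
    """Profile divergence and ΔΔG relief of a variant vs its parent.

    Returns (n_shared genes, shared_fraction, mean_ddg_shift, n_shared_sites).
    shared_fraction = |gene intersection| / |parent genes| (None when the
    parent profile is empty).  mean_ddg_shift rescores the variant guide on
    the identical target windows of the parent's sites (variant ΔΔG minus
    parent ΔΔG; the accessibility term is window-bound and cancels), so a
    positive shift is off-target relief.  n_shared_sites counts parent sites
    whose exact span also appears in the variant profile.
    """
    model = model or thermo.load_energy_model()
    parent_genes = parent_profile.gene_ids
    variant_genes = variant_profile.gene_ids
    n_shared = len(parent_genes & variant_genes)
    shared_fraction = n_shared / len(parent_genes) if parent_genes else None

    variant_site_keys = {
        (s.transcript_id, s.site.local_span) for s in variant_profile.sites
    }
    n_shared_sites = sum(
        1 for s in parent_profile.sites
        if (s.transcript_id, s.site.local_span) in variant_site_keys
    )

    shifts: list[float] = []
    for s in parent_profile.sites:
        seq = utr_sequences.get(s.transcript_id)
        if seq is None:
            continue
        ws, we = thermo.duplex_window_span(s.site.local_span, len(parent_guide), len(seq))
        window = seq[ws - 1 : we]
        dg_parent = thermo.duplex_energy(parent_guide, window, model)
        dg_variant = thermo.duplex_energy(variant_guide, window, model)
        shifts.append(dg_variant - dg_parent)
    mean_shift = sum(shifts) / len(shifts) if shifts else None
    return n_shared, shared_fraction, mean_shift, n_shared_sites


def apply_exclusion_rules(reports: Sequence[VariantReport]) -> list[VariantReport]:
    """Annotate variants with the empirical exclusion flags.

    Position-8 variants are flagged ``position8_overlap`` (their canonical
    7mer-A1/6mer repertoire is the parent's, so the off-target profile
    extensively overlaps).  Variants whose substitution removes a CG
    dinucleotide from the seed are flagged ``cpg_disruption`` (they gain
    off-targets because CG is rare in mammalian 3'UTRs).  Flags annotate,
    they do not drop: the caller decides.
    """
    out = []
    for r in reports:
        flag = "none"
        parent = replace(r.variant, name=r.parent_name,
                         sequence=r.variant.sequence[: r.position - 1]
                         + r.parent_nt + r.variant.sequence[r.position:])
        if r.position == 8:
            flag = "position8_overlap"
        elif seed_cpg_disrupted(parent, r.position, r.new_nt):
            flag = "cpg_disruption"
        out.append(replace(r, excluded=flag))
    return out


def rank_variants(
    reports: Sequence[VariantReport],
    rules: dict | None = None,
) -> list[VariantReport]:
    """Order variants by predicted on-target retention.

    retention_rank = position tier (5-6 best, 2 and 7 worst) refined by the
    opposition class (G:U wobble most tolerated, then pyr:pyr, then pur:pur).
    detox_rank uses the reverse class order (pur:pur discriminates best).
    Final ordering: non-excluded first, then lexicographic on
    (retention_rank, n_offtargets, shared_fraction).
    """
    rules = rules or load_retention_rules()
    tiers = {int(k): v for k, v in rules["position_tiers"].items()}
    default_tier = rules.get("default_position_tier", max(tiers.values()))
    retention_order = {k: i for i, k in enumerate(rules["retention_class_order"])}
    detox_order = {k: i for i, k in enumerate(rules["detox_class_order"])}

    ranked = []
    for r in reports:
        tier = tiers.get(r.position, default_tier)
        retention = tier * len(retention_order) + retention_order.get(r.opposition_class, len(retention_order))
        detox = tier * len(detox_order) + detox_order.get(r.opposition_class, len(detox_order))
        ranked.append(replace(r, retention_rank=retention, detox_rank=detox))
    ranked.sort(
        key=lambda r: (
            r.excluded != "none",
            r.retention_rank,
            r.n_offtargets,
            r.shared_fraction if r.shared_fraction is not None else math.inf,
            r.variant.name,
        )
    )
    return ranked


def design_variants(
    parent: Guide,
    utrome,
    expression=None,
    positions: Iterable[int] = range(2, 8),
    include_pos8: bool = False,
    rules: dict | None = None,
    **profile_opts,
) -> tuple[list[VariantReport], OffTargetProfile]:
    """Full redesign loop: enumerate, profile, compare, flag and rank.

    Returns the ranked reports and the parent profile.  ``profile_opts`` are
    forwarded to build_profile for both parent and variants (identical
    options, as the comparison contract requires).
    """
    from .profiles import build_profile  # local import to keep module load light

    parent_profile = build_profile(parent, utrome, expression, **profile_opts)
    utr_sequences = {u.transcript_id: u.sequence for u in utrome}
    reports: list[VariantReport] = []
    for variant in enumerate_seed_variants(parent, positions, include_pos8):
        pos, parent_nt, new_nt = variant_position(parent, variant)
        vprofile = build_profile(variant, utrome, expression, **profile_opts)
        n_shared, frac, shift, n_shared_sites = compare_profiles(
            parent_profile, vprofile, parent, variant, utr_sequences
        )
        reports.append(
            VariantReport(
                parent_name=parent.name,
                variant=variant,
                position=pos,
                new_nt=new_nt,
                parent_nt=parent_nt,
                opposition_class=opposition_class(parent_nt, new_nt),
                n_offtargets=len(vprofile.gene_records),
                n_expressed=len(vprofile.expressed_subset),
                n_shared=n_shared,
                shared_fraction=frac,
                n_shared_sites=n_shared_sites,
                mean_ddg_shift=shift,
                )
        )
    reports = apply_exclusion_rules(reports)
    return rank_variants(reports, rules), parent_profile


def variants_to_frame(reports: Sequence[VariantReport]) -> pd.DataFrame:
    """Figure-table style TSV: per-variant counts, flags, shifts, ranks."""
    rows = []
    for r in reports:
        rows.append({
            "variant": r.variant.name,
            "position": r.position,
            "substitution": f"{r.parent_nt}>{r.new_nt}",
            "opposition_class": r.opposition_class,
            "n_offtargets": r.n_offtargets,
            "n_expressed": r.n_expressed,
            "n_shared": r.n_shared,
            "shared_fraction": (
                round(r.shared_fraction, 4) if r.shared_fraction is not None else ""
            ),
            "n_shared_sites": r.n_shared_sites,
            "mean_ddg_shift": (
                round(r.mean_ddg_shift, 3) if r.mean_ddg_shift is not None else ""
            ),
            "excluded": r.excluded,
            "retention_rank": r.retention_rank,
            "detox_rank": r.detox_rank,
        })
    return pd.DataFrame(rows)
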
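"""Seed-complementary site discovery and mismatch typing.

Two scanners are provided: a canonical scanner for the four classic site
types (8mer, 7mer-m8, 7mer-A1, 6mer) and a relaxed scanner that tolerates
per-seed-length budgets of G:U wobbles and mismatches, specified in the
"6;0,7;1,8;1" mini-language.  Motif search is literal string matching on the
transcript strand; antisense matches are out of scope.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .seqcore import COMPLEMENT, Guide, SeedsafeError, UTRRecord, revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
#: strongest first; used for overlap resolution at a shared A1 anchor
SITE_TYPE_PRECEDENCE = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3}
SITE_TYPE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

DEFAULT_ALLOWANCE_SPEC = "6;0,7;1,8;1"

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")


@dataclass(frozen=True)
class SiteMatch:
    """A canonical seed-complementary site on a 3'UTR.

    ``local_span`` is 1-based inclusive in transcript orientation;
    ``genomic_span`` (chrom, start, end, strand), 0-based half-open, is
    present when the UTR carries genomic coordinates.
    """

    guide_name: str
    gene_id: str
    transcript_id: str
    site_type: str
    local_span: tuple[int, int]
    target_site_sequence: str
    genomic_span: tuple[str, int, int, str] | None = None

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise SeedsafeError(f"unknown site type {self.site_type!r}")
        expect = SITE_TYPE_LENGTH[self.site_type]
        got = self.local_span[1] - self.local_span[0] + 1
        if got != expect:
            raise SeedsafeError(
                f"{self.site_type} span length {got} != {expect}"
            )


@dataclass(frozen=True)
class RelaxedSiteMatch:
    """A seed site found under relaxed (wobble/mismatch-tolerant) matching.

    ``seed_length`` is the seed length used (guide positions 2..L+1);
    mismatch and wobble positions are guide seed coordinates.
    """

    guide_name: str
    gene_id: str
    transcript_id: str
    seed_length: int
    local_span: tuple[int, int]
    target_site_sequence: str
    n_mismatch: int
    n_gu: int
    mismatch_positions: tuple[int, ...]
    gu_positions: tuple[int, ...]
    genomic_span: tuple[str, int, int, str] | None = None


@dataclass(frozen=True)
class MismatchClass:
    """Classification of one guide:target nucleotide opposition."""

    guide_nt: str
    target_nt: str
    klass: str  # watson_crick | gu_wobble | pur_pur | pyr_pyr | pur_pyr_mismatch


def classify_mismatch(guide_nt: str, target_nt: str) -> MismatchClass:
    """Classify a guide:target opposition; total on {A,C,G,U}^2.

    Watson-Crick and G:U wobble pairings are recognized first; remaining
    oppositions split by purine/pyrimidine content (U:U is pyr:pyr, A:G is
    pur:pur — the distinction that separates tolerated from discriminating
    seed mismatches).
    """
    for nt in (guide_nt, target_nt):
        if nt not in COMPLEMENT:
            raise SeedsafeError(f"invalid nucleotide {nt!r}")
    if COMPLEMENT[guide_nt] == target_nt:
        klass = "watson_crick"
    elif {guide_nt, target_nt} == {"G", "U"}:
        klass = "gu_wobble"
    elif guide_nt in PURINES and target_nt in PURINES:
        klass = "pur_pur"
    elif guide_nt in PYRIMIDINES and target_nt in PYRIMIDINES:
        klass = "pyr_pyr"
    else:
        klass = "pur_pyr_mismatch"
    return MismatchClass(guide_nt, target_nt, klass)


def seed_of(guide: Guide, span: tuple[int, int] = (2, 7)) -> str:
    """Seed substring at the requested 1-based inclusive positions."""
    a, b = span
    if a < 1 or b > len(guide) or a > b:
        raise SeedsafeError(f"seed span {span} outside guide {guide.name!r}")
    return guide.sequence[a - 1 : b]


def canonical_motifs(guide: Guide) -> dict[str, str]:
    """Target-strand motifs (5'->3') for the four canonical site types.

    The trailing "A" of 7mer-A1/8mer is the target nucleotide opposite guide
    position 1 and is required to be a literal A regardless of the guide's
    first nucleotide.
    """
    core6 = revcomp(seed_of(guide, (2, 7)))
    core7 = revcomp(seed_of(guide, (2, 8)))
    return {
        "6mer": core6,
        "7mer-A1": core6 + "A",
        "7mer-m8": core7,
        "8mer": core7 + "A",
    }


def _genomic_span(utr: UTRRecord, local_span: tuple[int, int]) -> tuple[str, int, int, str] | None:
    """Map a 1-based local span to BED genomic coordinates (single block)."""
    if utr.genomic is None:
        return None
    chrom, gstart, gend, strand = utr.genomic
    s, e = local_span
    if strand == "+":
        return (chrom, gstart + s - 1, gstart + e, strand)
    return (chrom, gend - e, gend - s + 1, strand)


def scan_canonical(guide: Guide, utr: UTRRecord, include_6mer: bool = False) -> list[SiteMatch]:
    """Find all canonical seed sites of a guide on one UTR.

    At a shared A1 anchor (the target position opposite guide position 1)
    only the strongest applicable type is reported, precedence
    8mer > 7mer-m8 > 7mer-A1 > 6mer, so one physical site is never counted
    as several types.  Results are sorted by local_span.
    """
    seq = utr.sequence
    if len(seq) < 6:
        return []
    motifs = canonical_motifs(guide)
    # anchor a = 0-based index of the target position opposite guide pos 1,
    # i.e. the position immediately 3' of the seed-complementary core.
    sites: list[SiteMatch] = []
    for a in range(6, len(seq) + 1):
        hit_type = None
        if a >= 7 and a + 1 <= len(seq) and seq[a - 7 : a + 1] == motifs["8mer"]:
            hit_type, span = "8mer", (a - 6, a + 1)
        elif a >= 7 and seq[a - 7 : a] == motifs["7mer-m8"]:
            hit_type, span = "7mer-m8", (a - 6, a)
        elif a + 1 <= len(seq) and seq[a - 6 : a + 1] == motifs["7mer-A1"]:
            hit_type, span = "7mer-A1", (a - 5, a + 1)
        elif include_6mer and seq[a - 6 : a] == motifs["6mer"]:
            hit_type, span = "6mer", (a - 5, a)
        if hit_type is None:
            continue
        sites.append(
            SiteMatch(
                guide_name=guide.name,
                gene_id=utr.gene_id,
                transcript_id=utr.transcript_id,
                site_type=hit_type,
                local_span=span,
                target_site_sequence=seq[span[0] - 1 : span[1]],
                genomic_span=_genomic_span(utr, span),
            )
        )
    sites.sort(key=lambda s: s.local_span)
    return sites


def parse_allowance_spec(spec: str) -> dict[int, int]:
    """Parse a "len;count,len;count" budget spec into {seed_length: budget}."""
    budgets: dict[int, int] = {}
    for frag in spec.split(","):
        frag = frag.strip()
        if not frag:
            continue
        try:
            length_s, count_s = frag.split(";")
            length, count = int(length_s), int(count_s)
        except ValueError:
            raise SeedsafeError(f"malformed allowance spec fragment {frag!r}") from None
        if length not in (6, 7, 8) or count < 0:
            raise SeedsafeError(f"malformed allowance spec fragment {frag!r}")
        budgets[length] = count
    if not budgets:
        raise SeedsafeError(f"empty allowance spec {spec!r}")
    return budgets


def scan_relaxed(
    guide: Guide,
    utr: UTRRecord,
    gu_spec: str = DEFAULT_ALLOWANCE_SPEC,
    mm_spec: str = DEFAULT_ALLOWANCE_SPEC,
    forbid_anchor_defects: bool = False,
) -> list[RelaxedSiteMatch]:
    """Relaxed seed matching with independent G:U and mismatch budgets.

    For each configured seed length L (guide positions 2..L+1) every UTR
    window of length L is paired against the seed; windows within both
    budgets are reported with exact wobble/mismatch positions.  A perfect
    canonical core is always also reported with n_mismatch = n_gu = 0.
    ``forbid_anchor_defects`` additionally rejects any wobble or mismatch at
    guide position 2 (off by default).
    """
    gu_budget = parse_allowance_spec(gu_spec)
    mm_budget = parse_allowance_spec(mm_spec)
    seq = utr.sequence
    out: list[RelaxedSiteMatch] = []
    for L in sorted(set(gu_budget) & set(mm_budget)):
        if len(seq) < L or len(guide) < L + 1:
            continue
        seed = guide.sequence[1 : L + 1]  # guide positions 2..L+1
        max_gu, max_mm = gu_budget[L], mm_budget[L]
        for start in range(0, len(seq) - L + 1):
            window = seq[start : start + L]
            n_gu = n_mm = 0
            gu_pos: list[int] = []
            mm_pos: list[int] = []
            ok = True
            for k in range(L):
                g = seed[k]  # guide position k+2
                t = window[L - 1 - k]  # antiparallel pairing
                if COMPLEMENT[g] == t:
                    continue
                guide_pos = k + 2
                if {g, t} == {"G", "U"}:
                    n_gu += 1
                    gu_pos.append(guide_pos)
                    if n_gu > max_gu:
                        ok = False
                        break
                else:
                    n_mm += 1
                    mm_pos.append(guide_pos)
                    if n_mm > max_mm:
                        ok = False
                        break
                if forbid_anchor_defects and guide_pos == 2:
                    ok = False
                    break
            if not ok:
                continue
            span = (start + 1, start + L)
            out.append(
                RelaxedSiteMatch(
                    guide_name=guide.name,
                    gene_id=utr.gene_id,
                    transcript_id=utr.transcript_id,
                    seed_length=L,
                    local_span=span,
                    target_site_sequence=window,
                    n_mismatch=n_mm,
                    n_gu=n_gu,
                    mismatch_positions=tuple(mm_pos),
                    gu_positions=tuple(gu_pos),
                    genomic_span=_genomic_span(utr, span),
                )
            )
    out.sort(key=lambda s: (s.local_span, s.seed_length))
    return out


def dedupe_genomic(sites: Sequence[SiteMatch | RelaxedSiteMatch]) -> list:
    """Collapse sites sharing identical genomic coordinates and type.

    The key is (chrom, genomic start, end, strand, site type); sites without
    genomic coordinates are keyed by transcript coordinates instead.  The
    representative retains the lexicographically smallest transcript_id.
    Idempotent and order-insensitive.
    """
    best: dict[tuple, SiteMatch | RelaxedSiteMatch] = {}
    for s in sites:
        kind = s.site_type if isinstance(s, SiteMatch) else f"seed{s.seed_length}"
        if s.genomic_span is not None:
            key = (*s.genomic_span, kind)
        else:
            key = (None, s.transcript_id, *s.local_span, kind)
        prev = best.get(key)
        if prev is None or s.transcript_id < prev.transcript_id:
            best[key] = s
    out = list(best.values())
    out.sort(key=lambda s: (s.transcript_id, s.local_span,
                            s.genomic_span or ("", -1, -1, "")))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

SITE_TSV_COLUMNS = [
    "guide", "gene_id", "transcript_id", "site_type", "start", "end",
    "chrom", "gstart", "gend", "strand", "seed_len", "n_mm", "n_gu",
    "mm_positions",
]


def sites_to_frame(sites: Iterable[SiteMatch | RelaxedSiteMatch]) -> pd.DataFrame:
    """Serialize sites to the stable-column report table."""
    rows = []
    for s in sites:
        chrom, gstart, gend, strand = s.genomic_span if s.genomic_span else ("", "", "", "")
        if isinstance(s, SiteMatch):
            site_type, seed_len, n_mm, n_gu, mm_pos = s.site_type, SITE_TYPE_LENGTH[s.site_type], 0, 0, ()
        else:
            site_type, seed_len = f"seed{s.seed_length}", s.seed_length
            n_mm, n_gu, mm_pos = s.n_mismatch, s.n_gu, s.mismatch_positions
        rows.append({
            "guide": s.guide_name, "gene_id": s.gene_id,
            "transcript_id": s.transcript_id, "site_type": site_type,
            "start": s.local_span[0], "end": s.local_span[1],
            "chrom": chrom, "gstart": gstart, "gend": gend, "strand": strand,
            "seed_len": seed_len, "n_mm": n_mm, "n_gu": n_gu,
            "mm_positions": ",".join(map(str, mm_pos)),
        })
    return pd.DataFrame(rows, columns=SITE_TSV_COLUMNS)


def write_sites_tsv(sites: Iterable[SiteMatch | RelaxedSiteMatch], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)
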
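"""Retargeting a trusted low-off-target seed against a new transcript.

Given the hexamer seed (guide positions 2-7) of a well-tolerated guide, scan
a target mRNA for windows complementary to that seed with at most one seed
mismatch, classify each hit's transcript region (5'UTR / CDS / 3'UTR, with
an exon-junction flag), and assemble a full-length candidate guide whose
3' region is perfectly complementary to the target flank — the strategy that
turns a safe control sequence into an on-target silencer while leaving its
seed-driven off-target repertoire unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .seqcore import COMPLEMENT, Guide, SeedsafeError, TranscriptModel
from .seedmatch import MismatchClass, classify_mismatch
from . import thermo


@dataclass(frozen=True)
class RetargetHit:
    """A (<=1 mismatch) seed-complementary window on a target transcript."""

    seed: str
    transcript_id: str
    local_span: tuple[int, int]   # 1-based spliced coordinates
    n_mismatch: int
    mismatch_position: int | None   # guide seed coordinate, 2-7
    mismatch_class: MismatchClass | None
    region: str                     # 5utr | cds | 3utr
    junction_spanning: bool
    target_window: str


def find_retarget_sites(
    seed: str,
    transcript: TranscriptModel,
    max_mismatch: int = 1,
) -> list[RetargetHit]:
    """Scan a transcript for seed-complementary windows with <=1 defect.

    ``seed`` is the hexamer at guide positions 2-7.  Any non-Watson-Crick
    opposition — including G:U — counts toward the mismatch budget (a
    conservative search); the opposition's class is recorded so downstream
    ranking can still prefer wobbles.  Hits are sorted by position.
    """
    if len(seed) != 6:
        raise SeedsafeError(f"seed must be a hexamer, got {seed!r}")
    if max_mismatch not in (0, 1):
        raise SeedsafeError("max_mismatch must be 0 or 1")
    seq = transcript.sequence
    hits: list[RetargetHit] = []
    if len(seq) < 6:
        return hits
    for start in range(len(seq) - 5):
        window = seq[start : start + 6]
        n_mm = 0
        mm_pos: int | None = None
        mm_class: MismatchClass | None = None
        for k in range(6):
            g = seed[k]                  # guide position k+2
            t = window[5 - k]            # antiparallel pairing
            if COMPLEMENT[g] == t:
                continue
            n_mm += 1
            if n_mm > max_mismatch:
                break
            mm_pos = k + 2
            mm_class = classify_mismatch(g, t)
        if n_mm > max_mismatch:
            continue
        span = (start + 1, start + 6)
        region, junction = classify_region(span, transcript)
        hits.append(
            RetargetHit(
                seed=seed,
                transcript_id=transcript.transcript_id,
                local_span=span,
                n_mismatch=n_mm,
                mismatch_position=mm_pos,
                mismatch_class=mm_class,
                region=region,
                junction_spanning=junction,
                target_window=window,
            )
        )
    return hits


def classify_region(span: tuple[int, int], transcript: TranscriptModel) -> tuple[str, bool]:
    """Region (majority overlap, CDS on ties) and exon-junction flag of a span."""
    s, e = span
    if not (1 <= s <= e <= len(transcript)):
        raise SeedsafeError(f"span {span} outside transcript {transcript.transcript_id}")

    def overlap(region_span: tuple[int, int] | None) -> int:
        if region_span is None:
            return 0
        a, b = region_span
        return max(0, min(e, b) - max(s, a) + 1)

    cds = overlap(transcript.cds_span)
    utr5 = overlap(transcript.utr5_span)
    utr3 = overlap(transcript.utr3_span)
    if cds >= utr5 and cds >= utr3:
        region = "cds"
    elif utr5 > utr3:
        region = "5utr"
    else:
        region = "3utr"
    junction = any(s <= b < e for b in transcript.exon_ends[:-1])
    return region, junction


def assemble_guide(
    seed_parent: Guide,
    hit: RetargetHit,
    target: TranscriptModel,
    guide_length: int = 22,
    position1: str = "U",
) -> Guide:
    """Build a full candidate guide around a retarget hit.

    Positions 2-7 carry the parent seed unchanged (including the recorded
    mismatch versus the target); positions 8..L are the reverse complement
    of the target flank 5' of the seed-pairing window (full 3'
    complementarity); position 1 defaults to U, the conventional loading-
    biased 5' nucleotide, regardless of the target.
    """
    seed = seed_parent.sequence[1:7]
    if hit.seed != seed:
        raise SeedsafeError("hit was found with a different seed than seed_parent's")
    s = hit.local_span[0]
    flank_len = guide_length - 7
    if s - 1 < flank_len:
        raise SeedsafeError(
            f"insufficient 5' flank on target: need {flank_len} nt upstream of "
            f"position {s}, have {s - 1}"
        )
    flank = target.sequence[s - 1 - flank_len : s - 1]
    three_prime = "".join(COMPLEMENT[c] for c in reversed(flank))
    sequence = position1 + seed + three_prime
    return Guide(name=f"{seed_parent.name}ss_{hit.local_span[0]}", sequence=sequence)


def implied_passenger(guide: Guide) -> str:
    """Passenger strand implied by a fully complementary duplex register."""
    return "".join(COMPLEMENT[c] for c in reversed(guide.sequence))


def compare_binding_stability(
    guide_a: Guide,
    guide_b: Guide,
    shared_sites: Sequence[tuple[str, tuple[int, int]]],
    utr_sequences: dict[str, str],
    model: thermo.EnergyModel | None = None,
) -> tuple[list[float], float | None]:
    """Per-site and mean ΔΔG difference between two guides sharing a seed.

    Both guides are rescored on identical site windows; each entry is
    ΔΔG(guide_a) - ΔΔG(guide_b) at one (transcript_id, site span).  The
    accessibility term is shared and cancels, so the difference reduces to
    the hybridization energies; negative values mean guide_a binds that
    off-target site more stably.
    """
    if guide_a.sequence[1:7] != guide_b.sequence[1:7]:
        raise SeedsafeError("guides must share an identical seed (positions 2-7)")
    model = model or thermo.load_energy_model()
    diffs: list[float] = []
    for transcript_id, span in shared_sites:
        seq = utr_sequences[transcript_id]
        ws, we = thermo.duplex_window_span(span, max(len(guide_a), len(guide_b)), len(seq))
        window = seq[ws - 1 : we]
        dg_a = thermo.duplex_energy(guide_a, window, model)
        dg_b = thermo.duplex_energy(guide_b, window, model)
        diffs.append(dg_a - dg_b)
    mean = sum(diffs) / len(diffs) if diffs else None
    return diffs, mean


def hits_to_frame(hits: Sequence[RetargetHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append({
            "transcript_id": h.transcript_id,
            "start": h.local_span[0],
            "end": h.local_span[1],
            "n_mismatch": h.n_mismatch,
            "mismatch_position": h.mismatch_position if h.mismatch_position else "",
            "mismatch_class": h.mismatch_class.klass if h.mismatch_class else "",
            "region": h.region,
            "junction_spanning": h.junction_spanning,
            "target_window": h.target_window,
        })
    return pd.DataFrame(rows)
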
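"""Deterministic synthetic fixtures with planted ground truth.

Every pipeline stage is testable without downloads: UTRomes with
controllable length/GC/CpG composition and planted seed sites at known
coordinates, expression sets and ortholog maps with known overlap structure,
three-species fixtures with a chosen conservation pattern, and transcript
models with planted retarget windows.  Backgrounds are rejection-sampled so
a fixture contains *no* unintended site for its guide (the no-contamination
guarantee), which makes pipeline tests exact rather than statistical.

All randomness flows through one numpy Generator per fixture, seeded
explicitly and recorded in the emitted truth object; nucleotide choices use
integer draws only, so fixtures are byte-identical across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqcore import (
    COMPLEMENT,
    ExpressionSet,
    Guide,
    OrthologMap,
    SeedsafeError,
    TranscriptModel,
    UTRRecord,
    revcomp,
)
from .seedmatch import canonical_motifs, scan_canonical

_NTS = ("A", "C", "G", "U")
_MAX_RETRIES = 1000

SPECIES = ("human", "mouse", "rhesus")


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    transcript_id: str
    kind: str                  # site type, "relaxed", or "retarget"
    local_span: tuple[int, int]
    motif: str
    seed_length: int | None = None
    mismatch_position: int | None = None


@dataclass
class SynthTruth:
    """Ground truth for one synthetic fixture."""

    rng_seed: int
    planted: list[PlantedSite] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    conserved_genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# background sequence
# ---------------------------------------------------------------------------

def _draw_nt(rng: np.random.Generator, weights: Sequence[int]) -> str:
    total = sum(weights)
    r = int(rng.integers(0, total))
    acc = 0
    for nt, w in zip(_NTS, weights):
        acc += w
        if r < acc:
            return nt
    return _NTS[-1]


def _composition_weights(gc: float, cpg_depletion: float) -> tuple[list[int], list[int]]:
    """Integer per-position weights (ppm): generic, and after a C.

    After a C the G weight is scaled by (1 - cpg_depletion) and the removed
    mass moved to C, which preserves the GC fraction in expectation.
    """
    scale = 1_000_000
    g = int(gc / 2 * scale)
    a = (scale - 2 * g) // 2
    base = [a, g, g, scale - a - 2 * g]  # A, C, G, U
    g_after_c = int(g * (1.0 - cpg_depletion))
    after_c = [a, g + (g - g_after_c), g_after_c, scale - a - 2 * g]
    return base, after_c


def _random_sequence(rng: np.random.Generator, length: int, gc: float,
                     cpg_depletion: float) -> str:
    base, after_c = _composition_weights(gc, cpg_depletion)
    out = []
    prev = ""
    for _ in range(length):
        nt = _draw_nt(rng, after_c if prev == "C" else base)
        out.append(nt)
        prev = nt
    return "".join(out)


def _resolve_length(rng: np.random.Generator, length_dist) -> int:
    if isinstance(length_dist, int):
        return length_dist
    lo, hi = length_dist
    return int(rng.integers(lo, hi + 1))


def generate_utrome(
    n_genes: int,
    length_dist: int | tuple[int, int] = (300, 1200),
    gc: float = 0.45,
    cpg_depletion: float = 0.8,
    rng_seed: int = 0,
) -> tuple[list[UTRRecord], SynthTruth]:
    """Generate a synthetic UTRome with controlled composition.

    ``length_dist`` is a fixed length or an inclusive (low, high) range.
    Defaults emulate mammalian 3'UTRs: moderately AU-rich (GC 0.45) and
    strongly CpG-depleted.  Records of length >= 500 are resampled until
    their GC fraction is within +-5% of the target.
    """
    if n_genes < 0:
        raise SeedsafeError("n_genes must be >= 0")
    if not (0.0 <= gc <= 1.0 and 0.0 <= cpg_depletion <= 1.0):
        raise SeedsafeError("gc and cpg_depletion must lie in [0, 1]")
    if gc > 0.95 and cpg_depletion > 0.95:
        raise SeedsafeError(
            "infeasible composition: gc and cpg_depletion cannot both approach 1"
        )
    rng = np.random.default_rng(rng_seed)
    records: list[UTRRecord] = []
    offset = 0
    for i in range(n_genes):
        length = _resolve_length(rng, length_dist)
        for _ in range(_MAX_RETRIES):
            seq = _random_sequence(rng, length, gc, cpg_depletion)
            if length < 500:
                break
            obs_gc = (seq.count("G") + seq.count("C")) / length
            if abs(obs_gc - gc) <= 0.045:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise SeedsafeError(f"could not achieve GC {gc} for record {i}")
        records.append(
            UTRRecord(
                gene_id=f"G{i:04d}",
                transcript_id=f"T{i:04d}",
                sequence=seq,
                genomic=("chrS", offset, offset + length, "+"),
            )
        )
        offset += length + 100
    truth = SynthTruth(
        rng_seed=rng_seed,
        params={
            "n_genes": n_genes, "length_dist": length_dist,
            "gc": gc, "cpg_depletion": cpg_depletion,
        },
    )
    return records, truth


# ---------------------------------------------------------------------------
# site planting
# ---------------------------------------------------------------------------

def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _mutate_away(seq: list[str], idx: int, rng: np.random.Generator,
                 forbidden: str | None = None) -> None:
    """Replace seq[idx] with a different nucleotide (optionally avoiding one)."""
    choices = [n for n in _NTS if n != seq[idx] and n != forbidden]
    seq[idx] = choices[int(rng.integers(0, len(choices)))]


def _core_span_of_plant(kind: str, span: tuple[int, int]) -> tuple[int, int] | None:
    """1-based span of the 6-nt seed core inside a planted canonical motif."""
    s, e = span
    if kind == "8mer":
        return (s + 1, e - 1)
    if kind == "7mer-m8":
        return (s + 1, e)
    if kind == "7mer-A1":
        return (s, e - 1)
    if kind == "6mer":
        return (s, e)
    return None  # relaxed plants carry no intact core


def _decontaminate_core(
    seq: list[str],
    core: str,
    protected: list[tuple[int, int]],
    allowed_core_spans: set[tuple[int, int]],
    rng: np.random.Generator,
) -> bool:
    """Destroy every unintended occurrence of the 6-nt seed core.

    Every canonical site type contains the seed core, so removing stray core
    occurrences removes all stray canonical sites.  Only occurrences exactly
    at a planted core span are left alone; occurrences merely overlapping a
    planted motif are scrubbed at their unprotected positions.  Returns False
    if an occurrence cannot be touched without damaging a protected span.
    """
    for _ in range(_MAX_RETRIES):
        text = "".join(seq)
        dirty = False
        start = text.find(core)
        while start != -1:
            span = (start + 1, start + len(core))
            if span not in allowed_core_spans:
                free = [
                    i for i in range(start, start + len(core))
                    if not any(p[0] - 1 <= i <= p[1] - 1 for p in protected)
                ]
                if not free:
                    return False
                _mutate_away(seq, free[int(rng.integers(0, len(free)))], rng)
                dirty = True
            start = text.find(core, start + 1)
        if not dirty:
            return True
    return False


def _relaxed_motif(guide: Guide, seed_length: int, mismatch_position: int,
                   rng: np.random.Generator) -> str:
    """Target window complementary to the L-seed except at one guide position.

    The substituted target base forms a true (non-Watson-Crick, non-wobble)
    mismatch with the guide nucleotide, so the window stays invisible to the
    canonical scan.
    """
    if seed_length not in (6, 7, 8):
        raise SeedsafeError("seed_length must be 6, 7 or 8")
    if not (2 <= mismatch_position <= seed_length + 1):
        raise SeedsafeError(
            f"mismatch position {mismatch_position} outside seed 2..{seed_length + 1}"
        )
    core = revcomp(guide.sequence[1 : seed_length + 1])
    idx = seed_length - 1 - (mismatch_position - 2)
    g = guide.sequence[mismatch_position - 1]
    bad = {COMPLEMENT[g]}
    if g in "GU":  # avoid creating a wobble, which scan_relaxed counts as GU
        bad.add("U" if g == "G" else "G")
    choices = [n for n in _NTS if n not in bad]
    sub = choices[int(rng.integers(0, len(choices)))]
    return core[:idx] + sub + core[idx + 1 :]


def plant_sites(
    utrome: Sequence[UTRRecord],
    guide: Guide,
    spec: Sequence[tuple],
    rng_seed: int = 0,
    margin: int = 30,
) -> tuple[list[UTRRecord], SynthTruth]:
    """Plant seed sites into a UTRome and scrub everything else.

    ``spec`` entries are (gene_id, kind) with kind either a canonical site
    type ("8mer", "7mer-m8", "7mer-A1", "6mer") or a tuple
    ("relaxed", seed_length, mismatch_guide_position).  Motifs are written at
    randomized non-overlapping positions at least ``margin`` nt from either
    UTR end; the background is then re-sampled so the canonical scan finds
    exactly the planted canonical sites and nothing else.
    """
    rng = np.random.default_rng(rng_seed)
    motifs = canonical_motifs(guide)
    core6 = motifs["6mer"]
    by_gene: dict[str, list[tuple]] = {}
    for gene_id, kind in spec:
        by_gene.setdefault(gene_id, []).append(kind)

    out: list[UTRRecord] = []
    planted: list[PlantedSite] = []
    for utr in utrome:
        requests = by_gene.get(utr.gene_id, [])
        last_error = None
        for _attempt in range(50):
            try:
                new_utr, gene_plants = _plant_into_utr(
                    utr, guide, requests, motifs, core6, margin, rng
                )
            except SeedsafeError as exc:
                last_error = exc
                continue
            # definitive per-UTR check: the canonical scan sees exactly the
            # planted canonical sites
            found = {(s.local_span, s.site_type)
                     for s in scan_canonical(guide, new_utr, include_6mer=True)}
            want = {(p.local_span, p.kind) for p in gene_plants if p.kind != "relaxed"}
            if found == want:
                break
        else:
            raise SeedsafeError(
                f"could not build fixture for {utr.transcript_id}: {last_error}"
            )
        out.append(new_utr)
        planted.extend(gene_plants)

    _verify_no_contamination(out, guide, planted)
    truth = SynthTruth(rng_seed=rng_seed, planted=planted,
                       params={"guide": guide.sequence, "margin": margin})
    return out, truth


def _plant_into_utr(
    utr: UTRRecord,
    guide: Guide,
    requests: Sequence,
    motifs: Mapping[str, str],
    core6: str,
    margin: int,
    rng: np.random.Generator,
) -> tuple[UTRRecord, list[PlantedSite]]:
    """One placement + scrub attempt for a single UTR (may raise)."""
    seq = list(utr.sequence)
    protected: list[tuple[int, int]] = []
    allowed_cores: set[tuple[int, int]] = set()
    guards: list[tuple[int, str]] = []  # (0-based index, forbidden nt)
    gene_plants: list[PlantedSite] = []
    for kind in requests:
        if isinstance(kind, str):
            motif = motifs.get(kind)
            if motif is None:
                raise SeedsafeError(f"unknown site kind {kind!r}")
            seed_length, mm_pos = None, None
        else:
            tag, seed_length, mm_pos = kind
            if tag != "relaxed":
                raise SeedsafeError(f"unknown site kind {kind!r}")
            motif = _relaxed_motif(guide, seed_length, mm_pos, rng)
        lo = margin + 1
        hi = len(seq) - margin - len(motif) + 1
        if hi < lo:
            raise SeedsafeError(
                f"UTR {utr.transcript_id} too short to plant {kind} with margin {margin}"
            )
        for _ in range(_MAX_RETRIES):
            start = int(rng.integers(lo, hi + 1))  # 1-based
            span = (start, start + len(motif) - 1)
            guard_zone = (span[0] - 1, span[1] + 1)
            if not any(_spans_overlap(guard_zone, p) for p in protected):
                break
        else:
            raise SeedsafeError(
                f"could not place {kind} in {utr.gene_id} after {_MAX_RETRIES} tries"
            )
        seq[start - 1 : start - 1 + len(motif)] = list(motif)
        # guard nucleotides so a planted weaker type cannot upgrade: an
        # upstream complement of guide position 8 adds the m8 pairing, a
        # downstream A adds the A1 anchor
        if isinstance(kind, str):
            core = _core_span_of_plant(kind, span)
            allowed_cores.add(core)
            if kind in ("7mer-A1", "6mer"):
                guards.append((core[0] - 2, COMPLEMENT[guide.sequence[7]]))
            if kind in ("7mer-m8", "6mer"):
                guards.append((core[1], "A"))
        protected.append(span)
        gene_plants.append(
            PlantedSite(
                gene_id=utr.gene_id,
                transcript_id=utr.transcript_id,
                kind=kind if isinstance(kind, str) else "relaxed",
                local_span=span,
                motif=motif,
                seed_length=seed_length,
                mismatch_position=mm_pos,
            )
        )
    # decontaminate and re-apply guard nucleotides until both are stable
    # (a scrub mutation could otherwise recreate an upgrading neighbor)
    for _ in range(_MAX_RETRIES):
        if not _decontaminate_core(seq, core6, protected, allowed_cores, rng):
            raise SeedsafeError(
                f"could not decontaminate {utr.transcript_id}"
            )
        fixed = False
        for idx, forbidden in guards:
            if 0 <= idx < len(seq) and seq[idx] == forbidden:
                _mutate_away(seq, idx, rng, forbidden=forbidden)
                fixed = True
        if not fixed:
            break
    new_utr = UTRRecord(utr.gene_id, utr.transcript_id, "".join(seq), utr.genomic)
    return new_utr, gene_plants


def _verify_no_contamination(utrome: Sequence[UTRRecord], guide: Guide,
                             planted: Sequence[PlantedSite]) -> None:
    """Assert the no-contamination guarantee by brute rescan."""
    planted_canonical = {
        (p.transcript_id, p.local_span): p.kind
        for p in planted if p.kind != "relaxed"
    }
    for utr in utrome:
        for site in scan_canonical(guide, utr, include_6mer=True):
            key = (utr.transcript_id, site.local_span)
            if planted_canonical.get(key) != site.site_type:
                raise SeedsafeError(
                    f"contamination: unplanned {site.site_type} at "
                    f"{utr.transcript_id}:{site.local_span}"
                )


# ---------------------------------------------------------------------------
# expression / orthologs / species trio
# ---------------------------------------------------------------------------

def generate_expression_set(
    utrome: Sequence[UTRRecord],
    fraction: float = 0.8,
    species: str = "mouse",
    rng_seed: int = 0,
    include: Iterable[str] = (),
) -> ExpressionSet:
    """Mark a random fraction of genes as expressed (plus forced inclusions)."""
    rng = np.random.default_rng(rng_seed)
    genes = sorted({u.gene_id for u in utrome})
    n = int(round(fraction * len(genes)))
    idx = rng.permutation(len(genes))[:n]
    chosen = {genes[i] for i in idx} | set(include)
    return ExpressionSet(species=species, gene_ids=frozenset(chosen))


def generate_species_trio(
    base_utrome: Sequence[UTRRecord],
    base_truth: SynthTruth,
    guide: Guide,
    conservation_spec: Mapping[str, Iterable[str]],
    rng_seed: int = 0,
) -> tuple[dict[str, list[UTRRecord]], dict[tuple[str, str], OrthologMap], SynthTruth]:
    """Derive three species' UTRomes from one planted base fixture.

    ``conservation_spec`` maps a base gene id to the species (subset of
    human/mouse/rhesus) in which its planted site survives; in the other
    species the site is destroyed by a single substitution inside the seed
    match.  Gene ids are species-prefixed; ortholog maps connect every
    species pair and invert losslessly.
    """
    rng = np.random.default_rng(rng_seed)
    core6 = canonical_motifs(guide)["6mer"]
    planted_by_gene: dict[str, list[PlantedSite]] = {}
    for p in base_truth.planted:
        planted_by_gene.setdefault(p.gene_id, []).append(p)

    utromes: dict[str, list[UTRRecord]] = {}
    truths: list[PlantedSite] = []
    for sp in SPECIES:
        records = []
        for utr in base_utrome:
            keep = sp in set(conservation_spec.get(utr.gene_id, SPECIES))
            kept_plants = planted_by_gene.get(utr.gene_id, []) if keep else []
            want = {(p.local_span, p.kind) for p in kept_plants if p.kind != "relaxed"}
            for _attempt in range(50):
                seq = list(utr.sequence)
                protected = []
                allowed = set()
                for p in planted_by_gene.get(utr.gene_id, []):
                    if keep:
                        protected.append(p.local_span)
                        core = _core_span_of_plant(p.kind, p.local_span)
                        if core is not None:
                            allowed.add(core)
                    else:
                        s, e = p.local_span
                        idx = s - 1 + int(rng.integers(0, e - s + 1))
                        _mutate_away(seq, idx, rng)
                if not _decontaminate_core(seq, core6, protected, allowed, rng):
                    continue
                rec = UTRRecord(
                    gene_id=f"{sp}:{utr.gene_id}",
                    transcript_id=f"{sp}:{utr.transcript_id}",
                    sequence="".join(seq),
                    genomic=utr.genomic,
                )
                found = {(s2.local_span, s2.site_type)
                         for s2 in scan_canonical(guide, rec, include_6mer=True)}
                if found == want:
                    break
            else:
                raise SeedsafeError(f"decontamination failed for {sp}:{utr.gene_id}")
            records.append(rec)
            for p in kept_plants:
                truths.append(
                    PlantedSite(rec.gene_id, rec.transcript_id, p.kind,
                                p.local_span, p.motif, p.seed_length,
                                p.mismatch_position)
                )
        utromes[sp] = records

    maps: dict[tuple[str, str], OrthologMap] = {}
    genes = sorted({u.gene_id for u in base_utrome})
    for a in SPECIES:
        for b in SPECIES:
            if a < b:
                maps[(a, b)] = OrthologMap(
                    {f"{a}:{g}": frozenset({f"{b}:{g}"}) for g in genes}
                )
    conserved_all = sorted(
        g for g, sps in conservation_spec.items() if set(sps) == set(SPECIES)
    )
    truth = SynthTruth(rng_seed=rng_seed, planted=truths,
                       params={"conservation_spec": {k: sorted(v) for k, v in conservation_spec.items()}},
                       conserved_genes=conserved_all)
    return utromes, maps, truth


# ---------------------------------------------------------------------------
# transcript models for retargeting
# ---------------------------------------------------------------------------

def generate_transcript_model(
    seed: str,
    n_exons: int = 8,
    exon_length: tuple[int, int] = (120, 300),
    utr5_length: int = 150,
    utr3_length: int = 400,
    plants: Sequence[Mapping] = (),
    gc: float = 0.45,
    cpg_depletion: float = 0.8,
    rng_seed: int = 0,
    transcript_id: str = "TX0001",
) -> tuple[TranscriptModel, SynthTruth]:
    """A spliced transcript with planted (<=1 mismatch) seed-complement windows.

    ``plants`` entries: {"mismatch_position": 2-7 or None,
    "region": "5utr"|"cds"|"3utr", "junction": bool}.  A junction plant is
    placed straddling an internal exon boundary inside the CDS.  The
    background is scrubbed of every other window within one mismatch of the
    seed complement, so retarget scans recover exactly the planted windows;
    the guarantee is verified by brute rescan, resampling the whole model
    (deterministically) if a rare placement cannot be scrubbed cleanly.
    """
    if len(seed) != 6:
        raise SeedsafeError("seed must be a hexamer")
    rng = np.random.default_rng(rng_seed)
    last_error: Exception | None = None
    for _attempt in range(50):
        try:
            model, truth = _transcript_model_once(
                seed, n_exons, exon_length, utr5_length, utr3_length,
                plants, gc, cpg_depletion, rng, transcript_id,
            )
        except SeedsafeError as exc:
            last_error = exc
            continue
        if _verify_transcript_truth(seed, model, truth):
            truth.rng_seed = rng_seed
            return model, truth
    raise SeedsafeError(
        f"transcript-model generation did not converge: {last_error}"
    )


def _verify_transcript_truth(seed: str, model: TranscriptModel,
                             truth: SynthTruth) -> bool:
    """Brute rescan: exactly the planted windows lie within one defect."""
    target = revcomp(seed)
    planted = {p.local_span: p.mismatch_position for p in truth.planted}
    seq = model.sequence
    for start in range(len(seq) - 5):
        window = seq[start : start + 6]
        defects = sum(1 for a, b in zip(window, target) if a != b)
        span = (start + 1, start + 6)
        if defects <= 1:
            if span not in planted:
                return False
            expected = 0 if planted[span] is None else 1
            if defects != expected:
                return False
    return True


def _transcript_model_once(
    seed: str,
    n_exons: int,
    exon_length: tuple[int, int],
    utr5_length: int,
    utr3_length: int,
    plants: Sequence[Mapping],
    gc: float,
    cpg_depletion: float,
    rng: np.random.Generator,
    transcript_id: str,
) -> tuple[TranscriptModel, SynthTruth]:
    exon_lens = [int(rng.integers(exon_length[0], exon_length[1] + 1)) for _ in range(n_exons)]
    total = sum(exon_lens)
    if total <= utr5_length + utr3_length + 50:
        raise SeedsafeError("exons too short for the requested UTR lengths")
    exon_ends = tuple(np.cumsum(exon_lens).tolist())
    cds_span = (utr5_length + 1, total - utr3_length)
    seq = list(_random_sequence(rng, total, gc, cpg_depletion))

    planted: list[PlantedSite] = []
    protected: list[tuple[int, int]] = []
    region_spans = {
        "5utr": (1, cds_span[0] - 1),
        "cds": cds_span,
        "3utr": (cds_span[1] + 1, total),
    }
    pseudo_guide = Guide(name="seedcarrier", sequence="U" + seed + "A" * 15)
    for plant in plants:
        mm_pos = plant.get("mismatch_position")
        region = plant.get("region", "3utr")
        junction = bool(plant.get("junction", False))
        if mm_pos is None:
            motif = revcomp(seed)
        else:
            motif = _relaxed_motif(pseudo_guide, 6, mm_pos, rng)
        lo, hi = region_spans[region]
        lo = max(lo, 25)
        hi = min(hi, total - 25) - 5
        if junction:
            internal = [b for b in exon_ends[:-1] if lo + 2 <= b <= hi + 2]
            if not internal:
                raise SeedsafeError(f"no exon boundary available in region {region}")
            b = internal[int(rng.integers(0, len(internal)))]
            start = b - 2  # boundary strictly inside the 6-nt span
        else:
            for _ in range(_MAX_RETRIES):
                start = int(rng.integers(lo, hi + 1))
                span = (start, start + 5)
                if not any(_spans_overlap((span[0] - 1, span[1] + 1), p) for p in protected) \
                        and not any(start <= bnd < start + 5 for bnd in exon_ends[:-1]):
                    break
            else:
                raise SeedsafeError("could not place retarget plant")
        span = (start, start + 5)
        seq[start - 1 : start + 5] = list(motif)
        protected.append(span)
        planted.append(
            PlantedSite("", transcript_id, "retarget", span, motif,
                        seed_length=6, mismatch_position=mm_pos)
        )

    # scrub background windows within 1 defect of the seed complement
    target = revcomp(seed)
    for _ in range(_MAX_RETRIES):
        dirty = False
        text = "".join(seq)
        for start in range(len(text) - 5):
            span = (start + 1, start + 6)
            if any(_spans_overlap(span, p) for p in protected):
                continue
            window = text[start : start + 6]
            defects = sum(1 for a, b in zip(window, target) if a != b)
            if defects <= 1:
                free = [
                    i for i in range(start, start + 6)
                    if not any(p[0] - 1 <= i <= p[1] - 1 for p in protected)
                ]
                if not free:
                    raise SeedsafeError("cannot scrub window without damaging a plant")
                # push to >=2 defects in one pass where possible
                for i in free[:2]:
                    _mutate_away(seq, i, rng, forbidden=target[i - start])
                dirty = True
        if not dirty:
            break
    else:
        raise SeedsafeError("background scrub did not converge")

    model = TranscriptModel(
        transcript_id=transcript_id,
        sequence="".join(seq),
        exon_ends=exon_ends,
        cds_span=cds_span,
    )
    truth = SynthTruth(
        rng_seed=-1,  # the public wrapper records the caller's seed
        planted=planted,
        params={"seed": seed, "n_exons": n_exons, "cds_span": cds_span},
    )
    return model, truth
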
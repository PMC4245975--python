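"""Domain types, alphabet handling and file readers/writers.

Everything downstream works on RNA-alphabet strings (A, C, G, U).  DNA input
is accepted everywhere and converted on the way in, because 3'UTR FASTA files
are DNA-alphabet.  Local coordinates are 1-based inclusive throughout the
library; genomic intervals follow the BED convention (0-based half-open) and
are converted only at the report boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger("seedsafe")

RNA_ALPHABET = frozenset("ACGU")
COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

#: accepted guide lengths (nt); typical artificial-miRNA guides are 21-22 nt
GUIDE_LENGTH_BOUNDS = (16, 30)


class SeedsafeError(ValueError):
    """Input or contract violation; maps to a distinct CLI exit code."""


def normalize_sequence(raw: str, expect: str = "auto") -> str:
    """Uppercase, convert T->U and validate against the RNA alphabet.

    ``expect`` may be "DNA", "RNA" or "auto"; it only affects the error
    message, the conversion is identical.  Ambiguity codes are rejected with
    the offending character and its 1-based position.
    """
    if not raw:
        raise SeedsafeError("empty sequence")
    seq = raw.strip().upper().replace("T", "U")
    for i, ch in enumerate(seq, start=1):
        if ch not in RNA_ALPHABET:
            raise SeedsafeError(
                f"invalid nucleotide {ch!r} at position {i} (expected {expect} alphabet)"
            )
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return "".join(COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class Guide:
    """A guide-strand RNA, 5'->3', with 1-based position indexing.

    Position 1 is the 5'-most nucleotide of the loaded strand.  The seed is
    positions 2-7 (hexamer); the extended seed is 2-8.
    """

    name: str
    sequence: str
    seed_span: tuple[int, int] = (2, 7)
    extended_seed_span: tuple[int, int] = (2, 8)

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence, expect="RNA")
        object.__setattr__(self, "sequence", seq)
        lo, hi = GUIDE_LENGTH_BOUNDS
        if not lo <= len(seq) <= hi:
            raise SeedsafeError(
                f"guide {self.name!r}: length {len(seq)} outside bounds [{lo}, {hi}]"
            )
        for span in (self.seed_span, self.extended_seed_span):
            if span[0] < 1 or span[1] > len(seq) or span[0] > span[1]:
                raise SeedsafeError(f"guide {self.name!r}: span {span} outside sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def at(self, pos: int) -> str:
        """Nucleotide at a 1-based position."""
        if not 1 <= pos <= len(self.sequence):
            raise SeedsafeError(f"position {pos} outside guide {self.name!r}")
        return self.sequence[pos - 1]

    @property
    def seed(self) -> str:
        a, b = self.seed_span
        return self.sequence[a - 1 : b]


@dataclass(frozen=True)
class UTRRecord:
    """One 3'UTR sequence in spliced-transcript orientation.

    ``genomic`` is an optional (chrom, start, end, strand) tuple with a
    0-based half-open interval; when present its length must equal the
    sequence length.  Minus-strand UTRs keep the transcript-orientation
    sequence; the genomic interval is retained for deduplication only.
    """

    gene_id: str
    transcript_id: str
    sequence: str
    genomic: tuple[str, int, int, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.genomic is not None:
            chrom, start, end, strand = self.genomic
            if strand not in {"+", "-"}:
                raise SeedsafeError(
                    f"{self.transcript_id}: strand {strand!r} not in {{+,-}}"
                )
            if end - start != len(self.sequence):
                raise SeedsafeError(
                    f"{self.transcript_id}: genomic interval length {end - start} "
                    f"!= sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExpressionSet:
    """Set of gene ids expressed above background in one tissue/species."""

    species: str
    gene_ids: frozenset[str]

    def __contains__(self, gene_id: str) -> bool:
        return normalize_gene_id(gene_id) in self.gene_ids

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class OrthologMap:
    """Gene-to-gene correspondence between two species.

    ``pairs`` maps a species-A gene id to the (non-empty) set of species-B
    orthologs.  The map inverts losslessly.
    """

    pairs: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for a, bs in self.pairs.items():
            if not bs:
                raise SeedsafeError(f"ortholog map: empty target set for {a!r}")

    def reverse(self) -> "OrthologMap":
        rev: dict[str, set[str]] = {}
        for a, bs in self.pairs.items():
            for b in bs:
                rev.setdefault(b, set()).add(a)
        return OrthologMap({b: frozenset(av) for b, av in rev.items()})

    def get(self, gene_id: str) -> frozenset[str]:
        return self.pairs.get(normalize_gene_id(gene_id), frozenset())


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced mRNA with exon structure and CDS bounds.

    ``exon_ends`` are cumulative 1-based spliced coordinates of exon 3' ends
    (strictly increasing; the last equals the sequence length).  ``cds_span``
    is 1-based inclusive; the 3'UTR is everything after it.
    """

    transcript_id: str
    sequence: str
    exon_ends: tuple[int, ...]
    cds_span: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        n = len(self.sequence)
        if list(self.exon_ends) != sorted(set(self.exon_ends)):
            raise SeedsafeError(
                f"{self.transcript_id}: exon boundaries must be strictly increasing"
            )
        if self.exon_ends and self.exon_ends[-1] != n:
            raise SeedsafeError(
                f"{self.transcript_id}: last exon end {self.exon_ends[-1]} != length {n}"
            )
        a, b = self.cds_span
        if not (1 <= a <= b <= n):
            raise SeedsafeError(f"{self.transcript_id}: cds_span {self.cds_span} outside sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def utr5_span(self) -> tuple[int, int] | None:
        return (1, self.cds_span[0] - 1) if self.cds_span[0] > 1 else None

    @property
    def utr3_span(self) -> tuple[int, int] | None:
        n = len(self.sequence)
        return (self.cds_span[1] + 1, n) if self.cds_span[1] < n else None


# ---------------------------------------------------------------------------
# id normalization
# ---------------------------------------------------------------------------

def normalize_gene_id(gene_id: str) -> str:
    """Exact-match normalization: strip a trailing version suffix (".N").

    RefSeq/Ensembl ids drift in version between annotation snapshots; the
    unversioned accession is the stable join key.
    """
    base, dot, suffix = gene_id.rpartition(".")
    if dot and suffix.isdigit():
        return base
    return gene_id


def flag_noncoding_ids(ids: Iterable[str]) -> list[str]:
    """Return ids that do not look like protein-coding RefSeq accessions.

    Off-target prediction is usually restricted to NM_-prefixed transcripts;
    by default non-NM ids are only flagged (logged), not rejected.
    """
    flagged = [i for i in ids if i.startswith(("NR_", "XR_"))]
    if flagged:
        logger.warning("%d non-protein-coding (non-NM) transcript ids", len(flagged))
    return flagged


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an order-preserving list of (name, sequence).

    Sequences are normalized to RNA.  Duplicate record names are rejected.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeedsafeError(f"{path}: duplicate FASTA record name {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, normalize_sequence(str(rec.seq))))
    if not records:
        logger.warning("%s: empty FASTA file", path)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (name, sequence) pairs as wrapped FASTA (60 columns)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_utr_table(bed_path: str | Path, fasta_path: str | Path) -> list[UTRRecord]:
    """Join a BED6 interval table with a transcript-keyed FASTA into UTRRecords.

    BED name field is ``gene_id|transcript_id``.  Rows lacking a FASTA
    sequence are dropped with a logged count; an interval length that
    disagrees with its sequence length is a hard error.
    """
    seqs = dict(read_fasta(fasta_path))
    records: list[UTRRecord] = []
    dropped = 0
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise SeedsafeError(f"{bed_path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                gene_id, transcript_id = name.split("|", 1)
            except ValueError:
                raise SeedsafeError(
                    f"{bed_path}:{lineno}: name field {name!r} is not gene_id|transcript_id"
                ) from None
            seq = seqs.get(transcript_id)
            if seq is None:
                dropped += 1
                continue
            start_i, end_i = int(start), int(end)
            if end_i - start_i != len(seq):
                raise SeedsafeError(
                    f"{bed_path}:{lineno}: interval length {end_i - start_i} != sequence "
                    f"length {len(seq)} for {transcript_id}"
                )
            records.append(
                UTRRecord(gene_id, transcript_id, seq, (chrom, start_i, end_i, strand))
            )
    if dropped:
        logger.warning("read_utr_table: dropped %d BED rows without a FASTA sequence", dropped)
    flag_noncoding_ids(r.transcript_id for r in records)
    return records


def read_gene_set(path: str | Path, species: str = "") -> ExpressionSet:
    """Read a one-id-per-line expressed-gene list (deduplicated)."""
    ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            if any(c.isspace() for c in token):
                raise SeedsafeError(f"{path}:{lineno}: expected one id per line")
            ids.add(normalize_gene_id(token))
    if not ids:
        logger.warning("%s: empty gene set", path)
    return ExpressionSet(species=species, gene_ids=frozenset(ids))


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV of (species-A id, species-B id) pairs."""
    pairs: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(fields):
                raise SeedsafeError(f"{path}:{lineno}: expected two tab-separated ids")
            a, b = (normalize_gene_id(f) for f in fields)
            pairs.setdefault(a, set()).add(b)
    return OrthologMap({a: frozenset(bs) for a, bs in pairs.items()})


def write_gene_set(expr: ExpressionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(expr.gene_ids):
            fh.write(gid + "\n")


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in sorted(omap.pairs):
            for b in sorted(omap.pairs[a]):
                fh.write(f"{a}\t{b}\n")


def write_utr_table(records: Iterable[UTRRecord], bed_path: str | Path, fasta_path: str | Path) -> None:
    """Write UTRRecords as the BED6 + FASTA pair accepted by read_utr_table."""
    records = list(records)
    with open(bed_path, "w") as fh:
        for r in records:
            chrom, start, end, strand = r.genomic if r.genomic else ("na", 0, len(r), "+")
            fh.write(f"{chrom}\t{start}\t{end}\t{r.gene_id}|{r.transcript_id}\t0\t{strand}\n")
    write_fasta(((r.transcript_id, r.sequence) for r in records), fasta_path)
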
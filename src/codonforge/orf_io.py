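"""Sequence input and the ORF curation chain.

Reads genome/CDS sequences from FASTA or GenBank, calls open reading
frames de novo on both strands, and applies the curation filters that
define the analyzable ORF set:

1. short ORFs (< 350 nt including the stop codon) are removed;
2. nontranslatable ORFs (a codon containing a non-ACGT symbol, or an
   internal stop) are removed — a single terminal stop is legitimate and
   is trimmed by the metric layer, not a rejection;
3. ORFs whose sense codons all belong to single-codon families (no
   synonymous codons, so RSCU/ENC are undefined) are removed;
4. within a genome, overlapping ORFs conflict and only one is kept
   (longest first; ties broken by leftmost start, then id).

Coordinates are 0-based half-open on the forward strand internally;
human-facing reports use 1-based inclusive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .genetic_code import STOP, GeneticCode

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Malformed FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One input nucleotide sequence, normalized to uppercase DNA."""

    id: str
    description: str
    seq: str


@dataclass(frozen=True)
class ORFRecord:
    """One open reading frame.

    start/end are 0-based half-open on the forward strand of the parent
    genome; seq is in reading-frame orientation (reverse-complemented for
    strand ``-``).
    """

    id: str
    genome_id: str
    start: int
    end: int
    strand: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FilterReport:
    """Per-stage accounting of the curation chain; conserves every input ORF."""

    input: int = 0
    removed_short: int = 0
    removed_overlap: int = 0
    removed_nontranslatable: int = 0
    removed_no_synonymous: int = 0
    retained: int = 0

    def check(self) -> None:
        removed = (self.removed_short + self.removed_overlap
                   + self.removed_nontranslatable + self.removed_no_synonymous)
        if self.input - removed != self.retained:
            raise AssertionError(f"filter report does not conserve ORFs: {self}")

    def to_dict(self) -> dict[str, int]:
        return {
            "input": self.input,
            "removed_short": self.removed_short,
            "removed_overlap": self.removed_overlap,
            "removed_nontranslatable": self.removed_nontranslatable,
            "removed_no_synonymous": self.removed_no_synonymous,
            "retained": self.retained,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            for k, v in self.to_dict().items():
                fh.write(f"{k}\t{v}\n")


def normalize_seq(raw: str, *, context: str = "") -> str:
    """Uppercase, U->T; reject symbols outside A/C/G/T/N."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise FastaParseError(
            f"illegal sequence character(s) {sorted(bad)} in {context or 'input'}"
        )
    return seq


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects."""
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if first and not first.startswith(">"):
            raise FastaParseError(f"{path}: not FASTA (first line is not a header)")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(
            id=rec.id,
            description=rec.description,
            seq=normalize_seq(str(rec.seq), context=f"record {rec.id!r}"),
        ))
    if not records:
        logger.warning("%s: empty FASTA, no records read", path)
    return records


def write_fasta(orfs: Iterable[ORFRecord | SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in orfs:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_orf_fasta(path, genome_id: str | None = None) -> list[ORFRecord]:
    """Read a FASTA of already-extracted ORFs (coordinates unknown)."""
    out = []
    for i, rec in enumerate(read_fasta(path)):
        out.append(ORFRecord(
            id=rec.id, genome_id=genome_id or rec.id.rsplit("_orf", 1)[0],
            start=0, end=len(rec.seq), strand="+", seq=rec.seq,
        ))
    return out


def read_genbank_cds(path) -> list[ORFRecord]:
    """Extract CDS features from a GenBank flat file as ORF records.

    Non-pseudo CDS only; ``join()`` splices and ``complement()`` strands
    are resolved by Biopython's feature extraction. Features with
    coordinates outside the sequence are skipped with a warning.
    """
    orfs: list[ORFRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        n = 0
        for feat in rec.features:
            if feat.type != "CDS" or "pseudo" in feat.qualifiers:
                continue
            n += 1
            try:
                start = int(feat.location.start)
                end = int(feat.location.end)
                if start < 0 or end > len(rec.seq):
                    raise ValueError("coordinates outside sequence")
                sub = feat.extract(rec.seq)
            except Exception as exc:  # malformed feature: skip, keep going
                logger.warning("%s: skipping CDS %d (%s)", rec.id, n, exc)
                continue
            strand = "-" if feat.location.strand == -1 else "+"
            name = feat.qualifiers.get("locus_tag", feat.qualifiers.get(
                "protein_id", [f"{rec.id}_cds{n}"]))[0]
            orfs.append(ORFRecord(
                id=name, genome_id=rec.id, start=start, end=end,
                strand=strand,
                seq=normalize_seq(str(sub), context=f"CDS {name!r}"),
            ))
    return orfs


def _scan_frame(seq: str, code: GeneticCode, frame: int) -> list[tuple[int, int]]:
    """Maximal ATG->stop spans (nt offsets into seq) in one forward frame."""
    spans = []
    start = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        aa = code.codon_to_aa.get(codon)
        if aa == STOP:
            if start is not None:
                spans.append((start, i + 3))
                start = None
        elif start is None and codon == "ATG":
            start = i
    return spans


def find_orfs(record: SequenceRecord, code: GeneticCode) -> list[ORFRecord]:
    """Call all maximal start-to-stop ORFs on both strands.

    For each stop codon the most 5' in-frame ATG defines the ORF, so nested
    starts yield a single (longest) ORF. Coordinates are always reported on
    the forward strand; ``seq`` is the reading-frame sequence including the
    stop codon.
    """
    seq = record.seq
    rc = seq.translate(_COMPLEMENT)[::-1]
    n = len(seq)
    found: list[ORFRecord] = []
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            for a, b in _scan_frame(s, code, frame):
                if strand == "+":
                    start, end = a, b
                else:
                    start, end = n - b, n - a
                found.append(ORFRecord(
                    id="", genome_id=record.id, start=start, end=end,
                    strand=strand, seq=s[a:b],
                ))
    found.sort(key=lambda o: (o.start, o.end, o.strand))
    return [
        ORFRecord(id=f"{record.id}_orf{i + 1}", genome_id=o.genome_id,
                  start=o.start, end=o.end, strand=o.strand, seq=o.seq)
        for i, o in enumerate(found)
    ]


def _is_translatable(orf: ORFRecord, code: GeneticCode) -> bool:
    seq = orf.seq
    if len(seq) % 3:
        return False
    last = len(seq) - 3
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if any(b not in "ACGT" for b in codon):
            return False
        if code.codon_to_aa[codon] == STOP and i != last:
            return False
    return True


def _has_synonymous(orf: ORFRecord, code: GeneticCode) -> bool:
    seq = orf.seq
    for i in range(0, len(seq), 3):
        aa = code.codon_to_aa.get(seq[i:i + 3])
        if aa and aa != STOP and len(code.synonymous_families[aa]) > 1:
            return True
    return False


def filter_orfs(orfs: Sequence[ORFRecord], code: GeneticCode,
                min_len: int = 350, min_overlap: int = 1,
                ) -> tuple[list[ORFRecord], FilterReport]:
    """Apply the curation chain; each input ORF is counted exactly once.

    Stages run in order short -> nontranslatable -> no-synonymous ->
    overlap, so an ORF failing an early stage is not re-counted later.
    Overlap resolution is per genome: surviving ORFs are taken longest
    first (ties: leftmost start, then id) and an ORF overlapping an
    already-kept one by >= ``min_overlap`` nt on either strand is dropped.
    """
    report = FilterReport(input=len(orfs))
    survivors: list[ORFRecord] = []
    for orf in orfs:
        if len(orf.seq) < min_len:
            report.removed_short += 1
        elif not _is_translatable(orf, code):
            report.removed_nontranslatable += 1
        elif not _has_synonymous(orf, code):
            report.removed_no_synonymous += 1
        else:
            survivors.append(orf)

    by_genome: dict[str, list[ORFRecord]] = {}
    for orf in survivors:
        by_genome.setdefault(orf.genome_id, []).append(orf)
    kept_ids = set()
    for genome, group in by_genome.items():
        group = sorted(group, key=lambda o: (-len(o.seq), o.start, o.id))
        kept: list[ORFRecord] = []
        for orf in group:
            clash = any(
                min(orf.end, k.end) - max(orf.start, k.start) >= min_overlap
                for k in kept
            )
            if clash:
                report.removed_overlap += 1
            else:
                kept.append(orf)
        kept_ids.update(id(o) for o in kept)

    retained = [o for o in survivors if id(o) in kept_ids]
    report.retained = len(retained)
    report.check()
    dropped = report.input - report.retained
    if dropped:
        logger.info("filter_orfs: removed %d of %d ORFs", dropped, report.input)
    return retained, report
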
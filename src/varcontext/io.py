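"""Input/output layer: reference FASTA access, VCF reading with multiallelic
splitting, BED interval loading, and writers for the annotation table and
extracted sequences.

All genomic coordinates in this package are 1-based and closed unless a
function explicitly says otherwise (BED input is 0-based half-open, as usual).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from intervaltree import IntervalTree

logger = logging.getLogger("varcontext")

DNA_ALPHABET = frozenset("ACGTN")

# Column blocks of the annotation table, in fixed output order.
BASIC_COLUMNS = ("CHROM", "POS", "ID", "REF", "ALT", "GT")
AMBIGUITY_COLUMNS = (
    "FIVE_PRIME_ALIGNED",
    "THREE_PRIME_ALIGNED",
    "THREE_PRIME_EDGE",
    "AMBIGUOUS",
    "IN_DUPLICATE",
)
FLANK_COLUMNS = ("LEFT_FLANK", "RIGHT_FLANK", "REF_REGION", "ALT_REGION")
HGVS_COLUMNS = ("HGVS",)
DISTANCE_COLUMNS = ("DIST_3P_NEXT",)
BED_COLUMNS = ("BED_ANNOTATION",)
TR_COLUMNS = (
    "TR_MOTIF",
    "TR_START",
    "TR_END",
    "TR_COPY_NUMBER",
    "TR_MATCH_PCT",
    "TR_MISMATCH_PCT",
    "TR_GAP_PCT",
    "TR_ALIGNMENT_SCORE",
    "TR_REPEAT_SCORE",
    "TR_GC_PCT",
    "TR_COPY_CHANGE",
)

MISSING = "."


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant as read from a VCF after multiallelic splitting."""

    contig: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alt: str
    vid: str = MISSING
    genotype: str = MISSING

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele in record at {self.contig}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"REF equals ALT at {self.contig}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.pos} on {self.contig}")

    @property
    def end(self) -> int:
        """1-based position of the last REF base."""
        return self.pos + len(self.ref) - 1

    @property
    def has_n(self) -> bool:
        return "N" in self.ref or "N" in self.alt


@dataclass(frozen=True)
class ReferenceSequence:
    """A single reference contig with 1-based random access."""

    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """Base at 1-based ``pos``; empty string outside the contig."""
        if pos < 1 or pos > len(self.seq):
            return ""
        return self.seq[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Bases of the closed 1-based interval [start, end], clipped to the
        contig; empty when the interval is empty or entirely outside."""
        if end < start:
            return ""
        return self.seq[max(start, 1) - 1 : end]


class ReferenceSet(dict):
    """Mapping of contig name -> :class:`ReferenceSequence`."""

    def require(self, contig: str) -> ReferenceSequence:
        try:
            return self[contig]
        except KeyError:
            raise KeyError(
                f"contig {contig!r} not present in the reference FASTA"
            ) from None


def read_fasta(path: str | Path) -> ReferenceSet:
    """Load all contigs of a FASTA file (indexed on the fly by pysam)."""
    refs = ReferenceSet()
    with pysam.FastaFile(str(path)) as fa:
        for name in fa.references:
            refs[name] = ReferenceSequence(name=name, seq=fa.fetch(name).upper())
    return refs


@dataclass(frozen=True)
class BedInterval:
    """One BED interval; ``start`` is 0-based, ``end`` half-open."""

    contig: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty BED interval {self.contig}:{self.start}-{self.end}")


def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Load a BED file (3+ columns) into per-contig interval trees.

    Malformed lines are skipped with a warning. The fourth column, when
    present, is used as the annotation label; otherwise the interval's own
    coordinates serve as the label.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            try:
                contig, start, end = fields[0], int(fields[1]), int(fields[2])
                label = fields[3] if len(fields) > 3 else f"{contig}:{start}-{end}"
                iv = BedInterval(contig, start, end, label)
            except (IndexError, ValueError) as exc:
                logger.warning("skipping malformed BED line %d: %s (%s)", lineno, line, exc)
                continue
            trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, iv.label)
    return trees


def _genotype_string(
    indices: Sequence[int | None] | None, phased: bool, kept_alt: int
) -> str:
    """Remap a genotype tuple after splitting out ALT number ``kept_alt``.

    The kept ALT becomes allele 1, the reference stays 0, and every other
    ALT index becomes missing; the phase separator is preserved.
    """
    if not indices:
        return MISSING
    sep = "|" if phased else "/"
    out = []
    for a in indices:
        if a is None:
            out.append(MISSING)
        elif a == 0:
            out.append("0")
        elif a == kept_alt:
            out.append("1")
        else:
            out.append(MISSING)
    return sep.join(out)


def split_multiallelic(
    contig: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    vid: str = MISSING,
    gt_indices: Sequence[int | None] | None = None,
    phased: bool = False,
) -> list[VariantRecord]:
    """Expand a raw (possibly multi-ALT) VCF record into biallelic records.

    CHROM/POS/REF/ID are shared by the outputs; the genotype of each output
    keeps only the alleles relevant to its ALT (see :func:`_genotype_string`).
    An empty ALT list yields an empty output.
    """
    records = []
    for k, alt in enumerate(alts, start=1):
        records.append(
            VariantRecord(
                contig=contig,
                pos=pos,
                ref=ref.upper(),
                alt=alt.upper(),
                vid=vid if vid else MISSING,
                genotype=_genotype_string(gt_indices, phased, k),
            )
        )
    return records


def read_vcf(path: str | Path, reference: ReferenceSet) -> Iterator[VariantRecord]:
    """Stream biallelic :class:`VariantRecord` objects from a VCF file.

    Records are emitted in file order; multiallelic records are expanded with
    :func:`split_multiallelic`. Symbolic/breakend ALTs and alleles containing
    characters outside A, C, G, T, N are skipped with a warning. A contig
    missing from the FASTA or a REF allele that does not match the reference
    is fatal (the latter signals annotation against the wrong build).
    """
    with pysam.VariantFile(str(path)) as vcf:
        for nrec, rec in enumerate(vcf, start=1):
            if rec.chrom not in reference:
                raise ValueError(
                    f"record {nrec} ({rec.chrom}:{rec.pos}): contig {rec.chrom!r} "
                    "absent from the reference FASTA"
                )
            refseq = reference[rec.chrom]
            if rec.ref is None or rec.alts is None:
                logger.warning(
                    "skipping record %d (%s:%d): missing REF or ALT", nrec, rec.chrom, rec.pos
                )
                continue
            ref = rec.ref.upper()
            if set(ref) - DNA_ALPHABET:
                logger.warning(
                    "skipping record %d (%s:%d): non-DNA REF %r", nrec, rec.chrom, rec.pos, rec.ref
                )
                continue
            expected = refseq.slice(rec.pos, rec.pos + len(ref) - 1)
            if expected != ref:
                raise ValueError(
                    f"record {nrec} ({rec.chrom}:{rec.pos}): REF {ref!r} does not match "
                    f"reference {expected!r} — wrong reference build?"
                )
            alts = []
            for alt in rec.alts:
                a = alt.upper()
                if a.startswith("<") or set(a) - DNA_ALPHABET or a == ref:
                    logger.warning(
                        "skipping ALT %r of record %d (%s:%d): symbolic or non-DNA allele",
                        alt, nrec, rec.chrom, rec.pos,
                    )
                    continue
                alts.append(a)
            gt_indices: Sequence[int | None] | None = None
            phased = False
            if rec.samples:
                sample = next(iter(rec.samples.values()))
                gt_indices = sample.get("GT")
                phased = bool(sample.phased)
            yield from split_multiallelic(
                rec.chrom, rec.pos, ref, alts,
                vid=rec.id or MISSING, gt_indices=gt_indices, phased=phased,
            )


def write_annotation_table(
    rows: Iterable[dict], path: str | Path, columns: Sequence[str]
) -> int:
    """Write annotation rows as a TSV with a fixed header.

    ``columns`` is the full, ordered column set (basic columns first, then the
    enabled optional blocks). Cells missing from a row are printed as ".".
    Returns the number of data rows written.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, MISSING)) for c in columns) + "\n")
            n += 1
    return n


def write_sequences(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as FASTA with 60-column wrapping."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file back as (name, sequence) pairs (round-trip helper)."""
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records
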
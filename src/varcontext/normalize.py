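"""Variant normalization: parsimonious, left-aligned representation.

A variant is *parsimonious* when it is written with as few nucleotides as
possible without a zero-length allele, and *left aligned* when its position
cannot be shifted further 5' while keeping both allele lengths constant.
Every annotation in this package operates on normalized records, so the many
equivalent encodings of an indel collapse to one canonical form first.

The algorithm is the classic trim/extend scheme used by VCF normalizers:
right-trim the common trailing base repeatedly, prepending the reference base
to the left (and decrementing the position) whenever an allele would become
empty; then left-trim common leading bases while both alleles are longer than
one base. SNVs pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import ReferenceSet, VariantRecord, MISSING

logger = logging.getLogger("varcontext")


@dataclass(frozen=True)
class NormalizedVariant:
    """A parsimonious, left-aligned variant plus its original encoding."""

    contig: str
    pos: int
    ref: str
    alt: str
    vid: str = MISSING
    genotype: str = MISSING
    original_pos: int = 0
    original_ref: str = ""
    original_alt: str = ""
    normalized: bool = True  # False when left extension hit the contig start

    @property
    def end(self) -> int:
        return self.pos + len(self.ref) - 1

    @property
    def has_n(self) -> bool:
        return "N" in self.ref or "N" in self.alt

    @property
    def variant_class(self) -> str:
        """One of ``snv``, ``mnv``, ``ins``, ``del``, ``complex``.

        ``ins``/``del`` require the anchored form produced by normalization
        (the other allele is the shared leading base); everything else that
        changes length, e.g. REF CATTC / ALT G, is ``complex``.
        """
        r, a = self.ref, self.alt
        if len(r) == len(a):
            return "snv" if len(r) == 1 else "mnv"
        if len(a) == 1 and len(r) > 1 and r[0] == a:
            return "del"
        if len(r) == 1 and len(a) > 1 and a[0] == r:
            return "ins"
        return "complex"

    @property
    def is_indel(self) -> bool:
        return self.variant_class in ("ins", "del")

    @property
    def indel_pattern(self) -> str:
        """The anchor-trimmed inserted or deleted sequence (a1..an)."""
        cls = self.variant_class
        if cls == "del":
            return self.ref[1:]
        if cls == "ins":
            return self.alt[1:]
        raise ValueError(f"{cls} variant has no indel pattern")


def normalize(record: VariantRecord, reference: ReferenceSet) -> NormalizedVariant:
    """Return the parsimonious, left-aligned form of ``record``.

    If left extension would step below position 1 (a malformed variant at the
    contig start) the record is returned unnormalized with ``normalized``
    False and a warning is logged.
    """
    refseq = reference.require(record.contig)
    pos, ref, alt = record.pos, record.ref.upper(), record.alt.upper()

    def unchanged(ok: bool = True) -> NormalizedVariant:
        return NormalizedVariant(
            contig=record.contig, pos=record.pos, ref=record.ref.upper(),
            alt=record.alt.upper(), vid=record.vid, genotype=record.genotype,
            original_pos=record.pos, original_ref=record.ref.upper(),
            original_alt=record.alt.upper(), normalized=ok,
        )

    if len(ref) == 1 and len(alt) == 1:
        return unchanged()

    # Right-trim shared trailing bases, extending left from the reference
    # whenever one allele empties.
    while ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos - 1 < 1:
                logger.warning(
                    "cannot left-extend %s:%d %s>%s past the contig start; "
                    "record reported unnormalized",
                    record.contig, record.pos, record.ref, record.alt,
                )
                return unchanged(ok=False)
            base = refseq.base(pos - 1)
            pos -= 1
            ref, alt = base + ref, base + alt

    # Left-trim shared leading bases while both alleles stay non-degenerate.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    return NormalizedVariant(
        contig=record.contig, pos=pos, ref=ref, alt=alt,
        vid=record.vid, genotype=record.genotype,
        original_pos=record.pos, original_ref=record.ref.upper(),
        original_alt=record.alt.upper(), normalized=True,
    )


def is_normalized(record: VariantRecord, reference: ReferenceSet) -> bool:
    """True iff ``record`` already equals its normalized form."""
    norm = normalize(record, reference)
    return (
        norm.normalized
        and norm.pos == record.pos
        and norm.ref == record.ref.upper()
        and norm.alt == record.alt.upper()
    )


def as_record(norm: NormalizedVariant) -> VariantRecord:
    """View a normalized variant as a plain :class:`VariantRecord`."""
    return VariantRecord(
        contig=norm.contig, pos=norm.pos, ref=norm.ref, alt=norm.alt,
        vid=norm.vid, genotype=norm.genotype,
    )
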
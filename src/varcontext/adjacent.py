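"""Adjacent-sequence annotation of normalized variants.

An indel inside locally repeated sequence (microhomology) has many equivalent
placements that all produce the same mutated molecule — its breakpoint is
ambiguous. This module computes, for each normalized variant:

* the 5'-aligned position (leftmost equivalent placement),
* the 3'-aligned position (rightmost equivalent placement),
* the 3' edge position (rightmost reference base the variant can affect),
* whether the variant is ambiguous and whether it sits in a duplicate,

and, built on those coordinates: flanking bases including the full equivalent
region, HGVS DNA-level nomenclature (which follows the 3' rule), 3' distances
between adjacent variants, region-restricted wildtype/mutated sequences, and
overlap annotation against user BED intervals.

Coordinate conventions
----------------------
For a normalized deletion (anchored form) the deleted run starts at
``pos + 1``; the 5'-aligned position is the leftmost possible first deleted
base, the 3' edge the rightmost possible last deleted base, and the
3'-aligned position the first base of the 3'-most deleted run
(``edge - n + 1`` for pattern length ``n``), so that ``three - five`` equals
the total placement shift. For an insertion the aligned positions refer to
the base immediately 5' of the insertion point: the 5'-aligned position is
the (left-aligned) anchor position itself, and the 3'-aligned and edge
positions coincide at the rightmost possible anchor. SNV/MNV/complex records
have a single fixed placement: both aligned positions equal POS and the edge
is the last REF base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .io import ReferenceSet
from .normalize import NormalizedVariant

logger = logging.getLogger("varcontext")


def _bases_match(a: str, b: str) -> bool:
    # N is an unknown base: it never certifies a match, not even against N.
    return a == b and a != "N" and a != ""


@dataclass(frozen=True)
class AmbiguityAnnotation:
    five_prime_aligned: int
    three_prime_aligned: int
    three_prime_edge: int
    ambiguous: bool
    in_duplicate: bool

    @property
    def shift(self) -> int:
        """Total placement shift (number of alternative placements minus 1)."""
        return self.three_prime_aligned - self.five_prime_aligned


@dataclass(frozen=True)
class HGVSDescription:
    text: str


def three_prime_edge(variant: NormalizedVariant, reference: ReferenceSet) -> int:
    """Rightmost reference base the variant can affect (permutation walk).

    For a pure indel with pattern (a1..an), the pattern is compared with the
    reference bases immediately 3' of the indel: while the pattern's leftmost
    base equals the next reference base the pattern rotates left by one and
    the edge advances by one. SNV/MNV/complex records return the position of
    their last REF base.
    """
    refseq = reference.require(variant.contig)
    cls = variant.variant_class
    if cls not in ("ins", "del"):
        return variant.pos + len(variant.ref) - 1
    pattern = variant.indel_pattern
    n = len(pattern)
    if cls == "del":
        edge = variant.pos + n        # last deleted base
        walk = variant.pos + n + 1    # first 3'-adjacent reference base
    else:
        edge = variant.pos            # anchor base 5' of the insertion point
        walk = variant.pos + 1
    k = 0
    while walk + k <= refseq.length and _bases_match(pattern[k % n], refseq.base(walk + k)):
        edge += 1
        k += 1
    return edge


def aligned_positions(
    variant: NormalizedVariant, reference: ReferenceSet
) -> AmbiguityAnnotation:
    """Compute the full breakpoint-ambiguity annotation of a variant."""
    cls = variant.variant_class
    if cls not in ("ins", "del"):
        edge = variant.pos + len(variant.ref) - 1
        return AmbiguityAnnotation(
            five_prime_aligned=variant.pos,
            three_prime_aligned=variant.pos,
            three_prime_edge=edge,
            ambiguous=False,
            in_duplicate=False,
        )
    edge = three_prime_edge(variant, reference)
    n = len(variant.indel_pattern)
    if cls == "del":
        five = variant.pos + 1
        three = edge - n + 1
        shift = three - five
    else:
        five = variant.pos
        three = edge
        shift = edge - five
    return AmbiguityAnnotation(
        five_prime_aligned=five,
        three_prime_aligned=three,
        three_prime_edge=edge,
        ambiguous=five != three,
        in_duplicate=shift >= n,
    )


def in_duplicate(
    variant: NormalizedVariant,
    reference: ReferenceSet,
    ann: AmbiguityAnnotation | None = None,
) -> bool:
    """True when the placement shift covers at least one whole pattern copy:
    a deletion removing one copy of a duplicated run, or an insertion that
    creates or extends a duplication."""
    if ann is None:
        ann = aligned_positions(variant, reference)
    return ann.in_duplicate


def flanking_bases(
    variant: NormalizedVariant,
    reference: ReferenceSet,
    ann: AmbiguityAnnotation,
    n_flank: int,
) -> tuple[str, str, str, str]:
    """Flanks around the *equivalent region* plus the region itself.

    Returns (left flank, right flank, REF-side region, ALT-side region).
    The left flank is the ``n_flank`` bases 5' of the 5'-aligned position and
    the right flank the ``n_flank`` bases 3' of the 3' edge, truncated at the
    contig boundaries. The middle segments are the full equivalent region
    under the reference and alternative alleles.
    """
    refseq = reference.require(variant.contig)
    cls = variant.variant_class
    five, edge = ann.five_prime_aligned, ann.three_prime_edge
    left = refseq.slice(five - n_flank, five - 1)
    right = refseq.slice(edge + 1, edge + n_flank)
    if cls == "del":
        ref_region = refseq.slice(five, edge)
        alt_region = refseq.slice(five + len(variant.indel_pattern), edge)
    elif cls == "ins":
        ref_region = refseq.slice(five, edge)
        alt_region = variant.alt + refseq.slice(variant.pos + 1, edge)
    else:
        ref_region = variant.ref
        alt_region = variant.alt
    return left, right, ref_region, alt_region


def _rotated_pattern(variant: NormalizedVariant, ann: AmbiguityAnnotation) -> str:
    """The indel pattern as it reads at its 3'-most placement."""
    pattern = variant.indel_pattern
    s = ann.shift % len(pattern)
    return pattern[s:] + pattern[:s]


def hgvs_dna(
    variant: NormalizedVariant,
    reference: ReferenceSet,
    ann: AmbiguityAnnotation,
) -> HGVSDescription:
    """DNA-level (``g.``) HGVS description using the 3'-most representation.

    Substitutions read ``g.<pos><ref>><alt>``; deletions describe the 3'-most
    deleted run; an insertion whose sequence duplicates the immediately 5'
    reference run is a ``dup`` of that run, otherwise an ``ins``; equal-length
    multi-base and complex changes are ``delins``.
    """
    cls = variant.variant_class
    contig = variant.contig
    if cls == "snv":
        desc = f"{variant.pos}{variant.ref}>{variant.alt}"
    elif cls == "del":
        start, end = ann.three_prime_aligned, ann.three_prime_edge
        desc = f"{start}del" if start == end else f"{start}_{end}del"
    elif cls == "ins":
        n = len(variant.indel_pattern)
        edge = ann.three_prime_edge
        if ann.shift >= n:  # at least one pre-existing copy 5' of the 3'-most site
            start = edge - n + 1
            desc = f"{edge}dup" if n == 1 else f"{start}_{edge}dup"
        else:
            desc = f"{edge}_{edge + 1}ins{_rotated_pattern(variant, ann)}"
    else:  # mnv / complex
        start, end = variant.pos, variant.pos + len(variant.ref) - 1
        span = f"{start}" if start == end else f"{start}_{end}"
        desc = f"{span}delins{variant.alt}"
    return HGVSDescription(text=f"{contig}:g.{desc}")


def distance_to_next(
    current: AmbiguityAnnotation, next_ann: AmbiguityAnnotation
) -> int:
    """Reference bases strictly between the current variant's 3' edge and the
    next variant's 5'-aligned position. Overlapping variants yield 0."""
    d = next_ann.five_prime_aligned - current.three_prime_edge - 1
    if d < 0:
        logger.info("overlapping equivalent regions; distance reported as 0")
        return 0
    return d


def mutated_sequence(
    contig: str,
    start: int,
    end: int,
    variants: Sequence[NormalizedVariant],
    reference: ReferenceSet,
) -> tuple[str, str, str]:
    """Wildtype, mutated, and reverse-complemented-mutated sequence of a
    closed 1-based region, with all in-region variants applied.

    Variants must be non-overlapping after normalization and lie entirely
    within the region; overlaps are a hard error because no precedence among
    conflicting alleles is defined.
    """
    refseq = reference.require(contig)
    if start < 1 or end > refseq.length or start > end:
        raise ValueError(f"region {contig}:{start}-{end} outside the contig")
    wildtype = refseq.slice(start, end)
    ordered = sorted(variants, key=lambda v: v.pos)
    for v in ordered:
        if v.pos < start or v.end > end:
            raise ValueError(
                f"variant {v.contig}:{v.pos} {v.ref}>{v.alt} not fully inside "
                f"{contig}:{start}-{end}"
            )
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.pos <= prev.end:
            raise ValueError(
                f"overlapping variants at {contig}:{prev.pos} and {contig}:{nxt.pos}"
            )
    mutated = wildtype
    for v in reversed(ordered):  # right-to-left keeps 5' offsets valid
        off = v.pos - start
        mutated = mutated[:off] + v.alt + mutated[off + len(v.ref):]
    revcomp = str(Seq(mutated).reverse_complement())
    return wildtype, mutated, revcomp


def custom_bed_annotation(
    variant: NormalizedVariant,
    ann: AmbiguityAnnotation,
    intervals: dict,
) -> list[str]:
    """Labels of BED intervals overlapping the variant's affected span.

    The span is the closed interval [5'-aligned, 3' edge], so a variant
    partially overlapping or adjacent-through-ambiguity to an interval is
    still annotated. Returns sorted labels; empty when nothing overlaps.
    """
    tree = intervals.get(variant.contig)
    if tree is None:
        return []
    hits = tree.overlap(ann.five_prime_aligned - 1, ann.three_prime_edge)
    return sorted({h.data for h in hits})
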
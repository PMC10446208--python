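"""Tandem-repeat discovery and annotation at variant sites.

The engine explores the local sequence context of each variant (using the
breakpoint-ambiguity span, not just the reported POS) and searches for tandem
repeats that overlap or directly flank it:

1.  The *variant site* is the pair of reference coordinates immediately 5' of
    the 5'-aligned position and immediately 3' of the 3' edge position.
2.  For every window size w in [min_unit, max_unit], every w-mer whose span
    touches the site is a *candidate conserved motif*.
3.  From each candidate anchor, repeat units are collected first in the 5'
    and then the 3' direction. In each round, w-mers at gap distance
    0..max_gap from the last accepted unit are scored by positionwise base
    identity against the current motif; the best-scoring candidate (ties to
    the smallest gap) is accepted when its score reaches
    ``similarity_threshold * w``. Once five units (anchor included) have been
    collected the comparison motif becomes the per-column consensus of the
    units gathered so far and keeps updating; after the search, all units'
    mismatch counts are recomputed against the final consensus.
4.  Units are assembled into a candidate region whose alignment score is
    ``MS*match + MIS*mismatch + GS*gap`` over its bases, and whose repeat
    score is the alignment score divided by the region length times the copy
    number — the view being a global alignment of the region against an
    ideal perfect repeat of the same motif and copy number.
5.  Quality control keeps regions meeting minimum copy number, match
    percentage, and alignment score; if none pass, the best-scoring candidate
    is trimmed unit-by-unit from its ragged tails until it passes or its copy
    number falls below the floor.
6.  Redundant regions (e.g. the same tract reported under motif AT and ATAT)
    are removed: ranked by repeat score (then copy number), any pair whose
    reference-span overlap exceeds half of their union keeps only the region
    whose motif base composition is closest to its whole-region composition,
    ties going to the better-ranked region.

Surviving regions are finalized with their GC% and the signed copy-number
change the variant causes ((len(ALT) - len(REF)) / motif length).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

from .adjacent import AmbiguityAnnotation
from .io import ReferenceSequence, ReferenceSet
from .normalize import NormalizedVariant

logger = logging.getLogger("varcontext")

#: per-motif-size minimum copy numbers used for the perfect/imperfect STR
#: analyses: 10 for mononucleotide, 5 for dinucleotide, 4 for tri- to
#: hexanucleotide motifs.
STR_MIN_COPY_PROFILE = {1: 10, 2: 5, 3: 4, 4: 4, 5: 4, 6: 4}


@dataclass(frozen=True)
class TandemRepeatParams:
    """Tunables of the repeat engine.

    ``max_gap`` of None means "one motif length" (the default gap tolerance
    scales with the window size). ``min_copy`` may be a single integer or a
    {motif size: copies} map; sizes beyond the map reuse its largest key.
    ``min_alignment_score`` acts as a minimum-region-size control (with the
    default match score 2 it encodes a 10 bp minimum STR length) and
    ``min_match_pct`` as a purity control.
    """

    min_unit: int = 1
    max_unit: int = 6
    max_gap: int | None = None
    similarity_threshold: float = 1.0
    match_score: float = 2.0
    mismatch_score: float = -5.0
    gap_score: float = -7.0
    min_copy: int | dict = 3
    min_alignment_score: float = 20.0
    min_match_pct: float = 100.0

    def __post_init__(self) -> None:
        if not (1 <= self.min_unit <= self.max_unit):
            raise ValueError("need 1 <= min_unit <= max_unit")
        if not (0 < self.similarity_threshold <= 1):
            raise ValueError("similarity_threshold must be in (0, 1]")
        floors = (
            self.min_copy.values() if isinstance(self.min_copy, dict) else [self.min_copy]
        )
        if any(c < 2 for c in floors):
            raise ValueError("min_copy must be >= 2")

    def gap_limit(self, w: int) -> int:
        return w if self.max_gap is None else self.max_gap

    def min_copy_for(self, w: int) -> int:
        if isinstance(self.min_copy, dict):
            key = w if w in self.min_copy else max(self.min_copy)
            return self.min_copy[key]
        return self.min_copy

    @classmethod
    def perfect(cls, **overrides) -> "TandemRepeatParams":
        """Perfect-STR profile: 100% unit identity, minimum region length
        10 bp, minimum copies 10/5/4 by motif size."""
        base = dict(
            similarity_threshold=1.0,
            min_match_pct=100.0,
            min_copy=dict(STR_MIN_COPY_PROFILE),
            min_alignment_score=20.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def imperfect90(cls, **overrides) -> "TandemRepeatParams":
        """Imperfect-STR profile: regions need at least 90% matching bases."""
        base = dict(
            similarity_threshold=0.9,
            min_match_pct=90.0,
            min_copy=dict(STR_MIN_COPY_PROFILE),
            min_alignment_score=20.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class VariantSite:
    """The two reference coordinates bracketing a variant's affected span."""

    contig: str
    left_boundary: int   # base 5'-adjacent to the 5'-aligned position
    right_boundary: int  # base 3'-adjacent to the 3' edge position


@dataclass
class RepeatUnit:
    seq: str
    start: int
    end: int
    gap: int = 0          # bp between this unit and the previously accepted one
    mismatches: int = 0   # vs. the (final) comparison motif

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class TandemRepeatRegion:
    motif: str
    start: int
    end: int
    copy_number: int
    match_bases: int
    mismatch_bases: int
    gap_bases: int
    match_pct: float
    mismatch_pct: float
    gap_pct: float
    alignment_score: float
    repeat_score: float
    gc_pct: float | None = None
    copy_change: float | None = None
    units: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _match_count(a: str, b: str) -> int:
    # N certifies nothing: an N on either side scores 0 at that column.
    return sum(1 for x, y in zip(a, b) if x == y and x != "N")


def variant_site(
    variant: NormalizedVariant, ann: AmbiguityAnnotation
) -> VariantSite | None:
    """The search site of a variant, or None for variants containing N
    (unknown bases cannot seed or certify a repeat)."""
    if variant.has_n:
        logger.info(
            "skipping tandem-repeat search for %s:%d (allele contains N)",
            variant.contig, variant.pos,
        )
        return None
    return VariantSite(
        contig=variant.contig,
        left_boundary=ann.five_prime_aligned - 1,
        right_boundary=ann.three_prime_edge + 1,
    )


def candidate_motifs(
    site: VariantSite, reference: ReferenceSet, params: TandemRepeatParams
) -> list[tuple[int, str, int]]:
    """All (window size, motif, start) candidates touching the site, 5'→3'.

    A w-mer qualifies when its span intersects the closed interval
    [left_boundary, right_boundary]; windows truncated by contig ends are
    omitted.
    """
    refseq = reference.require(site.contig)
    out = []
    for w in range(params.min_unit, params.max_unit + 1):
        lo = max(1, site.left_boundary - w + 1)
        hi = min(site.right_boundary, refseq.length - w + 1)
        for start in range(lo, hi + 1):
            out.append((w, refseq.slice(start, start + w - 1), start))
    return out


def _consensus(units: list[RepeatUnit], anchor_motif: str) -> str:
    """Per-column majority base over the collected units; ties resolve toward
    the anchor motif's base at that column."""
    w = len(anchor_motif)
    cols = []
    for j in range(w):
        counts = Counter(u.seq[j] for u in units if len(u.seq) > j)
        if not counts:
            cols.append(anchor_motif[j])
            continue
        best = max(counts.values())
        tied = sorted(b for b, c in counts.items() if c == best)
        cols.append(anchor_motif[j] if anchor_motif[j] in tied else tied[0])
    return "".join(cols)


def search_units(
    motif: str,
    anchor_start: int,
    direction: str,
    reference: ReferenceSet,
    contig: str,
    params: TandemRepeatParams,
    collected: list[RepeatUnit] | None = None,
) -> list[RepeatUnit]:
    """Collect repeat units in one direction from an anchor motif occurrence.

    ``collected`` carries units already accepted (including the anchor) so
    that consensus updating counts rounds across both directions. Returns the
    newly accepted units in search order (nearest first).
    """
    refseq = reference.require(contig)
    w = len(motif)
    threshold = params.similarity_threshold * w - 1e-9
    max_gap = params.gap_limit(w)
    collected = list(collected) if collected is not None else [
        RepeatUnit(seq=motif, start=anchor_start, end=anchor_start + w - 1)
    ]
    accepted: list[RepeatUnit] = []
    cur_start, cur_end = anchor_start, anchor_start + w - 1
    if direction not in ("5'", "3'"):
        raise ValueError("direction must be \"5'\" or \"3'\"")
    while True:
        current_motif = _consensus(collected, motif) if len(collected) >= 5 else motif
        best: tuple[int, int, int, str] | None = None  # (score, gap, start, seq)
        for gap in range(0, max_gap + 1):
            if direction == "5'":
                s_end = cur_start - 1 - gap
                s_start = s_end - w + 1
            else:
                s_start = cur_end + 1 + gap
                s_end = s_start + w - 1
            if s_start < 1 or s_end > refseq.length:
                continue
            seq = refseq.slice(s_start, s_end)
            score = _match_count(current_motif, seq)
            if best is None or score > best[0]:  # strict > keeps the smallest gap
                best = (score, gap, s_start, seq)
        if best is None or best[0] < threshold:
            break
        score, gap, s_start, seq = best
        unit = RepeatUnit(
            seq=seq, start=s_start, end=s_start + w - 1,
            gap=gap, mismatches=w - score,
        )
        accepted.append(unit)
        collected.append(unit)
        cur_start, cur_end = unit.start, unit.end
    return accepted


def _region_from_units(
    motif: str, units: list[RepeatUnit], params: TandemRepeatParams
) -> TandemRepeatRegion:
    units = sorted(units, key=lambda u: u.start)
    start, end = units[0].start, units[-1].end
    copy = len(units)
    gap_bases = sum(b.start - a.end - 1 for a, b in zip(units, units[1:]))
    mismatch = sum(u.mismatches for u in units)
    match = sum(u.width for u in units) - mismatch
    length = end - start + 1
    align = (
        params.match_score * match
        + params.mismatch_score * mismatch
        + params.gap_score * gap_bases
    )
    return TandemRepeatRegion(
        motif=motif, start=start, end=end, copy_number=copy,
        match_bases=match, mismatch_bases=mismatch, gap_bases=gap_bases,
        match_pct=100.0 * match / length,
        mismatch_pct=100.0 * mismatch / length,
        gap_pct=100.0 * gap_bases / length,
        alignment_score=align,
        repeat_score=align / length * copy,
        units=units,
    )


def assemble_region(
    motif: str,
    anchor_start: int,
    units_5p: list[RepeatUnit],
    units_3p: list[RepeatUnit],
    reference: ReferenceSet,
    contig: str,
    params: TandemRepeatParams,
) -> TandemRepeatRegion:
    """Combine the anchor and both direction searches into one candidate
    region; the reported motif is the final consensus (anchor motif when
    fewer than five units were collected) and every unit's mismatch count is
    recomputed against it."""
    w = len(motif)
    anchor = RepeatUnit(seq=motif, start=anchor_start, end=anchor_start + w - 1)
    units = list(units_5p) + [anchor] + list(units_3p)
    final_motif = _consensus(units, motif) if len(units) >= 5 else motif
    for u in units:
        u.mismatches = u.width - _match_count(final_motif, u.seq)
    return _region_from_units(final_motif, units, params)


def _passes(region: TandemRepeatRegion, params: TandemRepeatParams) -> bool:
    return (
        region.copy_number >= params.min_copy_for(len(region.motif))
        and region.match_pct >= params.min_match_pct - 1e-9
        and region.alignment_score >= params.min_alignment_score - 1e-9
    )


def qc_and_trim(
    candidates: list[TandemRepeatRegion], params: TandemRepeatParams
) -> list[TandemRepeatRegion]:
    """Quality control with tail trimming as a fallback.

    Regions passing all three thresholds are kept. When none pass but at
    least one candidate exists, the best-alignment-score candidate has its
    5'/3' tail units removed one at a time (whichever removal scores higher;
    ties trim the 3' tail), recomputing all statistics, until it passes or
    its copy number drops below the floor (then it is abandoned).
    """
    passed = [c for c in candidates if _passes(c, params)]
    if passed or not candidates:
        return passed
    best = max(candidates, key=lambda c: (c.alignment_score, c.copy_number))
    units = list(best.units)
    motif = best.motif
    floor = params.min_copy_for(len(motif))
    while len(units) > 1:
        trim5 = _region_from_units(motif, units[1:], params)
        trim3 = _region_from_units(motif, units[:-1], params)
        region = trim3 if trim3.alignment_score >= trim5.alignment_score else trim5
        units = region.units
        if region.copy_number < floor:
            return []
        if _passes(region, params):
            return [region]
    return []


def _dedupe(regions: list[TandemRepeatRegion]) -> list[TandemRepeatRegion]:
    seen = set()
    out = []
    for r in regions:
        key = (r.start, r.end, r.copy_number, r.motif)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def _base_freq(seq: str) -> dict[str, float]:
    if not seq:
        return {}
    counts = Counter(seq)
    return {b: counts.get(b, 0) / len(seq) for b in "ACGTN"}


def _freq_difference(region: TandemRepeatRegion, refseq: ReferenceSequence) -> float:
    """L1 distance between the motif's and the whole region's base
    composition (both as fractions)."""
    fm = _base_freq(region.motif)
    fr = _base_freq(refseq.slice(region.start, region.end))
    return sum(abs(fm.get(b, 0.0) - fr.get(b, 0.0)) for b in "ACGTN")


def remove_redundancy(
    regions: list[TandemRepeatRegion],
    reference: ReferenceSet,
    contig: str,
) -> list[TandemRepeatRegion]:
    """Drop redundant regions (same tract under motifs that are multiples or
    rotations of each other).

    Regions are ranked by repeat score descending, ties by copy number
    descending. Walking down the ranking, a region whose overlap/union ratio
    with an already-kept region exceeds 0.5 (strictly) competes with it: the
    region with the smaller motif-vs-region composition difference survives,
    a tie keeping the earlier-ranked one.
    """
    refseq = reference.require(contig)
    ranked = sorted(regions, key=lambda r: (-r.repeat_score, -r.copy_number))
    survivors: list[TandemRepeatRegion] = []
    for r in ranked:
        keep = True
        for s in list(survivors):
            overlap = min(r.end, s.end) - max(r.start, s.start) + 1
            union = max(r.end, s.end) - min(r.start, s.start) + 1
            if overlap <= 0 or union <= 0:
                continue
            if overlap / union > 0.5:
                if _freq_difference(r, refseq) < _freq_difference(s, refseq):
                    survivors.remove(s)
                else:
                    keep = False
                    break
        if keep:
            survivors.append(r)
    return survivors


def finalize(
    region: TandemRepeatRegion,
    variant: NormalizedVariant,
    reference: ReferenceSet,
) -> TandemRepeatRegion:
    """Attach GC% of the region's reference span and the signed copy-number
    change the variant causes (fractional for off-motif indel lengths)."""
    refseq = reference.require(variant.contig)
    span = refseq.slice(region.start, region.end)
    gc = 100.0 * sum(1 for b in span if b in "GC") / len(span) if span else 0.0
    delta = len(variant.alt) - len(variant.ref)
    copy_change = delta / len(region.motif) if delta else 0.0
    return replace(region, gc_pct=gc, copy_change=copy_change)


def annotate_variant_tr(
    variant: NormalizedVariant,
    ann: AmbiguityAnnotation,
    reference: ReferenceSet,
    params: TandemRepeatParams | None = None,
) -> list[TandemRepeatRegion]:
    """Full tandem-repeat annotation pipeline for one variant.

    Returns the final (possibly empty) list of repeat regions, each carrying
    its motif, span, copy number, match/mismatch/gap accounting, alignment
    and repeat scores, GC%, and copy-number change.
    """
    if params is None:
        params = TandemRepeatParams()
    site = variant_site(variant, ann)
    if site is None:
        return []
    candidates: list[TandemRepeatRegion] = []
    for w, motif, start in candidate_motifs(site, reference, params):
        if "N" in motif:
            continue
        anchor = RepeatUnit(seq=motif, start=start, end=start + w - 1)
        units_5p = search_units(
            motif, start, "5'", reference, site.contig, params, collected=[anchor]
        )
        units_3p = search_units(
            motif, start, "3'", reference, site.contig, params,
            collected=[anchor] + list(units_5p),
        )
        # unit order: leftmost first on the 5' side (search returns nearest first)
        region = assemble_region(
            motif, start, list(reversed(units_5p)), units_3p,
            reference, site.contig, params,
        )
        candidates.append(region)
    candidates = _dedupe(candidates)
    kept = qc_and_trim(candidates, params)
    kept = remove_redundancy(kept, reference, site.contig)
    return [finalize(r, variant, reference) for r in kept]
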
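"""Synthetic references, VCFs, and brute-force oracles.

The generators build reference contigs with embedded tandem repeats whose
spans and copy numbers are known exactly (the bases flanking each tract are
chosen so the periodic pattern cannot extend by chance), plus matching VCFs
with spiked variants. The oracles are deliberately naive, exhaustive
implementations — quadratic searches over small sequences — used as
independent ground truth for the normalizer and the breakpoint-ambiguity
annotations. They are size-capped and test-only by design.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io import ReferenceSequence, ReferenceSet, VariantRecord
from .normalize import NormalizedVariant, normalize

_BASES = "ACGT"


@dataclass(frozen=True)
class EmbeddedRepeat:
    """A perfect (or deliberately impure) tandem repeat to embed."""

    motif: str
    copies: int
    position: int  # 1-based start of the tract
    impurities: tuple = ()  # (0-based offset within tract, replacement base)

    @property
    def span(self) -> tuple[int, int]:
        return self.position, self.position + len(self.motif) * self.copies - 1


@dataclass(frozen=True)
class SpikedVariant:
    """A VCF record to spike; ``alt`` may hold several comma-separated
    alleles to produce a multiallelic record."""

    pos: int
    ref: str
    alt: str
    vid: str = "."
    genotype: str = "0/1"


@dataclass
class FixtureSpec:
    length: int = 300
    gc: float = 0.4
    contig: str = "chr_fix"
    repeats: list = field(default_factory=list)
    variants: list = field(default_factory=list)
    seed: int = 0


def _random_base(rng: random.Random, gc: float) -> str:
    if rng.random() < gc:
        return rng.choice("GC")
    return rng.choice("AT")


def _rotations(motif: str) -> set[str]:
    return {motif[i:] + motif[:i] for i in range(len(motif))}


def _guard_zone(rng: random.Random, motif: str, first: str | None, last: str | None) -> list[str]:
    """A stretch of 2*len(motif) bases containing no window that perfectly
    matches any rotation of ``motif``, so a unit search with the default gap
    tolerance (one motif length) cannot extend a tract across it.

    ``first``/``last`` additionally forbid the period-continuation base at
    the zone edge adjacent to the tract.
    """
    w = len(motif)
    rots = _rotations(motif)
    for _ in range(10_000):
        zone = [rng.choice(_BASES) for _ in range(2 * w)]
        if first is not None and zone[0] == first:
            continue
        if last is not None and zone[-1] == last:
            continue
        if any("".join(zone[i : i + w]) in rots for i in range(w + 1)):
            continue
        return zone
    raise RuntimeError(f"could not build a guard zone for motif {motif!r}")


def make_reference(spec: FixtureSpec) -> tuple[ReferenceSet, list[dict]]:
    """Build the fixture contig and its repeat truth table.

    Background bases are drawn at the requested GC fraction; each embedded
    repeat is written verbatim and a guard zone of two motif lengths on each
    side is re-drawn so that the tract cannot extend in either direction,
    even through a gap up to one motif length: the guard contains no perfect
    occurrence of any motif rotation, and its tract-adjacent base breaks the
    period. Overlapping repeats (including guard zones) are an error.
    Deterministic under ``seed``.
    """
    rng = random.Random(spec.seed)
    seq = [_random_base(rng, spec.gc) for _ in range(spec.length)]
    spans = []
    for rep in sorted(spec.repeats, key=lambda r: r.position):
        start, end = rep.span
        g = 2 * len(rep.motif)
        if start - g < 1 or end + g > spec.length:
            raise ValueError(
                f"repeat {rep.motif}x{rep.copies} at {start} leaves no room for guards"
            )
        if spans and start - g <= spans[-1][1]:
            raise ValueError("embedded repeats (with guard zones) overlap")
        spans.append((start, end + g))
        tract = rep.motif * rep.copies
        for off, base in rep.impurities:
            tract = tract[:off] + base + tract[off + 1 :]
        seq[start - 1 : end] = list(tract)
        left = _guard_zone(rng, rep.motif, first=None, last=rep.motif[-1])
        right = _guard_zone(rng, rep.motif, first=rep.motif[0], last=None)
        seq[start - 1 - g : start - 1] = left
        seq[end : end + g] = right
    refs = ReferenceSet()
    refs[spec.contig] = ReferenceSequence(name=spec.contig, seq="".join(seq))
    truth = [
        {
            "motif": rep.motif,
            "start": rep.span[0],
            "end": rep.span[1],
            "copies": rep.copies,
        }
        for rep in spec.repeats
    ]
    return refs, truth


def write_fixture_fasta(reference: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, refseq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, refseq.length, 60):
                fh.write(refseq.seq[i : i + 60] + "\n")


def make_vcf(spec: FixtureSpec, reference: ReferenceSet, path: str | Path) -> None:
    """Write the spiked variants as a minimal valid VCF aligned to the
    fixture reference; spikes whose REF disagrees with the reference (or lie
    off the contig) are an error."""
    refseq = reference[spec.contig]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={spec.contig},length={refseq.length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE",
    ]
    for sv in sorted(spec.variants, key=lambda v: v.pos):
        expected = refseq.slice(sv.pos, sv.pos + len(sv.ref) - 1)
        if expected != sv.ref.upper():
            raise ValueError(
                f"spiked REF {sv.ref!r} at {sv.pos} disagrees with reference {expected!r}"
            )
        lines.append(
            f"{spec.contig}\t{sv.pos}\t{sv.vid}\t{sv.ref}\t{sv.alt}\t.\t.\t.\tGT\t{sv.genotype}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply one REF->ALT substitution to a full contig string (1-based)."""
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def oracle_equivalent_placements(
    variant: NormalizedVariant, reference: ReferenceSet
) -> dict:
    """Exhaustively enumerate all placements equivalent to an indel.

    For a deletion, every start position of a same-length deletion whose
    mutated sequence equals the variant's is collected (positions of the
    first deleted base); for an insertion, every anchor position p such that
    inserting between p and p+1 reproduces the mutated sequence (p = 0 means
    before the first base). Non-indels have exactly one placement.

    Returns {"kind", "positions", "five", "three", "edge"} with the expected
    aligned positions implied by the enumeration.
    """
    refseq = reference.require(variant.contig)
    seq = refseq.seq
    mutated = apply_variant(seq, variant.pos, variant.ref, variant.alt)
    cls = variant.variant_class
    if cls == "del":
        d = len(variant.ref) - len(variant.alt)
        positions = [
            p
            for p in range(1, len(seq) - d + 2)
            if seq[: p - 1] + seq[p - 1 + d :] == mutated
        ]
        return {
            "kind": "del",
            "positions": positions,
            "five": min(positions),
            "three": max(positions),
            "edge": max(positions) + d - 1,
        }
    if cls == "ins":
        d = len(variant.alt) - len(variant.ref)
        anchors = [
            p
            for p in range(0, len(seq) + 1)
            if seq[:p] + mutated[p : p + d] + seq[p:] == mutated
        ]
        return {
            "kind": "ins",
            "positions": anchors,
            "five": min(anchors),
            "three": max(anchors),
            "edge": max(anchors),
        }
    return {
        "kind": cls,
        "positions": [variant.pos],
        "five": variant.pos,
        "three": variant.pos,
        "edge": variant.pos + len(variant.ref) - 1,
    }


def oracle_normalize(record: VariantRecord, reference: ReferenceSet) -> tuple[int, str, str]:
    """Minimal leftmost equivalent representation by exhaustive search.

    Enumerates allele pairs of increasing total length (the REF/ALT length
    difference is invariant) and, within a length, increasing position; the
    first rewrite that reproduces the mutated sequence is returned. Intended
    for references up to ~1 kb.
    """
    refseq = reference.require(record.contig)
    seq = refseq.seq
    mutated = apply_variant(seq, record.pos, record.ref, record.alt)
    diff = len(record.ref) - len(record.alt)
    max_total = len(record.ref) + len(record.alt)
    t = max(2, abs(diff) + 2)
    while t <= max_total:
        rlen = (t + diff) // 2
        alen = t - rlen
        if (t + diff) % 2 == 0 and rlen >= 1 and alen >= 1:
            for p in range(1, len(seq) - rlen + 2):
                if seq[: p - 1] != mutated[: p - 1]:
                    break  # prefixes diverge; larger p cannot match either
                ref = seq[p - 1 : p - 1 + rlen]
                alt = mutated[p - 1 : p - 1 + alen]
                if ref != alt and seq[p - 1 + rlen :] == mutated[p - 1 + alen :]:
                    return p, ref, alt
        t += 1
    return record.pos, record.ref, record.alt


def random_case(
    rng: random.Random,
    max_ref_len: int = 300,
    max_indel: int = 10,
) -> tuple[ReferenceSet, VariantRecord]:
    """One random reference + variant pair for oracle cross-checks.

    The contig mixes random background with an occasional embedded repeat
    tract (so ambiguous placements are common, not rare); the variant is a
    random SNV/MNV/insertion/deletion/complex record, sometimes deliberately
    encoded unnormalized (shifted 3' or padded with shared bases). Positions
    stay clear of the contig start so left extension never runs off the end.
    """
    n = rng.randint(60, max_ref_len)
    seq = [rng.choice(_BASES) for _ in range(n)]
    # embed 0-2 repeat tracts to make microhomology frequent
    for _ in range(rng.randint(0, 2)):
        w = rng.randint(1, 4)
        motif = "".join(rng.choice(_BASES) for _ in range(w))
        copies = rng.randint(2, 6)
        start = rng.randint(16, max(16, n - w * copies - 2))
        tract = motif * copies
        seq[start - 1 : start - 1 + len(tract)] = list(tract)
    seq = "".join(seq)
    refs = ReferenceSet()
    refs["rand"] = ReferenceSequence(name="rand", seq=seq)

    kind = rng.choice(["snv", "mnv", "ins", "del", "complex"])
    size = rng.randint(1, max_indel)
    pos = rng.randint(16, n - max_indel - 16)
    if kind == "snv":
        ref = seq[pos - 1]
        alt = rng.choice([b for b in _BASES if b != ref])
    elif kind == "mnv":
        size = max(2, size // 2 + 1)
        ref = seq[pos - 1 : pos - 1 + size]
        alt = "".join(rng.choice(_BASES) for _ in range(size))
        while alt == ref:
            alt = "".join(rng.choice(_BASES) for _ in range(size))
    elif kind == "del":
        ref = seq[pos - 1 : pos - 1 + size + 1]
        alt = ref[0]
    elif kind == "ins":
        ref = seq[pos - 1]
        alt = ref + "".join(rng.choice(_BASES) for _ in range(size))
    else:  # complex: replace a slice with unrelated bases of different length
        rl = rng.randint(2, 5)
        al = rng.randint(1, 5)
        ref = seq[pos - 1 : pos - 1 + rl]
        alt = "".join(rng.choice(_BASES) for _ in range(al))
        while alt == ref or (alt[-1] == ref[-1] and al == 1):
            alt = "".join(rng.choice(_BASES) for _ in range(al))
    # sometimes pad with shared flanking bases so the record arrives unnormalized
    if rng.random() < 0.5:
        pad = rng.randint(1, 3)
        left = seq[pos - 1 - pad : pos - 1]
        end = pos - 1 + len(ref)
        right = seq[end : end + pad]
        ref = left + ref + right
        alt = left + alt + right
        pos -= pad
    return refs, VariantRecord(contig="rand", pos=pos, ref=ref, alt=alt)
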
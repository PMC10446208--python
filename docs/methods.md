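# Methods

This note documents the algorithms, conventions, parameters, and design
choices of `varcontext`, in the order the pipeline runs.

## Input handling

VCF records are read with pysam, split to one ALT per record, uppercased,
and validated against the reference FASTA (REF must match the reference
slice; a mismatch is fatal because it almost always means the wrong genome
build). Symbolic/breakend ALTs and alleles with characters outside A, C, G,
T, N are skipped with a warning. After a multiallelic split, the kept ALT
becomes allele 1 in the genotype, other ALT indices become missing (`.`),
and phase separators are preserved — the record set is split, and per-sample
information is retained without inventing genotypes. Records containing N
are read and annotated literally (N never certifies a base match) but are
excluded from tandem-repeat search, where an unknown base could fabricate
repeat structure. Contig names must match the FASTA exactly; no
`chr`-prefix fuzzing is attempted, since an explicit failure is safer than a
silent mis-mapping.

## Normalization

The normalizer makes each record parsimonious and left-aligned: repeatedly
trim the shared rightmost base of REF and ALT, prepending the reference base
5' of the record (and decrementing the position) whenever either allele
would become empty; then trim shared leftmost bases while both alleles are
longer than one base, incrementing the position. The order matters:
right-trim (with left extension) runs to completion before left-trim, since
interleaving differently can leave a non-left-aligned result. SNVs pass
through; MNVs with no shared prefix/suffix are already parsimonious. If left
extension would step below position 1 (a malformed record at the contig
start), the record is passed through unchanged, flagged unnormalized, with a
warning. Base comparison is case-insensitive; output is uppercase.

Correctness is checked two independent ways in the test suite: a
brute-force oracle that enumerates allele rewrites of increasing total
length (position ascending within a length) and returns the first one
reproducing the mutated molecule; and a mutated-sequence equivalence check
that applies both encodings to the reference.

## Aligned positions and the edge walk

For pure indels the anchor-trimmed pattern is rotated against the reference
bases 3' of the event; each match advances the 3' edge by one base. The
conventions, fixed so that the aligned positions equal the min/max of the
exhaustive placement enumeration:

| variant | 5'-aligned | 3'-aligned | 3' edge |
| --- | --- | --- | --- |
| deletion (anchored at POS) | POS + 1 (first deleted base) | edge − n + 1 (first base of the 3'-most deleted run) | walk result |
| insertion | POS (anchor base) | = edge | walk result (rightmost possible anchor) |
| SNV / MNV / complex | POS | POS | POS + len(REF) − 1 |

`ambiguous` = (5'-aligned ≠ 3'-aligned). The placement shift is
3'-aligned − 5'-aligned; a variant is *in a duplicate* when the shift is at
least the pattern length (at least one complete extra pattern copy adjacent
to the event): a deletion removing one copy of a duplicated run, or an
insertion creating or extending a duplication. For a deletion the 3'-aligned
position is defined as the *first* base of the 3'-most deleted run rather
than a run-end coordinate; this makes shift = 0 ⇔ unambiguous exact and is
the convention the placement-enumeration oracle pins down.

For insertions the aligned positions refer to the base 5' of the insertion
point, with the 5'-aligned position equal to the left-aligned anchor itself.
This keeps the duplicate criterion exact (an insertion next to one existing
copy has shift = pattern length) and matches the enumeration oracle's
minimum over equivalent anchors.

## HGVS, flanks, distances, sequences, BED

HGVS output is DNA-level (`g.`) only and uses the 3'-most representation:
substitutions `g.<pos><ref>><alt>`; deletions `g.<start>_<end>del` over the
3'-most run; insertions become `dup` of the immediately 5' run exactly when
the shift reaches the pattern length (equivalently, a whole copy precedes
the 3'-most site), else `ins` with the pattern as it reads at that
placement; equal-length multi-base and complex changes are `delins`.

Flank reporting returns the n bases 5' of the 5'-aligned position and 3' of
the 3' edge — i.e. flanks of the whole equivalent region, not of `POS` —
plus the region itself under REF and under ALT, truncated at contig ends.

The distance to the next variant counts reference bases strictly between
the current variant's 3' edge and the next variant's 5'-aligned position
(both ambiguity-aware); overlapping spans report 0 with a note. This
convention yields 4 bp for the worked example of a tract-end deletion
followed by an SNV four bases on. Distance annotation requires
position-sorted input, which the CLI verifies per contig.

Region sequence extraction applies all in-region normalized variants
right-to-left to the wildtype substring and also emits the reverse
complement of the mutated sequence (Biopython). Overlapping variants are a
hard error — no precedence among conflicting alleles is defined, and silent
priority would fabricate a haplotype.

BED annotation matches intervals against the closed span
[5'-aligned, 3' edge], so variants partially overlapping or
adjacent-through-ambiguity to an interval are annotated.

## Tandem-repeat engine

The variant site is the coordinate pair bracketing the ambiguity span
(5'-aligned − 1, 3' edge + 1). For each window size w in
[min_unit, max_unit], every w-mer intersecting the site anchors a search.

Unit search: in each round, the w-mers at gap 0…max_gap from the last
accepted unit (5' first, then 3' from the anchor) are scored by
positionwise base identity against the current motif; the highest score wins
(ties to the smallest gap) and is accepted when score ≥
similarity_threshold × w. From the fifth collected unit (anchor included)
the comparison motif becomes the per-column majority consensus of the units
so far, ties resolving to the anchor's base, and keeps updating; after the
search all units' mismatch counts are recomputed against the final
consensus, which is also the reported motif.

Region statistics: copy number = number of units; gap bases = inter-unit
gaps; match + mismatch = copy × w; match% / mismatch% / gap% are over the
region length (so match + mismatch + gap = length exactly).
AlignmentScore = MS·match + MIS·mismatch + GS·gap;
RepeatScore = AlignmentScore / length × copy. The picture is a global
alignment of the region against an ideal perfect repeat of the same motif
and copy number.

QC keeps regions with copy ≥ min_copy(w), match% ≥ min_match_pct, and
alignment score ≥ min_alignment_score. If candidates exist but none passes,
the best-alignment-score candidate is trimmed: remove the 5'- or 3'-tail
unit (whichever removal leaves the higher score; ties trim the 3' tail),
recompute, stop at the first pass, abandon when the copy number falls below
the floor. Note that a perfect rotation of the same tract often passes QC
outright, in which case the trimming fallback never fires — trimming is a
rescue path, not a refinement path.

Redundancy removal ranks survivors by repeat score (ties: copy number)
descending and compares pairs top-down. When overlap/union of two spans
exceeds 0.5 *strictly*, the pair keeps the region whose motif base
composition (fraction vector over A,C,G,T,N) is closest in L1 distance to
its whole-region composition; ties keep the earlier-ranked region. The
union-span denominator is this package's fixed definition of the ratio.
Finally each region gets its GC% over the reference span and the
copy-number change (len(ALT) − len(REF)) / motif length — signed, and
fractional when the indel length is not a motif multiple; 0 for
length-preserving variants.

### Parameters

| parameter | default | meaning |
| --- | --- | --- |
| min_unit / max_unit | 1 / 6 | motif size range (bp), the standard STR range |
| max_gap | one motif length | per-step gap tolerance (bp); settable to a fixed value |
| similarity_threshold | 1.0 | minimum fraction of matching bases for unit acceptance |
| MS / MIS / GS | 2 / −5 / −7 | match / mismatch / gap scores (magnitudes in the style of classic repeat finders; any consistent triple preserves the score identities) |
| min_copy | 3 (profiles: {1:10, 2:5, ≥3:4}) | copy-number floor, scalar or per-motif-size map |
| min_alignment_score | 20 | region-size floor; with MS = 2 encodes a 10 bp minimum STR length |
| min_match_pct | 100 | purity floor |

`TandemRepeatParams.perfect()` is the perfect-STR profile (100% matches,
10 bp minimum region, copies 10/5/4 by motif size);
`imperfect90()` relaxes the match floor and unit similarity to 90%. Note
that for motifs of ≤ 6 bp a 0.9 unit-similarity threshold still demands
perfect units (0.9·w rounds up to w matches), so in practice region
impurity under `imperfect90` enters through gaps and the region-level match
percentage.

Behavioural notes. (1) Because the best-scoring candidate wins, a gap
tolerance that reaches past a mutated unit to the next perfect unit will
jump it; capping `max_gap` below the motif length makes the search absorb
the mutated unit (with mismatches) instead. (2) Every reported region
satisfies the score identities exactly and is recomputable from its stored
counts; the tests enforce this, along with monotonicity (raising a QC floor
never adds regions) and rotation independence of the surviving region.

## Synthetic data

`varcontext.fixtures` generates reference contigs with embedded repeats at
known coordinates and matching VCFs; everything is seeded and reproducible.
Background bases are i.i.d. at a configurable GC fraction (default 0.40,
roughly genomic). Each embedded tract is written verbatim and flanked by
*guard zones* of two motif lengths re-drawn so that (a) the tract-adjacent
base breaks the period and (b) no window inside the zone perfectly matches
any rotation of the motif. The second condition matters because the unit
search tolerates gaps up to one motif length: guarding only the immediately
adjacent base would let the search hop over it into background that happens
to contain a motif copy, corrupting the known copy number. Spiked variants
may deliberately be encoded right-shifted or multiallelic to exercise the
normalizer and splitter.

What the generator does *not* emulate: real genomic base composition
(isochores, CpG depletion), interrupted/nested repeat families, sequencing
or calling artifacts, and genotype structure beyond a single sample. Tests
passing on these fixtures certify the algorithms' correctness against their
definitions and oracles — not calling performance on real data.

The oracles are exhaustive by construction and size-capped (references of a
few hundred bp): equivalent-placement enumeration tries every same-length
placement and keeps those reproducing the mutated molecule;
minimal-representation search tries allele pairs of increasing total length
and increasing position. Oracle-vs-implementation agreement is asserted
exactly, at 10⁴ random cases per property in the test suite and 5 × 10³ in
the acceptance script (a few seconds of runtime; the case generator embeds
repeat tracts so ambiguous placements are common rather than rare).

## Degenerate inputs and numerics

Empty or equal alleles and non-positive positions are rejected at record
construction. Windows truncated by contig ends are omitted from candidate
motifs; flanks truncate silently. All scores are plain floats; QC
comparisons use a 1e-9 slack so user-supplied floating-point thresholds
(e.g. a 2/3 similarity) behave as written. Annotation is fully
deterministic: identical inputs and parameters produce byte-identical
outputs, and every tie in the repeat engine (equal unit scores, equal trim
scores, equal redundancy rank or composition distance) has a fixed,
documented resolution.

## Known limitations

* HGVS output is genomic (`g.`) only — no transcript-level c./p.
  descriptions, no normalization against transcript orientation.
* No structural-variant (symbolic ALT) support; no haplotype-aware
  normalization across records; mutated-sequence extraction ignores
  genotypes (all in-region ALTs are applied).
* The repeat engine searches variant sites only; it is not a genome-wide
  repeat scanner, and very long or heavily interrupted repeats adjacent to
  a site may be reported in trimmed form only.
* Right-alignment mode is not provided.
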
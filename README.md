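# varcontext

Sequence-context annotation of genomic variants from a VCF and a reference
FASTA: variant normalization, indel breakpoint ambiguity, HGVS DNA
nomenclature, flanking bases, inter-variant distances, wildtype/mutated
sequence extraction, custom BED annotation, and tandem-repeat discovery at
variant sites.

## Who this is for

Analysts of short-variant call sets who need to know *where a variant really
sits*. An indel inside repeated sequence (microhomology) has many equivalent
VCF encodings — the reported `POS` is one placement among several, the
breakpoint cannot be identified uniquely, and downstream annotations that
look only at `POS` miss partial overlaps with short tandem repeats (STRs).
`varcontext` quantifies this ambiguity per variant and discovers the repeat
context directly from the reference, with user-controllable repeat
definitions.

## The model

**Normalization.** Every record is split to biallelic form and made
*parsimonious* (fewest nucleotides, no zero-length allele) and *left-aligned*
(no further 5' shift possible at constant allele lengths): shared trailing
bases are trimmed (prepending the 5' reference base whenever an allele would
empty), then shared leading bases are trimmed.

**Breakpoint ambiguity.** For a normalized pure indel with anchor-trimmed
pattern (a₁…a_n), the pattern is compared against the reference bases r₁,r₂,…
immediately 3' of the event: while a₁ = r₁ the pattern rotates left by one
and the affected region extends one base 3'. This yields

* the **3' edge** — rightmost reference base the variant can affect;
* the **5'-aligned position** — leftmost equivalent placement (first deleted
  base, or the insertion's anchor base);
* the **3'-aligned position** — rightmost equivalent placement
  (edge − n + 1 for deletions; the edge itself for insertions).

A variant is **ambiguous** when the 5'- and 3'-aligned positions differ, and
**in a duplicate** when the placement shift covers at least one whole pattern
copy. SNV, MNV and complex records (e.g. REF `CATTC` → ALT `G`) have a single
fixed placement. HGVS `g.` descriptions follow the 3' rule (`del`, `dup`,
`ins`, `delins`) built from these coordinates.

**Tandem-repeat discovery.** Each variant's ambiguity span defines a search
site; every k-mer (k = 1…6 by default) touching the site seeds a unit search
in both directions, accepting the best positionwise-matching unit within a
gap tolerance of one motif length per step (consensus motif updating from
the fifth unit on). Candidate regions are scored

    AlignmentScore = MS·match + MIS·mismatch + GS·gap          (default 2 / −5 / −7)
    RepeatScore    = AlignmentScore / region length × copy number

quality-controlled by minimum copy number, match percentage, and alignment
score (with tail trimming as a fallback), and de-duplicated by an
overlap/union redundancy ratio (> 0.5 drops the less motif-representative
region). The shipped `perfect` profile requires 100% unit identity, a 10 bp
minimum region, and minimum copies 10/5/4 for mono-/di-/longer motifs; the
`imperfect90` profile relaxes matches to 90%.

## Worked example

Build a 400 bp synthetic contig with a (GC)₇ tract at positions 123–136, a
right-shifted GC deletion inside it, and an SNV four bases past the tract
(the `varcontext.fixtures` module generates such files programmatically),
then:

```bash
varcontext --vcf demo.vcf --ref demo.fa --out demo \
    --ambiguity --hgvs --distance --tandem-repeat --profile perfect
```

`demo.tsv` (columns abbreviated):

```
CHROM    POS  ID     REF  ALT  FIVE  THREE  EDGE  AMBIG  IN_DUP  HGVS                  DIST  TR_MOTIF  TR_COPY  TR_GC_PCT  TR_COPY_CHANGE
chr_fix  122  gcdel  TGC  T    123   135    136   yes    yes     chr_fix:g.135_136del  4     GC        7        100        -1
chr_fix  141  snv1   C    G    141   141    141   no     no      chr_fix:g.141C>G      .     .         .        .          .
```

Reading the first row: the deletion (VCF `POS` 129 on input) normalizes to
anchor 122; the deleted GC can sit anywhere in the tract — first deleted base
123 through 135, affecting bases up to 136 — so the breakpoint is ambiguous
and the deletion removes one copy of a duplicated unit. HGVS places it
3'-most (`g.135_136del`). The repeat engine reports the tract: motif GC,
7 copies, GC% 100, and a copy-number change of −1 caused by the deletion.
Four reference bases separate the tract's 3' edge from the next variant.

Other switches: `--flank N` (flanks plus the full equivalent region under
REF and ALT), `--region contig:start-end` (writes wildtype, mutated, and
reverse-complemented-mutated FASTA), `--bed file.bed` (custom interval
labels, matched against the ambiguity span, not `POS` alone).

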
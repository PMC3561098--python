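# Methods

## Scope and data model

Everything operates on circular nucleotide sequences (`CircularSeq`) with
1-based inclusive coordinates; an interval with start > end wraps across the
origin and spans L − start + 1 + end positions. This convention matches how
mitotype papers print feature tables, and it is checked by enumeration in
the test suite. BED export converts to 0-based half-open at the boundary
only. N bases are excluded from GC content and never seed alignments.

## One aligner for every similarity question

All similarity stages (synteny, repeats, unique-region coverage, plastid
segments, ORF sharedness, CDS location) run through a single seeded local
aligner so that "percent identity" means the same thing everywhere:
identical columns divided by alignment columns, with gap columns counting
against. The design is the classic seed-and-extend stack:

1. **Seeds.** Exact k-mers (default k = 12; k = 8 for short-repeat
   detection, where 30 bp copies at 90% identity may lack an exact 12-mer).
   K-mers occurring more than 200 times in the target are skipped.
2. **Two-hit runs.** Hits are grouped per diagonal; a group needs at least
   two hits within 100 bp (single random k-mer hits are overwhelmingly
   noise at genome scale). Run identity is computed exactly by comparing
   the two equal-length substrings.
3. **Chaining.** Co-linear runs with both gaps ≤ 100 bp are chained
   greedily; each gap is closed with the exact global aligner so column
   accounting stays exact. A join is declined if it would drop the chain
   below the reporting identity threshold — chaining must never turn a
   reportable match unreportable. (Without this guard, random nearby runs
   get welded onto clean short matches through ~50%-identity gap columns;
   plant-and-recover exposed exactly this failure.)
4. **Extension.** Chain ends are extended ungapped under an X-drop rule
   (X = 20). The extension mismatch penalty is scaled to the reporting
   threshold θ as −θ/(1−θ) (−1 at 50%, −9 at 90%, −19 at 95%): a +1/−1
   walk would happily append ~50%-identity tails and dilute borderline
   matches below θ.

Circularity follows the doubled-query convention: the query is doubled
internally, chains starting beyond L are dropped as duplicates, and a
post-origin tail reported a second time (the "shadow" of a wrapping match)
is removed by containment. Matches crossing the *target* origin are
reported split; none of the downstream statistics depend on joining them.

`align_pair` is exact Needleman–Wunsch with linear gap costs (+1 match,
−1 mismatch, −2 gap), row-vectorized, with deterministic tie-breaking
(substitution over gap, gap in the second sequence over gap in the first)
and a 20 kb cap — beyond that the quadratic memory is the limit, and the
seeded engine is the right tool. In tests it is the independent oracle the
seeded matches are held to (agreement within 1 identity point on ≤ 2 kb
pairs).

## Synteny

Matches ≥ 1 kb at ≥ 95% identity (the conventional mitotype criterion) are
the regions; overlapping candidates on the focal genome are resolved in
favour of the higher-scoring region, the other being trimmed to ≤ 50 bp
overlap and dropped if it falls below the length floor. Labels S1… follow
focal-genome coordinate order; they are coordinate labels, not identities
across runs. Region identity is the column-weighted value of the chained
match. Coverage is the union span over the genome length, wraparound-aware.

## Repeats and recombination

Repeats are reported as *pairs* of disjoint copies (direct or inverted,
canonical order iv1 before iv2, mirrored duplicates removed); tandem
(overlapping) arrangements are a different phenomenon and are excluded.
Published counts of "n repeats" are ambiguous between copies and pairs; a
pair count is used here because pairs are the recombination substrate (a
62-pair catalogue corresponds to ~124 copies). Large repeats (≥ 1 kb at
≥ 95%) are kept separate from short ones (30–500 bp at ≥ 90%): the large
class drives the multipartite structure, the short class smaller
rearrangements.

Subgenomic circles from a direct pair are measured start-of-copy to
start-of-copy, so each product keeps exactly one fused repeat copy and the
two sizes sum to L exactly. The inverted-pair isomer reverse-complements
the arc strictly between the copies; applying it twice restores the
original (rotation-normalized equality via lexicographically minimal
rotation). Junction explanations test every repeat pair for copies within a
flank window (default 500 bp, covering the sub-kilobase displacements seen
in mitotype comparisons) of *both* focal-side breakpoints of a syntenic
junction; all candidates within 4× the window are reported with offsets,
and a junction with no candidate is still listed, unexplained.

## Unique regions and plastid segments

Uniqueness asks for the *absence of any appreciable homology*, so coverage
thresholds sit far below the synteny regime: a focal position is covered by
a comparator if a match ≥ 50 bp at ≥ 70% identity spans it. The unique set
is the intersection of uncovered sets across all comparators, as maximal
runs ≥ 400 bp (the floor keeps point noise and repeat-planting scars out
while admitting the ~445 bp scale of the smallest published unique region).
Runs separated by any covered stretch stay separate. A comparator identical
to the focal genome trivially covers everything. Unique regions inside
duplicated repeats appear once per copy, as published tables do.

Plastid-derived segments are matches to the chloroplast genome at ≥ 95%
identity and ≥ 100 bp, labelled by length descending. Fractions are sums of
segment lengths over L.

## Gene-level comparisons

SNP calling is substitution-only on pre-trimmed equal-length CDSs (indels
are boundary-shift territory); codons with several substitutions are
translated jointly and each site emits a record carrying the joint effect.
Translation uses the standard genetic code (plant mitochondria use it;
configurable). Transition means purine↔purine or pyrimidine↔pyrimidine.
The package ships the published 39-row cybrid-vs-nap SNP table
(`load_reference_snp_table`); the running text of the source claims 40 SNPs
(13 synonymous + 27 non-synonymous) while its printed rows give 39
(13 + 26) — the printed rows are encoded verbatim (one "trnasition" typo
normalized) and the discrepancy is left as a property of the source.

Boundary-shift detection locates the reference CDS in the alternative
genome (≥ 90% identity core match), then scans in frame. 3′: if the
orthologous stop codon is disrupted, the next in-frame stop k codons
downstream gives a 3k bp extension. 5′: the longest upstream in-frame
ATG-led open extension is computed in *both* genomes and a shift is
reported only when they differ — an unmodified ortholog can coincidentally
carry an upstream in-frame ATG before the first stop, and the differential
rule keeps that from being called a shift. Single-interval (unspliced)
gene models only.

ORF finding is six-frame ATG-to-stop with the stop codon included in the
length (so a 303 bp minimum is a whole number of codons), longest ORF per
(stop, frame), wraparound-aware on circles. The transmembrane predictor is
Kyte–Doolittle mean hydropathy over a 19-residue window with threshold 1.6
— the canonical setting for membrane-span scanning. The CMS screen ranks
ORFs by the three classic criteria (mitotype-unique, membrane-spanning,
within 2 kb of a functional gene); overlapping reading frames inside one
introgression can all satisfy the criteria, and resolving them is transcript
work outside this package's scope.

## The synthetic cybrid generator

The generator emulates the inferred history of a cybrid mitogenome and is
the package's ground truth at full scale (the preset yields exactly
258,473 bp):

- recipient backbone: i.i.d. bases at GC 0.4521, carrying 23 planted
  protein-coding genes (random sense-codon CDSs, 110–480 codons, ≥ 700 bp
  clear on both sides) — no higher-order composition structure, a
  documented limitation;
- plastid segments (printed-table lengths 2196…178 bp, GC 0.37 source) are
  written into the *recipient*, because every mitotype of the genus carries
  them — so comparators inherit them and they never masquerade as unique;
- comparators: recipient + 0.5% substitutions + up to 3 neutral block
  moves, no donor content — a clean negative set for uniqueness;
- cybrid: the recipient cut into 8 blocks (cuts clear of genes and plastid
  segments), permuted with 3 inversions; 310 and 232 bp mediator repeats
  written beside broken-adjacency breakpoints; 11 donor segments (printed
  lengths 2×2220, 2×469, 5130, 1052, 445, 3572, 2700, 3828, 879 — 8.89% of
  the final circle) and one duplicated 9,731 bp large repeat inserted at
  block splits; ~60 background short repeat pairs (50–350 bp, identities
  0.90–0.95, fresh random content so they match nothing but each other —
  their union is ~6% of the genome, matching the published short-repeat
  scale, and they stay below the 400 bp unique-region floor by
  construction); 40 coding SNPs at transition fraction 29/40; a +27 bp 3′
  stop displacement and a +498 bp 5′ start extension. Repeats and boundary
  shifts are *overwrites* of background sequence, so the final length is
  exactly recipient + Σdonor + large-repeat. The 5′ extension minimally
  edits the existing upstream context (stop codons removed, ATG and a stop
  guard written) so the region still matches the comparators and does not
  leak into the unique set. One orf138-like chimeric ORF (138 codons with a
  25-residue hydrophobic block) is written near the edge of the largest
  donor segment, deliberately within ~1.2 kb of a functional gene.

All randomness flows from a single seeded generator; the same seed gives
byte-identical genomes and truth. What passing recovery tests on this
generator shows: the detectors find what they are defined to find at the
published scales and thresholds, with near-exact boundaries. What they do
not show: performance on real genomes' skewed composition, nested repeat
families, RNA-level features, or homology below the configured noise
models.

## Problem sizes and numerical choices

The default validation scale is the full 258 kb preset for the comparative
stages (a few seconds per genome pair on one core) and 30–60 kb genomes for
repeated plant-and-recover rounds. Recovery scoring matches called to
planted intervals at reciprocal overlap ≥ 0.8 with both boundary errors
within tolerance (100 bp for unique regions; detector accuracy in practice
is ~0–2 bp). Reported percentages use half-even rounding to two decimals.
Ties in alignment scoring are broken deterministically; output orderings
are total (coordinates, then strand), so reruns are byte-identical.

## Known limitations

- The seeded aligner reports target-origin-crossing matches as two pieces.
- `_trim_match` shifts the partner interval linearly when resolving synteny
  overlaps — exact for ungapped chains, approximate across indels.
- Repeat families with > 2 copies are reported as all qualifying pairs,
  not clustered.
- The simulator's comparator noise is substitutions + block moves only (no
  indel noise), and its backbone is i.i.d. sequence; both make recovery
  cleaner than on real data.
- Published mitotype percentages (coverage, repeat fractions) from the
  original programs are not exactly reproducible — their identity
  definitions differ from each other and from this package's single
  definition; the printed-table *length arithmetic* (8.89%, 2.88%) is
  reproduced exactly. The source also prints one large repeat as 9713 bp
  where its text says 9731 bp; 9731 is treated as canonical here, and two
  unique-region rows whose printed lengths disagree with their printed
  coordinates by 1–2 bp follow coordinate arithmetic.
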
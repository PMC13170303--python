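# Methods

## Alignment conventions

All identity values trace back to one convention: a local affine-gap
(Gotoh) alignment scored with match +2, mismatch −3, gap open −5, gap extend
−2 (a gap of length L costs `open + (L−1)·extend`), and percent identity
`100 · matches / alignment columns`, gap columns counted in the denominator.
This is the conservative "pairwise identity" convention of common alignment
viewers: indels dilute identity instead of disappearing. `N` never matches
anything, including another `N`.

Ties between equal-scoring local alignments are broken deterministically:
smallest subject start, then smallest query start, then fewest columns
(implemented by tracing back from every tied end cell, capped at the first 64
in scan order, which already favours small end coordinates). Scores are
exactly symmetric in the argument order; the identity of the reported
alignment is symmetric for homologous pairs but can differ between
equal-scoring alternatives when the two sequences are unrelated — the
symmetry property is therefore only asserted for diverged-copy pairs.

### Seeded search

The genome-scale search seeds on exact words plus, for queries under 200 bp,
their one-substitution neighbours (word size 7 by default — the short-query
convention appropriate to ~51 bp satellite monomers; gene annotation uses
word size 11 with exact seeds only). Seeds are clustered by diagonal; each
cluster is resolved by the exact kernel on a padded subject window. Because
tandem copies of the query yield clusters whose windows may span several
copies, the best alignment is carved out of the window and the flanking
segments are re-aligned until no near-qualifying alignment remains — this is
what makes per-copy recovery of dense tandem arrays reliable. Long queries
require at least 8 seeds per cluster (3 for 200–1000 bp); a genuine hit at
80% identity over even 200 bp expects ~17 exact 11-mers, so the guard
discards chance clusters without costing sensitivity.

Filtering uses only percent identity and query coverage — the satellite
classification criteria themselves. No E-values are computed; at these query
lengths and the 50% identity floor, deterministic filters are both simpler
and reproducible.

### Star alignment

Monomers are aligned to a designated centre with a global edit-distance
alignment (edlib) and projected onto the centre's coordinate frame: the
frame has exactly one column per centre base, deletions appear as gaps, and
insertions relative to the centre are dropped. Column counts of the
resulting position frequency matrix always sum to the number of sequences.
The majority-rule consensus breaks base ties alphabetically and drops
columns where the gap is the strict majority.

## Array reconstruction

The 5.8S gene anchors the search: it is short, occurs once per unit, and is
conserved enough that one reference works across distant taxa. Anchor hits on
a contig are merged whenever the inter-hit distance is at most `max_gap`
(default 50 kb — above the longest plausible unit, ~33 kb, and below typical
inter-locus distances), then extended by `flank` (default 8 kb). The flank
must exceed the anchor-to-unit-end distance (ITS2 + 28S + 3'ETS + IGS ≈ 7.1 kb
under the default subunit sizes) or terminal units lose their spacer; 8 kb
leaves ~1 kb of margin. Minus-orientation regions are reverse-complemented on
extraction so annotation always reads in the 18S→28S sense. Regions on
different contigs are never merged.

## Unit annotation

Units are phased at the 18S start: a unit runs from its 18S start to the base
before the next 18S (the last unit to the array end). This makes annotation
deterministic without RNA-seq; the 5'ETS recovered later by coverage simply
lands in the preceding unit's span and is reassigned. Hits of one gene
separated by ≤ 800 bp are chained into a single gene interval, which is what
lets an 18S split by a ≤ 430 bp satellite insertion surface as one gene copy
spanning the insertion; fragments must align ≥ 30 query bases to join a chain
(chance word matches must not seed chains) and a chained copy must cover
≥ 50% of the reference at ≥ 80% identity. Units missing a gene, or with genes
out of canonical order, are flagged incomplete and never silently repaired.

The unit consensus star-aligns all complete units onto the median-length
unit. Within a tandem array the units differ only by their satellite copies
(concerted evolution keeps the rest homogeneous), so the consensus length
tracks the unit length to well under 1%.

## IGS delimitation from coverage

Pre-rRNA transcription covers 5'ETS through 3'ETS; the IGS is silent. Reads
are placed at their best location (exact occurrences by word lookup; inexact
reads by the seeded aligner at ≥ 90% identity; multi-mappers leftmost), and
the transcribed region is extended outward from the 18S start and the 28S
end while depth exceeds `rel_threshold ×` median gene depth.

The default `rel_threshold` is 0.001 — deliberately far below typical
ETS:gene coverage ratios (~1:10). Two facts drive this. First, a threshold
at 0.1 of the gene median sits exactly at a 10:1 ETS plateau, so the scan
would stop at the gene edge. Second, coverage ramps linearly over one read
length at each transcript end, so any threshold T placed within the ramp
biases the boundary inward by roughly `T / read-start rate` bases. With zero
IGS transcription, the informative signal is the edge of the zero-coverage
run, and a threshold just above zero tracks it with mean error
`read_length / ETS depth` bases. The parameter exists for noisy real tracks
(background multi-mapping), where it should be raised. Coverage can also be
ingested from a SAM/BAM or a per-position depth TSV in place of the internal
read placement.

For species without RNA-seq, the fallback rule reports everything between
one unit's 28S end and the next unit's 18S start as the spacer (which then
also contains the undelimited ETS regions — the two IGS flavours are marked
by a `method` field and should not be mixed in cross-species comparisons).

## Satellite scanning

Monomer detection applies the field's classification criteria directly:
identity to the consensus ≥ 50%, query coverage ≥ 60%, both strands; hits
overlapping a higher-identity hit by more than half of the shorter are
removed; monomer length is reported but never filtered on. Tandem groups
join consecutive same-strand hits separated by at most one consensus length
(51 bp by default). "Variants" are operationalised as orientation-normalised,
exactly deduplicated monomer sequences, consistent with unique-monomer
counting. Degenerate-unit discovery partitions genome-wide hits into
inside/outside annotated 45S regions (the interval-subtraction step) and
reports any 18S gene copy holding ≥ 2 interior tandem monomers, with count
and span — a declared, automatic substitute for manual inspection of such
loci.

A consequence of the 50% floor worth knowing: random sequence contains
occasional ~30–40 bp stretches at 60–75% identity to any short AT-rich
consensus. These are genuine matches under the criteria (real genomes show
the same background), but they have no planted counterpart, so the
validation scores planted-monomer precision within the spacer compartment
where monomers are planted.

## Dotplots and sub-repeats

Dotplots record maximal runs of matching words (default word size 10; ≤ 1
mismatch via wobble enumeration) in both senses, reverse-sense matches on
forward coordinates. Self-dotplots of spacers show the tandem structure as
off-diagonal lines; the sub-repeat report groups forward off-diagonal
matches by lag, reports the union span per lag and `span // lag` repeats,
and suppresses lags below a minimum block size (50 bp), which keeps random
sequence silent at these word sizes.

## Cross-species statistics

Shapiro–Wilk (scipy) screens normality; association is then quantified by
Spearman's ρ on midranks, with the t approximation on n−2 degrees of freedom
for the p-value (an exact permutation p is available for n ≤ 8; full
enumeration beyond that costs more than it informs). Significance is α =
0.05. The per-species summary table refuses duplicate labels and leaves
missing fields blank rather than imputing.

## The synthetic locus generator

`SimConfig` defaults define the study conditions: three arrays of 5/11/22
units on one contig; subunit sizes 800 / 1800 / 350 / 160 / 300 / 4000 / 400
bp (5'ETS, 18S, ITS1, 5.8S, ITS2, 28S, 3'ETS) and a 2,380 bp IGS — the
cross-species median magnitude — giving a ~10.2 kb unit, compact-genome-like;
12 satellite monomers per IGS at 5% per-base divergence, drawn from 6
template variants of a packaged 51 bp AT-rich monomer (a synthetic stand-in
sequence, not the real As51 consensus; users supply their own FASTA for real
analyses); inter-array gaps of 65 kb so that distinct arrays stay distinct
under the default merge radius. Substitutions are uniform; 1–3 bp indels are
available behind `indel_rate` (default 0). The IGS background and the array
offset are species-level templates (tandem units homogenise by concerted
evolution), while each monomer copy re-mutates independently. Degenerate
units — 18S with a 4–6-monomer interior array spanning ≤ 430 bp inserted
150–250 bp after the gene start, diverged subunits, 28S truncated to 30% —
are placed one inter-array gap away from the arrays, as the dispersed copies
in real assemblies are. Everything is reproducible byte-for-byte per seed,
and the truth manifest records every planted coordinate, template variant
and realized divergence.

Transcriptome reads are sampled from the transcribed span only, with the
gene interior at `read_depth`-fold coverage (default 400×; rRNA dominates
total-RNA libraries, and the 5'ETS boundary error is read-start-rate
limited — mean error ≈ read_length / ETS-depth bp, so ETS depth needs to be
well above 10× for ~2 bp precision) and the ETS at one tenth of that. Reads
carry no sequencing errors.

What the generator does **not** emulate: sequencing error, assembly
collapse of near-identical units, unit-length heterogeneity within an
array, transposable-element insertions in the IGS, pseudogenised 5S decoys
beyond a cosmetic block, or population-level copy-number variation. Passing
tests therefore demonstrate that the pipeline's logic is correct under its
structural assumptions, not that those assumptions hold for any particular
real assembly.

## Validation design

The validation suite regenerates data from seeds and scores recovery against
the manifests: (i) seeded-search intervals against an exhaustive
masking Smith–Waterman oracle on 1,000 random monomer-length pairs (half with
planted copies at ≤ 20% divergence); (ii) end-to-end recovery on 20 replicate
genomes (array and unit counts exact; gene boundaries, effectively exact at
zero gene divergence; IGS boundary mean absolute error ≤ 10 bp — the mean is
used because finite-coverage boundary estimates have exponential tails);
(iii) degenerate-locus detection with exact monomer counts on 20 replicates;
(iv) Spearman ρ = 1 recovery on a 19-species panel whose unit length varies
only through the IGS (drawn 295–21,311 bp, the observed cross-species
extremes), plus robustness to σ = 500 bp measurement noise; (v) a 0–40%
divergence sweep in which detected identity decreases and detection
vanishes below the 50% identity floor. Problem sizes are the package's own
defaults throughout.

## Known limitations

* Unit walking assumes orientation-normalised arrays; palindromic or
  mixed-orientation arrays are flagged `mixed` and annotated on the plus
  sense only.
* The coverage-based boundary rule assumes zero (or near-zero) IGS
  transcription; pervasive readthrough would require raising the threshold
  and accepting ramp bias.
* Exact-string deduplication of monomer variants is conservative: at high
  divergence nearly every copy is unique, so unique-monomer counts approach
  total counts.
* The flank-fallback IGS includes the ETS regions by construction.
* Smith–Waterman memory is one byte per DP cell; queries beyond ~10 kb
  against large windows should be chunked by the caller.
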
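# Methods

This note documents the conventions, models and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates, strands and the model

All external coordinates are 1-based inclusive, matching published
annotation tables; features never wrap the circular origin (none do in
the bundled annotations, and wrapping inputs are rejected). Strand
symbols `+`/`J` and `−`/`-`/`N` are normalized to `J` (majority) and `N`
(minority). A gene's coding-sense sequence is the direct slice for
J-strand genes and the reverse complement for N-strand genes, so PCGs
always read 5'→3' in mRNA sense.

## Annotation geometry

For consecutive features in start order, the signed junction gap is
`start(downstream) − end(upstream) − 1`: positive values are intergenic
spacers, negative values overlaps (reported as positive magnitudes),
zero exact adjacency. The circular junction from the control region back
to the first gene is **not** emitted: annotation tables carry no
intergenic entry for it, and the published spacer-location counts (22
and 19) are reproducible only under this convention. Category length
totals sum `end − start + 1` per gene with no overlap deduplication,
matching how the published tables total their length columns.

Stop codons are classified purely from the annotated length: `length mod
3 = 0` requires a trailing `TAA`/`TAG` (complete), `mod 3 = 2` a trailing
`TA`, `mod 3 = 1` a trailing `T` (incomplete); anything else is an error
naming the gene. No scanning beyond the annotated boundary is done.

The bundled fixtures are verbatim transcriptions of the two hoverfly
annotation tables. Cross-checking them exposed three internal
inconsistencies, all asserted explicitly in the tests with the
coordinate-derived value treated as truth: the prose spacer totals (255
and 230 bp) disagree with the coordinate sums (230 and 213 bp); the
partial genome's printed PCG total (11,211 bp) disagrees with its
coordinate sum (11,213 bp); and one intergenic cell (trnS2, partial
genome) prints 17 where its own coordinates give 16.

## Gene order and breakpoints

An arrangement is the circular, strand-aware gene order with the control
region excluded, canonically rotated to begin at trnI (or at the
lexicographically smallest token if trnI is absent). The ancestral
insect arrangement ships as a constant (23 J / 14 N genes). Breakpoint
distance counts signed adjacencies of one arrangement absent from the
other; adjacency (x→y) also matches its opposite-strand reading
(−y→−x), so the measure is invariant to reading the circle from the
other strand, symmetric, and zero exactly for identical circular
arrangements. No rearrangement-event reconstruction is attempted.

## Composition and skews

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), on integer counts or on
already-tabulated percentages. Ambiguous IUPAC bases are excluded from
every denominator and tallied separately (not fractionally allocated —
the simplest defensible rule, and flagged in the profile). Region
composition concatenates coding-sense gene sequences in genomic order;
this mRNA-sense convention is what gives fly PCG sets their
characteristic negative GC-skew. Reported percentages round to 2
decimals and skews to 4, the print precision of the source table. Of the
15 panel species, only a minority of printed skews reproduce exactly
from the printed 2-decimal percentages (the originals were evidently
computed from unrounded counts); the recomputed-from-percentages value
is the one this package reports, and `analysis/02_composition_skews.py`
lists every cell that differs.

## Codon usage

Counting reads non-overlapping triplets from position 1 of each
coding-sense PCG; trailing 1–2 nt (incomplete stops) are discarded, not
padded, and codons containing ambiguity symbols are tallied but not
counted. Stop codons are counted separately and excluded from RSCU
families. The invertebrate mitochondrial code (table 5: AGA/AGG → Ser,
TGA → Trp, ATA → Met; Ser family size 8, Leu 6) is shipped as data via
Biopython's codon tables, not computed. Start codons are counted as
ordinary codons — no ATN-as-Met special-casing — so results match the
default behaviour of classic codon-usage tools. RSCU of a codon is its
count divided by its family's mean count; unused families are reported
as all-zero rather than undefined.

## Nucleotide diversity

Pi is the unweighted mean of pairwise p-distances over all C(n,2)
unordered pairs — the interspecific quantity appropriate to
one-sequence-per-species panels; no n/(n−1) sample correction and no
frequency weighting. Gapped or ambiguous columns are removed per pair
(pairwise deletion, maximizing comparable sites). Pi(JC) applies
d = −(3/4)·ln(1 − (4/3)p) to each pair before averaging
(correct-then-average): by Jensen's inequality this differs from
correcting the mean, and the per-pair form is the standard usage.
Pairs with no comparable sites are skipped with a warning; p ≥ 0.75 is a
saturation error. Records sort ascending by Pi with ties broken by gene
token, so rankings are deterministic.

## tRNA clover-leaves

Structures are inputs (dot-bracket beside the sequence), never
predicted. A clover-leaf is exactly four helices: the outermost
(acceptor/AA) stem enclosing, left to right, the DHU, anticodon and TΨC
arms, with the variable loop between the anticodon and TΨC arms; helices
are maximal stacked runs, square/curly brackets are rejected as
pseudoknots, and any other helix count or nesting is "not clover-leaf".
The anticodon is read at positions 3–5 of the 7-nt anticodon loop. A
stem pair is a mismatch iff outside {A·U, U·A, G·C, C·G, G·U, U·G} — G·U
wobble is canonical, consistent with mismatch inventories that list only
U-U and A-A pairs. Stem variability across a homolog panel counts
alignment columns (mapped from the ungapped reference's paired
positions) with more than one distinct non-gap nucleotide — distinct
states, not substitution events.

The 22 bundled templates are synthetic: built deterministically from a
per-tRNA arm-length plan chosen so each template's total length equals
the corresponding real gene length (64–72 bp) and all arms fall in the
observed ranges (AA stem 7 bp, AC loop 7 nt, DHU stem 2–4 bp — here 3 —
AC stem 4–5, TΨC stem 3–5, variable loop 4–8 nt), with fully
Watson–Crick stems and the real anticodons. Real per-species mismatch
totals require the real sequences and predicted structures, which are
out of scope; the mismatch machinery is validated by injection instead.
Degenerate DHU "stems" of length 0 (a bare loop, common in metazoan
mitochondrial tRNAs) are representable but not used by the templates.

## Phylogenetic preparation

Genes concatenate in the ancestral gene order (a fixed, documented
choice; the order does not affect any statistic, only column
coordinates). Taxa missing a gene receive an all-gap block rather than
being dropped, mirroring how partially sequenced taxa are retained in
practice. Partitions are 1-based inclusive and must tile the matrix;
RAxML (`DNA, gene = a-b`) and NEXUS (`charset gene = a-b;`) exports are
byte-deterministic. JC distances use the same p-distance/correction code
as the diversity module. Neighbor joining follows the Saitou–Nei Q
criterion with ties broken by the lowest index pair, negative
branch-length estimates clamped to zero with a warning, and branch
lengths printed to 6 decimals; on additive matrices it recovers the
generating tree exactly (verified against an exhaustive 4- and 5-taxon
topology enumeration and against an independent implementation).
Model selection and Bayesian/ML inference are export targets, not
reimplemented; the NJ tree is a sanity check only.

## Synthetic-data generator

Defaults are the real complete-genome study conditions: the 37 gene
lengths, intergenic gaps (including the real overlaps), strands,
anticodons and start codons of the complete hoverfly annotation, a
1,129 bp control region, total length 16,175 bp. PCGs are start codon +
body codons drawn i.i.d. from a codon-weight table + stop; the default
weights are `exp(β·#AT)` per sense codon with a 4× boost for
TTA/ATT/TTT/ATA, with β solved deterministically (Brent's method) so the
expected body A+T fraction is 78.85% — the real PCG A+T content. rRNA,
control-region and intergenic bases are i.i.d. draws at A+T ≈ 84.6%,
85% and 82% respectively; tRNAs are instantiated from the clover-leaf
templates. Features are written in genomic order, so at real overlap
junctions the downstream feature overwrites shared bases; a final pass
re-forces every PCG's start and stop codon, which can perturb up to a
few bases of an overlapping neighbour (exactly as real overlapping genes
share sequence). Realized PCG A+T therefore scatters around target with
SD ≈ 0.2 points per genome at 11 kb plus a ~+0.1 point contribution from
the AT-rich forced termini; recovery tests average a handful of seeds.

Evolution along a Newick tree is site-wise Jukes–Cantor: substitution
probability p = (3/4)(1 − e^(−4·d·r/3)) for branch length d and per-site
rate multiplier r (per-gene multipliers; later features win where genes
overlap; PCG start/stop positions are masked immutable, i.e. ~78 of
11,220 coding sites). There are no indels, so per-gene panels are exact
alignments by construction — diversity and phylogeny tests isolate the
statistics, not an aligner. The default rate multipliers span 0.40
(cox1) to 1.60 (atp8), emulating the observed slow
cytochrome/nad1–fast atp8/nad2 ordering with 13 distinct values so rank
recovery is well-defined. One seeded numpy generator per operation
(genome synthesis and tree evolution use independent streams derived
from the same seed); identical config + seed gives byte-identical
output.

What the generator does **not** emulate: indels and alignment
uncertainty, secondary-structure-aware rRNA/tRNA evolution, composition
drift along branches, codon-position rate structure within genes, and
selection. Passing tests on synthetic panels therefore validate the
statistics and their parameter recovery under the stated model — they do
not certify behaviour on real, indel-containing alignments.

## Problem sizes and tolerances

Simulation-based checks use the default 16.2 kb genome: two-taxon JC
recovery is checked on the ~11.2 kb concatenated PCG set within 3
standard errors (delta-method SE plus the small masked-termini bias);
rate-ranking recovery uses the 5-taxon default tree and 10 seeds (mean
Spearman ρ ≥ 0.9); NJ split recovery uses 50 seeded 4-taxon panels
(internal branch 0.1, tips 0.05, ~14.8 kb of genes) requiring ≥ 95%
recovery. Skew antisymmetry and RSCU conservation properties are checked
over 1,000 random inputs each. The whole suite runs in well under a
minute.
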
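# Methods

This note documents the models, conventions and numerical choices
behind each stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Sequence conventions

All sequences are stored DNA-style (U→T) in one {A,C,G,T} alphabet so
reads, mature miRNAs, transcripts and repeats compare directly.  Every
coordinate in every output is 1-based inclusive on the forward strand
of the named reference; minus-strand siRNA alignments are *printed*
high→low (e.g. `157-139`) but stored internally as (start ≤ end,
strand).

## Read cleaning

The 3′ adapter is located as the leftmost read suffix that is an exact
prefix of the adapter with ≥ 6 nt overlap; the match must run to the
end of the read (a partial adapter hit followed by other bases is not
an occurrence).  Mismatch-tolerant trimming and quality-based trimming
are deliberately out of scope: the trimmer is deterministic and
byte-exact, which the truth-table tests rely on.  Reads still carrying
an N are discarded.  Filter order is fixed — trim → length (18–28 nt)
→ complexity (≥ 3 distinct bases) → contaminant — and each stage count
is reported, so both "before contaminant removal" and "after" totals
are available (conventions differ between published summary tables).
Contaminant matching is an exact substring test against the
concatenated contaminant set and its reverse complement; this is
conservative (no tolerance) and reproducible.

## miRNA profiling

Matching is ungapped and end-to-end: a read is compared to every
reference mature of equal length and to every equal-length window of
longer references; Hamming distance ≤ 3 is required, minimal distance
wins, ties break on the lexicographically smallest reference id (a
read is never multi-counted across families, which keeps the count
tables additive for the exact test).  Variant labels within a family
(Roman numerals) are assigned by lexicographic order of the distinct
mature sequences — published labels of this kind are artifacts of
library processing order, so a deterministic rule replaces them.
Genome anchoring (requiring an additional match to a related genome)
is not implemented; the reference set is the sole authority.  RPM uses
each library's post-filter total and is reported to two decimals.

## Fisher exact test and concordance

The two-sided p-value is the classical conditional one: with margins
fixed, sum the hypergeometric probabilities of all tables whose
probability does not exceed the observed table's, with a 1 + 1e-7
relative slack against floating-point ties (the same convention R and
scipy use).  The kernel computes the whole conditional family at once
and is numba-compiled, so exhaustive verification against brute-force
enumeration over every table with both library totals ≤ 200 runs in
about a minute.  Bonferroni correction multiplies by the number of
sequences tested within one library pair (per-contrast correction,
matching pairwise-table reporting).  The libraries are unreplicated
pools, so no replicate-aware model (negative binomial etc.) is
offered; that is a property of the design, not of the software.

Concordance between pooled and individual-genotype libraries uses RPM
ratio directions with a pseudocount of one raw read substituted for
zero counts before the ratio is formed ("same profile" is not defined
numerically in the literature this reproduces; the pseudocount rule is
the disclosed choice).  Comparison 2 OR-combines the per-genotype
flags: agreement in a single genotype suffices for `+`.  The class of
a miRNA is the deterministic function of its (comp1, comp2) flags:
both / comp1-only / comp2-only / neither.

A curated flag table for the 39 drought-responsive sugarcane miRNAs
ships as package data (`canesrna.datasets.load_pool_individual_flags`);
feeding it through the classifier partitions it 17 / 10 / 12 / 0.

## Target prediction

Duplexes are strictly ungapped and full-miRNA-length (published
start–end spans of such sites equal the miRNA length, and the stated
ruleset never mentions bulges).  G:U wobbles weigh 0.5 in the numeric
caps (R1 ≤ 4.0 total, R5 ≤ 2.5 over positions 1–12) but count as
mismatch *positions* for the adjacency rules (R2: no run > 2 anywhere;
R3: no adjacent pair within positions 2–12; R4: positions 10–11
paired), following the Allen-style convention plant target predictors
implement.  Two historically co-numbered adjacency rules are kept
separate as R3 and R4 and reported independently.

The energy model is an embedded nearest-neighbor table: published
RNA/RNA Watson-Crick stack free energies (37 °C, kcal/mol), a flat
−1.3 kcal/mol for any stack containing a G:U pair, 0 for stacks
touching a mismatch, and +1.0 kcal/mol per mismatch.  The acceptance
criterion R6 consumes only the *ratio* of the duplex energy to the
perfect-complement energy computed by the same function, so the flat
terms cancel at the reference point and a perfect complement scores
exactly 1.0 by construction (same float divided by itself).  Full
secondary-structure folding engines give slightly different absolute
energies; because only the ≥ 0.74 ratio matters, the embedded table
keeps the stage deterministic and dependency-free.  A ratio for an
all-mismatch duplex (non-negative energy) is clamped to 0.

The cleavage position is the transcript base paired to miRNA position
10 — the 5′ side of the 10–11 scissile bond, standard slicer geometry.

## Secondary siRNA discovery

Triggers are the distinct matched miRNA sequences of exactly 22 nt.
Their predicted target transcripts are scanned against the read pool
*excluding every sequence with a miRNA hit*; a read hits when a
contiguous ungapped exact match of ≥ 18 nt exists on either strand
(seeded 18-mer index with maximal extension — equivalent to the
brute-force all-substrings test, which the suite asserts).  Hits whose
start and end each differ by ≤ 2 nt merge transitively; the
representative is the member with the maximal summed count (ties to
the lexicographically smallest sequence), and groups from distinct
transcripts with an identical representative are reported jointly
without double-counting shared members.

"Present in a library" means raw count strictly > 50 (literal reading
of "more than 50 reads"; RPM is reported but not filtered on).  The
core set is present in all libraries.

Cleavage concordance: a candidate is concordant when its alignment
interval covers the cleavage position within ±1 nt.  This is the
geometry of the first secondary species of the 3′ cleavage fragment
(it starts at the scissile bond) and it reproduces the published
concordant/non-concordant partition of such candidates; a rule keyed
to "alignment end near the cleavage coordinate" does not, because the
archetypal concordant siRNA spans the whole binding site.  Phasing in
the canonical 21-nt register is computed and reported, never filtered
on — discrete, out-of-phase candidates are a documented outcome.

## siRNA clusters

Placements are exact and full-length on either strand; a read with k
placements contributes 1/k to each, so total read weight is conserved
from placement through tabulation (asserted as a test invariant).
Mismatch-tolerant mapping is not implemented.  Clusters merge
transitively within a 100-nt gap (configurable; a typical sRNA-cluster
choice, disclosed in output metadata); both strands share a cluster
because siRNA loci are double-stranded.  Category priority is
named repeat class > TC EST > unannotated repeat >
unannotated-siRNA-cluster; unmapped reads fall into the last class.
An id annotated as both repeat and EST is a configuration error.

## Synthetic data: what it does and does not emulate

The generator's defaults are the study conditions the pipeline is
built for: four leaf-pool libraries (tolerant/sensitive × 0 h/24 h) of
100,000 reads each.  Per library the read composition is 24 %
conserved miRNA, 10 % t/rRNA contaminant, 1 % ta-siRNA fragments, 53 %
repeat-derived siRNA, 9 % background mapping nowhere, and 1 % each of
planted N-containing, length-violating and low-complexity reads (so
the filter truth table is non-trivial).  Read lengths follow the leaf
triple peak (21/22/24 nt); mature miRNAs start with U with probability
0.8.  Eight miRNA families are planted, with one 22-nt trigger, one
miRNA\*, and one family down-regulated two-fold under stress (a
planted power check for the exact test).  The trigger's target
transcript sheds sense fragments anchored at the cleavage position
with 1–2-nt end variants, > 50 reads per library.  Decoy binding sites
violating exactly one named duplex rule (R1, R2, R4) are planted and
must be rejected.  The repeat mixture is 40 % LTR-gypsy, 27 % TC EST,
16 % unannotated repeat, 6 % transposon, 6 %
centromere/telomere/ribosomal, 5 % MITE, and the LTR-gypsy fraction
shifts from 24-nt-dominated (T0h) to 21-nt-dominated (T24h) — the size
shift the cluster histograms must expose.

Construction guarantees that keep truth tables exact: inserts never
contain the adapter's 6-nt prefix (otherwise ~0.5 % of reads would
trim early and shift stage counts); planted families are ≥ 8
mismatches apart so assignment is unambiguous; EST-derived siRNA reads
are drawn only from transcripts without planted binding windows (a
window overlapping a decoy site would be a near-copy of the trigger's
star strand and would leak into the miRNA fraction); background reads
are rejection-sampled against all references and the 3-mismatch miRNA
radius; ta-siRNA members are explicitly verified not to match any
miRNA reference.

Not emulated: sequencing errors and quality scores, isomiR ladders,
true phased 21-nt registers, genome-scale reference complexity,
cross-mapping between homoeologous repeat families, and depth
imbalance between libraries.  Passing tests therefore demonstrate the
*logic* of every stage under clean, known-truth conditions — not
robustness to noisy real libraries, where adapter errors and
sequencing noise would blur the exact counts the tests assert.

## Problem sizes and determinism

The default synthetic scale (4 × 100k reads) runs the whole pipeline
in well under a minute on one CPU; the unit suite uses a 4 × 20k
version of the same design.  The exhaustive exact-test sweep covers
all 2×2 tables with both totals ≤ 200 (completed by the asserted swap
symmetry).  A single seed drives every random draw; the same seed
reproduces libraries byte-for-byte, and the run manifest (config hash,
stage row counts, version, seed) is identical across reruns with
identical inputs.

## Known limitations

No genome anchoring or hairpin-based novel-miRNA discovery; no
degradome/PARE validation of cleavage; exact-match-only contaminant
removal and cluster mapping (no mismatch tolerance); the embedded
energy model is a stacking approximation, not a folding engine; the
Fisher test treats pooled libraries as single observations, so
p-values quantify sampling noise within pools, not biological
replication.
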
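# Methods

This note documents the models implemented in `rjmap`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want written down.

## Coordinate and naming conventions

All coordinates are 0-based, half-open. A junction *position* is the index
of the first base to the right of the boundary. Fraction length (FL) on a
chromosome arm runs from 0 at the centromere to 1 at the telomere; a
chromosome's arm split is given by `arm_fraction` (short arm = the
`[0, arm_fraction·L)` prefix). A deletion line with breakpoint *b* on arm
*A* retains the proximal fraction `[0, b]` of that arm, so a locus is lost
iff its FL is strictly greater than *b*; consequently bins are half-open
intervals `(a, b]` and a locus exactly at a breakpoint is retained by that
line.

## Synthetic genomes and truth bookkeeping

Genomes are assembled from segments. Each transposable-element insertion
picks a host segment — background sequence, or an existing element with
probability `nesting_prob` — and splits it at a point at least 60 bp from
any existing boundary. Each insertion therefore adds exactly two boundaries,
so a genome with *k* insertions carries exactly *2k* truth junctions, and a
nested host+insert configuration shows the expected four (two
element–element, two element–flank). The 60 bp margin guarantees junctions
are separated and flankable; it also means the generator cannot produce
genuinely abutting elements, which is why the detector's abutting-merge rule
is exercised by constructed fixtures rather than by simulation.

Genes are spliced into TE-free background with GC 0.55 (slightly above the
0.50 background, as in real genic sequence) and lengths 300–900 bp. Reads
are single-end, fixed-length, substitution-errors-only: the downstream
filters are exact-substring and occupancy screens, so indel realism buys
nothing. `tile_reads` provides a deterministic, error-free read tiling used
where a filter's contract is about depth, not sampling noise.

Ploidy is represented as per-locus copy counts (control = 1), not duplicate
sequences: the hybridization model needs dosage only, and it keeps the
copy-number function trivially checkable (`copy ∈ {0, 1}`, a nullisomic
line zeroing exactly its chromosome).

## Hybridization signal model

Expected intensity for a locus present in *c* copies is
`base_intensity · copy_gain^(c−1)` for c ≥ 1. At c = 0 a junction probe
sees nothing (its insertion site does not exist elsewhere), while a gene
probe keeps `cross_hyb · base_intensity` of homeologous background. Noise
is multiplicative lognormal per spot measurement (`lognormal_sd`, default
0.15 — a typical inter-replicate CV for two-colour arrays), and each spot
value is independently replaced by near-background with probability
`dropout_rate` (default 0.02, modelling scratches and failed spots). The
noise law is a modelling choice; the source experiments report no noise
model, only replicate counts (3 spots × 2 arrays).

`cross_hyb` defaults to 0.3: with one D-genome copy lost, the remaining
homeologous (A/B) copies would contribute up to two thirds of the signal if
hybridization were sequence-independent, but homeolog divergence under
stringent wash conditions attenuates it; 0.3 yields a ~70 % loss for
deleted gene probes — detectable across the whole stringency ladder —
while junction probes go to background, reproducing the qualitative
contrast between the two probe classes (genes retain partial signal, RJMs
do not). Homeologous genomes are not simulated explicitly; a single factor
is sufficient for that contrast and keeps the dosage model exact.

## Junction matcher

The published pipelines run BLAST-based software against a repeat database;
`rjmap` replaces this with a self-contained k-mer-seeded ungapped extender
(defaults k = 16, `min_match_len` = 30, `min_identity` = 0.9) so the
package has no external tool dependency. Two numerical rules matter:

* **Extension guard.** A mismatch may be crossed only if it is followed by
  a match run of ≥ 8 bases and the running identity stays above
  `min_identity`. Without the run guard, a long match entering random
  flanking sequence can drift tens of bases before the identity budget is
  exhausted, destroying junction localisation; with it, the expected
  overshoot is the few bases that match by chance (P = 4⁻ᵏ for k bases).
  At `min_identity = 1.0` no mismatch is ever crossed, so reported matches
  are exactly the maximal exact matches — this is the property the
  brute-force oracle tests assert.
* **Abutting merge.** Two matches whose facing edges are within 5 bp (gap
  or overlap — sequencing-error slack) collapse into one element–element
  junction at the floor of the edge midpoint.

A lone match edge is reported as an (element, unknown) junction when both
the match and the sequence beyond the edge provide ≥ `min_flank` (default
25) bases. Edges at the read boundary never qualify. Both strands are
scanned; coordinates are reported on the forward strand of the query.

## Probe filters

Probes are 52-mers with the junction at offset 26. The cascade order is
homopolymer → read validation → copy number → thermodynamics, with each
rejected probe charged to its first failing filter; all verdicts are
evaluated for every candidate, so the *selected set* is independent of
order (only the rejection attribution depends on it). Duplicate windows
(the same junction seen in several reads) are counted separately.

"Exactly matched" means exact, full-length, both-strand substring
occurrence. Zero hits in the target-genome reads fail the copy-number
screen: a junction absent from the target genome cannot serve as a marker
there. Gene probes skip the read-based screens by default (genes are
expected in homeologous copies, so target-read counts would reject them
wholesale); this is configurable.

The melting temperature uses the salt-adjusted long-oligo formula
`Tm = 81.5 + 16.6·log₁₀[Na⁺] + 0.41·GC% − 600/N`. The default
`[Na⁺] = 0.165 M` was chosen so that for 52-mers the GC window [50, 65] %
maps approximately onto the Tm window [76, 83] °C (GC 50 % → 77.5 °C;
GC 65 % → 83.6 °C, just outside), making the two published windows mutually
consistent rather than redundant; salt is configurable.

## Signal analysis

Columns are normalized, then each spot's test value is divided by its
same-spot reference value, ratios are scaled by the control line's median
ratio per probe, and each line's spot-level ratios (2 arrays × 3 spots = 6)
are compared with the control line's by a two-sided pooled-variance
Student's t-test. Loss is `1 − mean(test)/mean(ref)`.

**Normalization default.** Full quantile normalization (rank mean, with
tied entries receiving the mean of their tied ranks' reference values) is
implemented and tested to its postcondition — identical sorted column
vectors. It is *not* the pipeline default: in an aneuploid dosage design a
sizeable fraction of probes genuinely drops to background in each line, and
forcing identical column distributions compresses exactly the losses under
test (in a three-chromosome fixture a noise-free 85 % loss shrinks to 18 %
after quantile normalization). The pipeline therefore defaults to median
scaling, which is invariant to the shifted minority as long as fewer than
half of a column's probes shift — true for panels of three or more
chromosomes (the real design has seven). Both normalizations are selectable
(`normalize="quantile" | "median" | "none"`).

**Reference-channel dropout masking.** Reference spots below 5 % of the
probe's median reference intensity are masked to NaN before ratios are
formed. The reference genome carries every locus, so a near-background
reference value can only be a failed measurement; left in place, a single
such spot inflates the ratio denominator and voids the probe. Test-channel
values are never masked — a near-zero test value is the signal being
measured. Degenerate zero-variance t-tests (the noise-free limit) resolve
to p = 0 when means differ and p = 1 when they agree.

**Stringency ladder.** Thresholds run strict → lenient (0.5, 0.4, 0.3,
0.2). A level is *clean* when exactly one nullisomic line is flagged and
the deletion-line pattern on that chromosome is valid: an ascending prefix
of breakpoints (the bin bounded by the largest flagged and smallest
unflagged breakpoints), all lines (terminal bin), or none (pericentromeric
by inference). The first clean level fixes the assignment. A probe whose
chromosome call is clean at some level but whose deletion pattern never is
receives a chromosome-only assignment at its first chromosome-clean level —
mirroring the real data's probes that map on nullisomic lines but fail on
deletion bins. Probes flagged in several nullisomic lines, or in deletion
lines of a chromosome other than their own, stay unassigned.

## Bin bookkeeping

Bin physical length is `(b − a) ×` cytogenetic arm length. The
pericentromeric composite (both arms' proximal residue plus centromere) is
not assayed by any deletion line; its marker count is the chromosome total
minus the assayed-bin sum — an identity asserted on every synthetic
end-to-end run — and its physical length is the chromosome length minus the
assayed bins. A negative subtraction is reported as an error, never
clamped: the bundled published tables contain two cells (4D gene, 7D RJM)
that genuinely violate the identity, and the test suite asserts the
*disagreement*.

Within-bin order comes from the genetic map. A marker is flagged discordant
when its cM position falls outside the interval spanned by its bin's
remaining markers (leave-one-out min–max) *and* inside a physically
adjacent bin's interval — i.e. the genetic map actively places it next
door, not merely at its bin's edge. The min–max interval was preferred over
a robust (median/MAD) interval because it makes the swap-detection property
exact on clean data; its cost is that a corrupted bin-mate can widen a
bin's interval and shadow borderline cases, which matters only for bins
with very few mapped markers. The synthetic genetic map is monotone in
physical position with local rate ∝ FL², reproducing the distal
concentration of recombination in cereal chromosomes (distal bins get large
cM spans, proximal bins cluster).

## Recovery experiments and problem sizes

The real mapping experiment (46k probes, real aneuploid stocks) is not
computationally reproducible, so the package's accuracy claim is a
parameter-recovery experiment (`rjmap.recovery`): 7 chromosomes × 1 Mb,
300 insertions, 500 genes, 2,000 truth-derived probes, a panel of one
control + 7 nullisomic + 12 deletion lines. At zero noise, chromosome and
bin recovery are exact (100 %); at `lognormal_sd = 0.15`,
`dropout_rate = 0.02` they stay above 95 % / 90 %. Unit fixtures use 2–3
chromosomes of 50–60 kb; these sizes keep the whole suite around ten
seconds while leaving every rate estimated from hundreds of events.

## What passing tests do and do not show

The simulator's reads have uniform coverage, independent substitution
errors, and no chimeras; its repeat library is exactly the detection
library (no diverged families, no truncated elements); hybridization noise
is lognormal and spot-independent with a single cross-hybridization factor.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's logic and its robustness to calibrated noise — not performance
on real 454/Illumina data, diverged repeat families, or spatially
correlated array artefacts. The published-table arithmetic, by contrast,
is exact and independent of simulation.

## Known limitations

* Elements are inserted verbatim (no LTR structure, target-site
  duplications, or sequence decay), so detection is easier than against a
  real repeat landscape.
* The abutting-merge path cannot arise in simulated genomes (60 bp margin)
  and is covered by constructed fixtures only.
* The discordance rule is order-of-magnitude, not optimal, for bins with
  fewer than ~3 mapped markers.
* `quantile_normalize` should not be combined with panels where a line
  shifts ≥ 50 % of probes (e.g. two-chromosome toy genomes); the pipeline
  default (median scaling) has the same restriction in the extreme case of
  a single-chromosome genome.
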
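# Methods

## The quantities computed

`cpgscope` profiles the sequence context of CpG dinucleotides (5′-CG-3′) in
genome datasets and relates those profiles to DNA-uptake measurements on
NK cells carrying the inhibitory receptor KIR3DL2. Four summaries drive the
analysis.

**CpG interdistance (CpG-ID) spectrum.** For successive CpG motifs on the
same FASTA record, the interdistance is the number of bases strictly
between the two motifs, i.e. start-to-start distance minus 2 (`CGTCG` has
interdistance 1). This convention — rather than start-to-start distance —
is the one under which the designed two-motif 14-mers with "interdistances
of 1–8 bases" and the repeat-adduct observation (pentamer repeats place
motifs too close; heptamer repeats, five bases apart, do not) are
consistent, and it makes the genomic 3x−2 peaks (d = 1, 4, 7, 10, i.e.
d ≡ 1 mod 3) correspond to codon-period spacing of motif starts. Counts for
d ≤ `max_id` (default 1,000) are tabulated, larger gaps pooled in an
overflow bin; the relative frequency divides by the dataset's total base
count. Records are the unit of contiguity: no gap spans a record or file
boundary, because FASTA headers delimit chromosomes and contigs.

**Peak detection.** d is a peak iff its count strictly exceeds both
neighbours. The periodicity flag is true iff every peak in the scanned
range satisfies d ≡ 1 (mod 3) and every member of {1, 4, 7, 10} inside the
range is a peak. Strict inequalities mean flat (e.g. all-zero or uniform)
spectra yield no peaks and a false flag.

**CpG⁺ octamer census.** Windows of 8 bases centred on the motif
(positions 1-2-3-C-G-6-7-8) define 4⁶ = 4,096 possible octamers, indexed by
the six flanking bases in base-4 (A=0, C=1, G=2, T=3), an order that
coincides with lexicographic octamer order. A window is counted iff it lies
fully inside its record and contains only A/C/G/T; motifs with truncated or
N-containing context still count toward `total_cpg_sites` but contribute no
window (no context is fabricated). Overlapping windows are all counted.
Scanning is forward-strand by default — the original survey scanned
deposited files as given — with a both-strands option that adds the
reverse complement of every record. Relative frequency divides by total
valid windows (so it sums to 1); a per-total-bases normalization mirroring
the interdistance convention is available because the source material does
not pin the octamer denominator.

**Positional composition and similarity.** The 6 × 4 composition matrix
gives the frequency of each base at the six flank positions,
occurrence-weighted by census counts (an unweighted per-distinct-octamer
mode exists for sensitivity analysis). Two datasets are compared by the
Pearson correlation over the 24 paired entries (a per-position mode that
averages six row-wise correlations is exposed for comparison; the 24-entry
form is the default). Uniform composition has zero variance and the
coefficient is reported as NaN with a warning.

## Ranking, top-k overlap and representative octamers

Octamers are ranked by descending count with lexicographic tie-breaks;
unobserved octamers follow the observed ones lexicographically, so ranks
are a permutation of 1..4,096 and the least frequent possible octamer has
rank 4,096. Top-k overlap intersects the (up to) k most frequent *observed*
octamers of two datasets.

Representative octamers — the sequences synthesized for uptake and
functional assays — are chosen per dataset from its own top-k (default 20)
in rank order, requiring exactly one CpG motif (multi-motif octamers
confound uptake through the motif-count effect) and exclusivity: under the
default `exclusive` rule the octamer may appear in no other dataset's
top-k; under `shared-at-most-once` it may appear in one. Both rules exist
because the two published descriptions of the selection differ slightly;
the figure-legend (exclusive) form is the default.

## Oligonucleotide design rules

All generators flank with thymine (the TLR-9-compatible convention) and
re-verify the emitted sequence with the CpG scanner instead of trusting the
construction:

* `design_central_cpg(L)`: T×f5 + CG + T×f3 with f5 = ⌊(L−2)/2⌋. The floor
  on the 5′ side is fixed by the canonical pentamer TCGTT (one T before,
  two after).
* `design_spaced_cpg(n, d, L)`: core ("CG" + T×d) repeated n times with the
  trailing spacer dropped, thymine flanks split with floor 5′; the motif
  count and every pairwise interdistance are checked by scanning.
* `design_adduct(core, r)`: the core repeated r times; repeats of a
  length-n single-CpG core sit n − 2 bases apart, which is why pentamer
  repeats (d = 3) are taken up poorly while heptamer repeats (d = 5) behave
  like independent cores. If a junction creates an unintended motif (core
  ending C followed by a copy starting G), a warning reports the true
  count.
* `gpc_control`: the single central CG becomes GC, length preserved.

Properties: GC fraction; melting temperature by the Wallace rule
2(A+T) + 4(G+C) °C for oligos under 14 nt and a nearest-neighbor model
(biopython's Tm_NN) above, both forceable; molecular weight as the sum of
monophosphate residue masses (A 313.21, C 289.18, G 329.21, T 304.2 g/mol)
minus 61.96, the standard synthesis-vendor convention. `n_cpg` is a
property recomputed from the sequence on every access, never cached.

The multi-motif panel's spacing is not recorded in the experimental tables;
the builder spreads motifs into equal segments, d = ⌊(L − 2n)/(n + 1)⌋. The
discussion of dominant sequences mentions a 9-mer "GTTTCGACC" where an
octamer is expected; the panels include only the octamer GTTCGACC.

## Regression screening

For each species the 4,096-vector of octamer relative frequencies,
restricted to the panel's octamers, is regressed (ordinary least squares)
against uptake, in two modes: raw, and human-normalized (each frequency
divided by the reference genome's; octamers absent from the reference are
NA by default and drop out pairwise, or a pseudo-count of 1 can be added to
all reference counts). The p-value is the two-sided t test of the slope
(n − 2 df), Bonferroni-multiplied by the number of regressions — "auto"
counts the fits in the current run; the study-wide constant 705 can be
supplied for reproduction — and capped at 1. A species passes at r² ≥ 0.2
(the strict `>` variant is a flag, since the published threshold is stated
both ways) with a positive slope; the best-fit species maximizes r² among
positive slopes, negative-slope fits being disqualified. Degenerate fits:
constant x is fatal; constant y returns slope 0, r² 0, p 1. Panels carrying
two experimental conditions (e.g. a FITC label and an intercalating dye)
are averaged per octamer after dividing each condition by its own mean
level.

Worked check: r² = 0.50 at n = 31 gives t = √29, raw p ≈ 8.7 × 10⁻⁶
(verified against numerical integration of the t density), × 705 = 0.0061,
printing as 0.01 at two decimals.

## Assay statistics

The lysis-escape ratio divides the DNA-treated co-culture's adjusted
surviving-target fraction by the untreated co-culture's; the targets-alone
baseline cancels algebraically but is accepted so callers pass gated
percentages as recorded. IFN-γ, trypsin-internalization and
surface-fraction readouts are plain treated/control quotients. Replicates
are normalized to each experiment's control condition before pooling.

Significance uses an ordinary two-way fixed-effects ANOVA with
species-of-origin and within-species octamer rank as crossed factors, so
the species effect is assessed independently of how first/second/third-
ranked octamers distribute. The interaction term is included automatically
when every cell has replicates; since the published analysis does not state
whether it was, both models can be emitted. The design must be balanced
(the experiments were); unbalanced data require an explicit flag and are
analysed with a type-II decomposition. The fit is delegated to statsmodels
(`ols` + `anova_lm`); the balanced decomposition is verified in tests
against a closed-form cell-means oracle.

## Synthetic data: what is emulated, and what is not

`generate_genome` plants exact, recoverable structure: an i.i.d. background
(default base frequencies 0.3/0.2/0.2/0.3) is scrubbed of accidental CG
dinucleotides by rewriting the C to A — a bias of at most n_CG/L per
record, accepted so that planted motifs are the only CpG sites and ground
truth stays exact. CpG motifs are then placed left to right with gaps drawn
from the interdistance law, and each motif's six flanking bases are drawn
from a 4,096-weight vector. A flank context is only written when both
neighbouring motifs are at least 7 bases of interdistance away — closer
motifs would collide with the ±3-base flanks or their junctions — so
motifs in tight clusters keep the CG-free background as context
(`n_context_skipped` reports how many). Junction bases adjacent to a
written flank are rewritten (C→A, G→T) if they would form a spurious motif.
When the weight vector is supported on single-CpG octamers the generator
asserts that the scanned motif positions equal the planted ones.

Consequences for recovery, exercised by the acceptance suite:

* with a law supported on d ≥ 7, the census equals the placed-context
  multiset exactly; against the *planted weight vector* the residual is
  pure multinomial sampling noise, E[TV] ≈ 0.376 √(k/n) for k supported
  categories. The recovery condition uses 10⁵ insertions and a random
  weight vector supported on 150 single-CpG octamers — emulating the
  concentrated flank composition of real genomes — for which the bound
  sits below 0.02 with margin. Weights on multi-CpG octamers are allowed
  but create additional genuine motifs, and exact recovery no longer holds.
* the default periodic law places gaps on d = 0..12 with a geometric
  baseline (ratio 0.7, as genomic spectra decay over this range) boosted
  8-fold at {1, 4, 7, 10}; every non-3x−2 distance in [1, 10] then has a
  boosted neighbour, so peak detection over that range is robust to
  counting noise.

`generate_uptake_panel` samples 31 (configurable) single-CpG octamers with
positive frequency in the target census — panels are built from sequences
present in the genome they represent — and sets
uptake = intercept + slope·freq + N(0, σ), floored at 0 to respect the
non-negative fluorescence invariant (the floor count is recorded; defaults
make it essentially impossible). Recovery tests calibrate σ to the sampled
panel's own frequency spread (a two-pass generation with the same seed
redraws the same octamers), so the planted population r² is exact.

`generate_assay_table` emits balanced species × rank × replicate tables
with readout = species mean + rank offset + Gaussian noise. The planted
conditions mirror the experimental scale: species means 1.0 vs 0.6 with
σ = 0.05 over 3 ranks × 5 replicate experiments for power checks; equal
means for null calibration.

What the synthetic data does **not** emulate: isochore and CpG-island
structure, methylation-driven CpG depletion, repeat families, soft-masking,
assembly gaps beyond uniform N injection, species phylogenetic correlation,
and any optics of flow cytometry beyond a linear mean plus Gaussian noise.
Passing recovery tests therefore demonstrates correctness of the counting,
ranking, regression and ANOVA machinery on data satisfying the model
assumptions — not that real genomes meet them.

## Numerical and interface choices

* Frequencies are written to TSV with 12 significant digits; counts
  exactly — tables round-trip bit-stably.
* Sanitization maps lowercase to uppercase (a flag maps soft-masked bases
  to N instead, excluding masked windows), U to T and every other IUPAC
  ambiguity code to N; non-IUPAC characters are fatal with offset.
  Sanitization is idempotent.
* Problem sizes in the acceptance script (10⁵ insertions × 20 seeds for
  weight recovery, 10 genomes for periodicity, 3 screen trials of 21
  species, 200/1,000 seeds for ANOVA power/null) were chosen to make the
  binomial/multinomial error of each reported rate small relative to the
  quantity while keeping a desktop run in the low minutes.
* All simulation randomness flows through a single
  `numpy.random.default_rng` stream per artifact; seeds are recorded in
  ground-truth records and output headers.

## Known limitations

Whether the original Perl survey counted both strands, included edge
motifs, and which Pearson variant (24-entry vs per-position) produced the
published similarity values is not recorded; each choice is a documented
flag here, and the published real-genome correlation values are therefore
not reproduced at desk scale. Reported Tm values are indicative only —
hybridization conditions are not modelled. The screen treats species as
independent; no phylogenetic correction is applied.
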
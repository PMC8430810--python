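# Methods

`structdrop` studies a failure mode of RNA-seq: transcripts with strong
secondary structure can vanish from a sequencing library prepared with
chemical fragmentation while remaining perfectly measurable on a cDNA
microarray (and by qRT-PCR from ordinary cDNA). The package implements the
full desk-side chain of that investigation — detection concordance between
platforms, raw-read pattern search to rule out mapping artifacts, RNA
secondary-structure folding with the length-normalized stability score
|MFE|/L, and a generative model of structure-dependent fragmentation bias —
so that the whole phenomenon can be produced, recovered, and tested
synthetically.

## Detection model

RNA-seq non-detection is taken literally: a gene is undetected iff its
total normalized count across all replicates is exactly zero (a small-count
threshold exists as a policy knob, `DetectionPolicy.rnaseq_min_total`, but
defaults to 0). Microarrays always emit some fluorescence, so array
detection is a threshold on the per-gene mean log2 signal; the default
threshold is the 25th percentile of those means (`tau_array` overrides it).
This percentile rule is a pragmatic stand-in for vendor detection p-values,
which the package deliberately does not consume; it reproduces an
"undetected on array" category without raw probe data. Correlation between
platforms is Spearman's rho on per-gene mean log2 signal over co-detected
genes only, with average ranks for ties; perfectly concordant or perfectly
reversed rank vectors return exactly ±1.

Gene-identifier mapping between platforms (probe ↔ Ensembl) is the
caller's responsibility via an optional two-column TSV; unmapped genes are
reported as platform-private, never silently dropped.

## Pattern search

Patterns are short DNA strings (the two SOX21 20-mers and a GAPDH control
in the motivating use case) scanned against every window of both mates of
every read pair. Distance is Hamming — substitutions only, no indels —
with `N` counting as a mismatch. Hits are recorded per *exact* distance
level; "up to m mismatches" is the sum of levels 0..m. The reverse
complement is scanned by default (library strandedness is generally
unknown) and hits carry a strand label. The scanner vectorizes the window
comparison (numpy sliding windows over byte-encoded read blocks); the test
suite holds it bit-identical to a naive per-offset scan.

The positive-control rule makes absence interpretable: if a control
pattern yields at least `c_min` exact hits (default 10) in the same read
stream while the target has zero hits at ≤ 1 mismatch, the verdict is
`absent_despite_control` — the target's reads are missing from the
library, not merely unmapped.

## Folding model

The internal energy model is a deliberately simplified nearest-neighbour
loop model chosen so that the Zuker-style dynamic program is *provably*
optimal under the model — every energy can be checked against exhaustive
enumeration of all pseudoknot-free structures for short sequences:

| term | value (kcal/mol) |
|---|---|
| allowed pairs | AU/UA, CG/GC, GU/UG; hairpin loop ≥ 3 nt |
| stack | weaker pair decides: −3.0 (both CG/GC), −2.0 (any AU/UA), −1.0 (any GU/UG) |
| hairpin, loop l | 3.0 + 1.75 ln(l/3) |
| internal/bulge, u unpaired | 2.0 + 1.75 ln(u), u ≥ 1 |
| multiloop | 3.4 + 0.4 per branching helix (closing included) + 0.0 per unpaired |

No dangles, coaxial stacking, or lonely-pair prohibition. The
"weaker-pair-decides" stacking rule resolves mixed stacks (e.g. a CG
stacked on a GU scores −1.0) with one deterministic convention shared by
the dynamic program, the structure scorer, and the enumeration oracle.
These are not Turner parameters and the energies are not literature
comparable; for Turner-accurate values `fold_external` shells out to an
installed ViennaRNA `RNAfold`. Energies from the two engines are never
mixed inside one comparison (profile provenance is checked at runtime).

The DP is the standard V/WM decomposition with three performance choices:

* internal/bulge loops capped at 30 unpaired nucleotides (the usual
  Zuker-implementation convention; irrelevant below 32 nt, so it cannot
  affect the enumeration-oracle comparisons, which are guarded to 25 nt);
* the multiloop bifurcation is sparsified with candidate lists: because
  the per-unpaired multiloop cost is non-negative, the segment energy is
  subadditive under concatenation, and only helices `(k, j)` whose closed
  energy undercuts every decomposition of `[k, j]` can terminate an
  optimal split. This takes the cubic bifurcation term down to the
  candidate count per column and makes 3,000 nt transcripts fold in a few
  seconds (5,000 nt well under a minute) on one CPU;
* kernels are numba-compiled; traceback is reconstructed outside the
  kernel with an explicit worklist (stacks can be thousands deep).

Tie-breaking: `enumerate_structures` returns the exact canonical argmin
(lowest energy, then fewest pairs, then lexicographically smallest
dot-bracket). The DP traceback is deterministic and prefers unpaired
expansions case-by-case, which favours sparse structures but does not
guarantee the globally canonical witness; energies, which are what the
statistics consume, always agree with the oracle, and tests assert
structure validity plus energy consistency rather than string identity.

## Structure statistic

The per-gene score is the quotient q = |MFE| / L in kcal/(mol·nt) — free
energy magnitude normalized by transcript length, so long and short mRNAs
are comparable. The contrast "undetected genes have higher q" is made
falsifiable with a two-sided Mann–Whitney U test (average-rank ties,
undetected ranked against detected), which adds an inferential layer on
top of what is otherwise a descriptive scatter; the identical test applied
to GC fraction serves as the negative control. Groups smaller than 3 are
refused with advice to report descriptive medians only. Folds are cached
by sequence digest so matched simulations over one gene set fold each
transcript once; profiling uses the energy-only DP path (no traceback).

## Synthetic study

The generator emulates the two-platform design directly:

* **Genes.** 300 transcripts by default, uniform lengths 500–3,000 nt,
  i.i.d. uniform ACGU. Structure is planted as a perfect inverted repeat:
  classes low/mid/high commit 0 / 0.15 / 0.35 of the length to the two
  arms (arm = sf·L/2, separated by a 4 nt loop), assigned round-robin so
  classes stay balanced. Planting guarantees the *internal* model assigns
  clearly separated quotients (random background folds to q ≈ 0.26 under
  this model; mid ≈ 0.40, high ≈ 0.55), so recovery does not depend on
  Turner-accurate energetics.
* **Abundances.** Log-normal per gene (μ = 4, σ = 1.5 on the natural-log
  scale, arbitrary units) — a realistic heavy-tailed expression
  distribution — shared across replicates up to a small log-normal
  replicate jitter (σ = 0.1) so replicate columns correlate strongly, as
  biological replicates should.
* **Array.** signal = log2(abundance·gain) + N(0, 0.2), independent of
  structure by construction.
* **RNA-seq.** Expected reads ∝ abundance · L · efficiency(q); counts are
  a multinomial draw per sample totalling the library depth (100,000 read
  pairs by default — a desk-scale stand-in for the tens of millions of a
  production run; two replicates). Capture efficiency is the fragmentation
  model: `exp(−β·max(0, q − q0))` with β = 40, q0 = 0.02 for chemical
  shearing, constant 1 for mechanical. The whole-molecule multiplier is
  the simplest monotone mechanism consistent with "chemical shearing
  fails to break strongly structured RNA"; β and q0 are exposed. Optional
  FASTQ output draws 200–500 bp fragments uniformly from replicate 1's
  transcripts and reports 75 bp mates, mate 2 reverse-complemented,
  error-free by default (a per-base substitution rate is available for
  stress tests).

What the simulation does *not* model: positional fragmentation bias along
the molecule, GC-dependent amplification, sequencing error profiles,
isoform mixtures, or partial (rather than whole-molecule) capture loss.
Passing the recovery tests therefore shows the pipeline detects the
planted mechanism faithfully; it does not certify effect sizes on real
libraries.

With the default chemical parameters the efficiency ratio between classes
is enormous (e^(−40·0.15) ≈ 2.5×10⁻³ per 0.15 of q), so the mid and high
classes account for nearly all zero-count genes — deliberately extreme, a
caricature of the qualitative claim rather than a calibrated fit.
Mechanical runs produce essentially no dropout at default depth, so the
undetected group is usually below the rank test's minimum size; matched
mechanical analyses count that outcome as "no structure effect
demonstrable", which is the scientifically correct reading.

## Numerical and design choices

* Expression tables are TSV; GEO series-matrix-style `!` comment lines are
  skipped on request. Missing values in arrays are rejected rather than
  imputed, keeping detection calls unambiguous.
* Transcripts are normalized to the RNA alphabet (T→U) on input; reads
  stay DNA. One FASTA record per gene is the caller's isoform choice.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning, so bundles are byte-reproducible.
* Desk-scale problem sizes used by the test-suite recovery checks and the
  acceptance script: 300 genes at full length (folded once, ~5 min on one
  CPU), 20 matched mechanical re-simulations reusing those folds, 10,000
  reads × 50 patterns for the search equivalence, 500 short sequences for
  the folding-oracle equivalence.

## Limitations

* The internal energy model is intentionally crude; absolute |MFE|/L
  values are not comparable to RNAfold output (use `fold_external`).
* The array detection threshold is a percentile convention, not a
  vendor-calibrated present/absent call.
* Pattern search is substitution-only; an indel in a read's pattern window
  would be missed.
* The fragmentation model collapses library chemistry into one monotone
  curve; it is a mechanism probe, not a protocol simulator.
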
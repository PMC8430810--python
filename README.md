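# structdrop

**Structure-dependent gene dropout in RNA-seq: concordance, raw-read
pattern search, RNA folding, and fragmentation-bias simulation.**

Some genes that are plainly expressed — detectable by cDNA microarray and
by qRT-PCR — come back with *zero* read counts from an RNA-seq experiment.
When the library was prepared with chemical fragmentation (divalent
cations or enzymes at elevated temperature), a strong mRNA secondary
structure can survive the shearing step, and the molecule never makes it
into the fragment pool. `structdrop` is a toolkit for investigating and
simulating that failure mode, aimed at transcriptomics researchers who
compare platforms or debug suspicious dropouts:

* **concordance** — classify every gene as detected-both / array-only /
  seq-only / neither across a microarray and an RNA-seq matrix, and
  compute Spearman's ρ of mean log2 signal over co-detected genes;
* **readsearch** — mismatch-tolerant (Hamming, ≤ k substitutions) search
  for short diagnostic patterns directly in raw paired FASTQ, with a
  positive-control rule that distinguishes "reads absent from the
  library" from "reads lost in mapping";
* **folding** — minimum free energy of RNA secondary structure by a
  Zuker-style O(L³) dynamic program over a simplified loop model, exactly
  verifiable against exhaustive enumeration (and an adapter to ViennaRNA's
  `RNAfold` for literature-comparable kcal/mol);
* **structure_stat** — the per-gene structure quotient q = |MFE|/L and a
  Mann–Whitney U contrast of q between RNA-seq-detected and undetected
  genes (with GC content as negative control);
* **synthetic_data** — a generative model of the whole study: planted
  inverted-repeat structure classes, log-normal abundances, a
  structure-blind array readout, and RNA-seq counts plus paired 75 bp
  FASTQ under chemical (efficiency = exp(−β·max(0, q−q0))) or mechanical
  (efficiency = 1) shearing.

The central claim the pipeline recovers: **after chemical shearing,
undetected genes carry a higher |MFE|/L than detected genes; after
mechanical shearing the effect disappears, and GC content explains
nothing either way.**

## Worked example

```python
from structdrop import (
    SyntheticConfig, FragmentationModel, make_genes, compute_quotients,
    simulate_rnaseq, detection_calls, profile_genes, compare_quotients,
)

config = SyntheticConfig(n_genes=30, length_range=(200, 400),
                         depth=20_000, seed=42)
genes, truth = make_genes(config)
quotients = compute_quotients(genes)          # folds every transcript
matrix, _ = simulate_rnaseq(genes, truth, quotients,
                            FragmentationModel("chemical"), config, seed=1)
profiles = profile_genes(genes, detection_calls(matrix))
cmp = compare_quotients(profiles)
print(f"detected n={cmp.n_detected} median q={cmp.median_detected:.3f}")
print(f"undetected n={cmp.n_undetected} median q={cmp.median_undetected:.3f}")
print(f"Mann-Whitney U={cmp.statistic_u:.0f}  p={cmp.p_value:.2e}")
```

prints

```
detected n=23 median q=0.299
undetected n=7 median q=0.525
Mann-Whitney U=154  p=4.42e-05
```

— the seven genes with zero counts are precisely the strongly folded
ones: their |MFE|/L median (0.525 kcal/(mol·nt)) sits far above that of
the detected genes (0.299), and the rank test rejects equality.

## Analysis drivers

The numbered scripts under `analysis/` run the full study (add `--quick`
for a 30-gene smoke run) and write their tables to `results/`:

```bash
python analysis/01_simulate_study.py    # genes, folds, chemical+mechanical bundles
python analysis/02_concordance.py       # detection categories + Spearman rho
python analysis/03_pattern_search.py    # SOX21/GAPDH patterns in raw reads
python analysis/04_structure_quotients.py  # the |MFE|/L contrast
```

At the default scale (300 genes, 500–3,000 nt, 100k read pairs/sample) a
full run takes a few minutes, dominated by folding, and finds: ~150 of
300 genes drop out chemically (101 array-only) versus none mechanically;
the GAPDH control pattern hits 1,978 reads exactly while both SOX21
patterns hit zero reads at any mismatch level (verdict
`absent_despite_control`); and the quotient contrast gives p ≈ 8×10⁻³⁹
chemically but p = 0.34 mechanically. Large intermediates (FASTQ bundles)
go to `scratch/`.

A `structdrop` CLI wraps the same stages (`simulate`, `concordance`,
`patternsearch`, `foldscan`, `profile`, `report`); see `structdrop --help`.

## Layout

```
src/structdrop/     io_formats, concordance, readsearch, folding,
                    structure_stat, synthetic_data, cli
analysis/           numbered narrative drivers (write to results/)
scripts/acceptance.py
tests/              pytest suite incl. oracle-equivalence and recovery tests
docs/methods.md     model details, parameter choices, limitations
```
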
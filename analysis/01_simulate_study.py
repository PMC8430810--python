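#!/usr/bin/env python
"""Generate the matched chemical/mechanical synthetic study.

One gene set (300 transcripts, 500-3000 nt, three structure classes with
planted inverted repeats) is folded once; RNA-seq is then simulated twice
from the same latent abundances — once with chemical shearing (capture
efficiency decaying with |MFE|/L) and once with structure-blind mechanical
shearing — alongside a structure-independent array readout. Diagnostic
20-mers are embedded first: a GAPDH-primer pattern into an abundant
low-structure transcript (positive control) and the two printed SOX21
patterns into the most abundant high-structure transcript, the designed
dropout.

Bundles land under scratch/study/ (large; regenerated on demand); a class
summary of the folded quotients goes to results/study_quotient_summary.tsv.
"""

import argparse
import shutil
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import (  # noqa: E402
    GAPDH_PATTERN,
    SOX21_PATTERN_1,
    SOX21_PATTERN_2,
    RESULTS,
    SCRATCH,
    embed_pattern,
    study_config,
)

from structdrop.synthetic_data import (  # noqa: E402
    FragmentationModel,
    compute_quotients,
    make_genes,
    simulate_study,
)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--quick", action="store_true",
                        help="30 short genes instead of the full study")
    args = parser.parse_args()

    config = study_config(args.seed, quick=args.quick)
    genes, truth = make_genes(config)

    by_class = truth.groupby("class")["base_abundance"].idxmax()
    for i, g in enumerate(genes):
        if g.gene_id == by_class["low"]:
            genes[i] = embed_pattern(g, GAPDH_PATTERN, 50)
        elif g.gene_id == by_class["high"]:
            genes[i] = embed_pattern(
                embed_pattern(g, SOX21_PATTERN_1, 50), SOX21_PATTERN_2, 100
            )
    print(f"control pattern host: {by_class['low']} (low-structure, abundant)")
    print(f"target pattern host:  {by_class['high']} (high-structure, abundant)")

    print(f"folding {config.n_genes} transcripts ...")
    quotients = compute_quotients(genes)

    out_root = SCRATCH / "study"
    if out_root.exists():
        shutil.rmtree(out_root)
    for mode, with_fastq in (("chemical", True), ("mechanical", False)):
        bundle = simulate_study(
            config,
            FragmentationModel(mode),
            out_root / mode,
            quotients=quotients,
            genes_truth=(genes, truth),
            with_fastq=with_fastq,
        )
        zero = (bundle.rnaseq_matrix.values.sum(axis=1) == 0).sum()
        print(f"{mode}: {zero} of {config.n_genes} genes with zero counts "
              f"-> {bundle.directory}")

    truth = truth.assign(quotient=[quotients[g] for g in truth.index])
    summary = (
        truth.groupby("class")
        .agg(
            n=("quotient", "size"),
            median_quotient=("quotient", "median"),
            min_quotient=("quotient", "min"),
            max_quotient=("quotient", "max"),
            median_length=("length", "median"),
        )
        .round(4)
        .loc[["low", "mid", "high"]]
    )
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "study_quotient_summary.tsv", sep="\t")
    print("\nfolded |MFE|/L by structure class:")
    print(summary.to_string())
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
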
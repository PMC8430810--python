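#!/usr/bin/env python
"""The headline contrast: |MFE|/L in detected vs undetected genes.

Joins the folded structure quotients (from the study truth table) with
RNA-seq detection status in each fragmentation mode and runs the two-sided
Mann-Whitney U test, plus the same test on GC fraction as a negative
control. Chemical shearing should give a strongly significant quotient
separation (higher |MFE|/L in undetected genes) with no GC association;
mechanical shearing should give no testable structure effect at all.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import RESULTS, SCRATCH  # noqa: E402

from structdrop.concordance import detection_calls  # noqa: E402
from structdrop.io_formats import ValidationError, read_expression_table  # noqa: E402
from structdrop.structure_stat import (  # noqa: E402
    GeneProfile,
    compare_quotients,
    gc_association_check,
)


def profiles_from_bundle(bundle_dir: Path) -> list[GeneProfile]:
    truth = pd.read_csv(bundle_dir / "truth.tsv", sep="\t", index_col=0)
    rnaseq = read_expression_table(bundle_dir / "rnaseq.tsv", "rnaseq")
    calls = detection_calls(rnaseq)
    from structdrop.io_formats import read_fasta

    gc = {g.gene_id: g.gc_fraction for g in read_fasta(bundle_dir / "genes.fasta")}
    return [
        GeneProfile(
            gene_id=g,
            length=int(row["length"]),
            gc_fraction=gc[g],
            mfe=-row["quotient"] * row["length"],
            quotient=float(row["quotient"]),
            detected_rnaseq=calls.calls[g].detected,
        )
        for g, row in truth.iterrows()
    ]


def main() -> int:
    out = {}
    for mode in ("chemical", "mechanical"):
        bundle_dir = SCRATCH / "study" / mode
        if not bundle_dir.exists():
            print(f"missing {bundle_dir}; run 01_simulate_study.py first")
            return 1
        profiles = profiles_from_bundle(bundle_dir)
        pd.DataFrame([vars(p) for p in profiles]).to_csv(
            RESULTS / f"gene_profiles_{mode}.tsv", sep="\t", index=False
        )
        try:
            q = compare_quotients(profiles)
            gc = gc_association_check(profiles)
            out[mode] = {
                "quotient": {
                    "p_value": q.p_value,
                    "median_detected": q.median_detected,
                    "median_undetected": q.median_undetected,
                    "n_detected": q.n_detected,
                    "n_undetected": q.n_undetected,
                },
                "gc": {"p_value": gc.p_value, "significant": gc.significant},
            }
            print(
                f"{mode}: quotient p={q.p_value:.3g} "
                f"(median detected {q.median_detected:.3f}, "
                f"undetected {q.median_undetected:.3f}); "
                f"GC p={gc.p_value:.3g}"
            )
        except ValidationError as exc:
            out[mode] = {"note": str(exc)}
            print(f"{mode}: {exc}")

    (RESULTS / "quotient_comparison.json").write_text(
        json.dumps(out, indent=2) + "\n"
    )
    print(f"\nwrote {RESULTS}/quotient_comparison.json")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
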
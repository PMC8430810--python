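"""Shared constants and helpers for the numbered analysis drivers."""

from pathlib import Path

from structdrop.io_formats import GeneRecord
from structdrop.synthetic_data import SyntheticConfig

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

# the two SOX21 diagnostic 20-mers and a GAPDH-primer-region control
SOX21_PATTERN_1 = "TACATGATCCCGTGCAACTG"
SOX21_PATTERN_2 = "TTAACCTTTATGTGTAAATG"
GAPDH_PATTERN = "TGGGGAAGGTGAAGGTCGGA"


def study_config(seed: int, quick: bool = False) -> SyntheticConfig:
    if quick:
        return SyntheticConfig(
            n_genes=30, length_range=(200, 400), depth=20_000, seed=seed
        )
    return SyntheticConfig(seed=seed)


def embed_pattern(gene: GeneRecord, dna_pattern: str, position: int) -> GeneRecord:
    """Overwrite a window of the transcript with a diagnostic pattern."""
    rna = dna_pattern.replace("T", "U")
    seq = gene.sequence
    return GeneRecord(gene.gene_id, seq[:position] + rna + seq[position + len(rna) :])
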
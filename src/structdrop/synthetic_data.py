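"""Fully synthetic two-platform study generator.

Emulates the experimental design under scrutiny: the same latent transcript
abundances measured by (a) a microarray, whose fluorescence readout is
independent of RNA secondary structure, and (b) an RNA-seq library built
from 200-500 bp fragments sequenced as 75 bp paired-end reads, where the
fragmentation step may be *chemical* (capture efficiency decays with the
structure quotient q = |MFE|/L) or *mechanical* (structure-blind).

Structure is planted as perfect inverted repeats so that the internal
simplified energy model reliably assigns high q to the high-structure
class; nothing depends on Turner-accurate energies. Defaults are
desk-scale: 100,000 read pairs per sample rather than the tens of millions
of a production run, with two biological replicates per platform.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneRecord,
    ReadPair,
    ValidationError,
    write_expression_table,
    write_fasta,
    write_fastq_pairs,
)
from .folding import EnergyModel
from .structure_stat import _cached_fold, structure_quotient

__all__ = [
    "SyntheticConfig",
    "FragmentationModel",
    "StudyBundle",
    "make_genes",
    "simulate_array",
    "simulate_rnaseq",
    "simulate_study",
]

_RNA_BASES = np.array(list("ACGU"))
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_REPEAT_LOOP = 4  # unpaired nt between the two arms of a planted repeat


def _revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator; defaults are the study design."""

    n_genes: int = 300
    length_range: tuple[int, int] = (500, 3000)
    structure_classes: tuple[tuple[str, float], ...] = (
        ("low", 0.0),
        ("mid", 0.15),
        ("high", 0.35),
    )
    abundance_mu: float = 4.0  # log-normal location (natural log scale)
    abundance_sigma: float = 1.5
    replicate_sigma: float = 0.1  # per-replicate log-normal jitter
    n_replicates: int = 2
    read_length: int = 75
    insert_range: tuple[int, int] = (200, 500)
    depth: int = 100_000  # read pairs per sample
    error_rate: float = 0.0  # optional per-base substitution rate in reads
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.depth < 1 or self.n_replicates < 1:
            raise ValidationError("n_genes, depth and n_replicates must be >= 1")
        for _, sf in self.structure_classes:
            if not 0.0 <= sf < 0.5:
                raise ValidationError(f"stem_fraction {sf} outside [0, 0.5)")
        if self.insert_range[0] > self.length_range[0]:
            raise ValidationError(
                "minimum insert size exceeds the shortest transcript length"
            )


@dataclass(frozen=True)
class FragmentationModel:
    """Whole-molecule capture efficiency as a function of structure.

    chemical:   efficiency(q) = exp(-beta * max(0, q - q0))
    mechanical: efficiency(q) = 1 (structure-blind acoustic shearing)
    """

    mode: str = "chemical"
    beta: float = 40.0
    q0: float = 0.02

    def __post_init__(self) -> None:
        if self.mode not in ("chemical", "mechanical"):
            raise ValidationError(f"unknown fragmentation mode {self.mode!r}")
        if self.beta < 0 or self.q0 < 0:
            raise ValidationError("beta and q0 must be >= 0")

    def efficiency(self, q: float) -> float:
        if q < 0:
            raise ValidationError("structure quotient must be >= 0")
        if self.mode == "mechanical":
            return 1.0
        return math.exp(-self.beta * max(0.0, q - self.q0))


def make_genes(config: SyntheticConfig) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Random transcripts with planted inverted repeats, plus the truth table.

    Each gene is an i.i.d.-uniform RNA sequence; genes of stem fraction
    ``sf > 0`` carry a perfect inverted repeat whose two arms of
    ``round(sf * L / 2)`` nt (separated by a short loop) jointly occupy a
    fraction ``sf`` of the length. Classes rotate round-robin so class
    sizes are balanced. Abundances are log-normal per gene with a small
    per-replicate jitter.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genes: list[GeneRecord] = []
    rows = []
    lo, hi = config.length_range
    for g in range(config.n_genes):
        label, sf = config.structure_classes[g % len(config.structure_classes)]
        length = int(rng.integers(lo, hi + 1))
        arm = round(sf * length / 2)
        if 2 * arm + _REPEAT_LOOP > length:
            raise ValidationError(
                f"stem_fraction {sf} infeasible for length {length}"
            )
        seq = rng.choice(_RNA_BASES, size=length)
        sequence = "".join(seq)
        if arm > 0:
            start = int(rng.integers(0, length - 2 * arm - _REPEAT_LOOP + 1))
            arm_seq = sequence[start : start + arm]
            tail = start + arm + _REPEAT_LOOP
            sequence = (
                sequence[:tail] + _revcomp_rna(arm_seq) + sequence[tail + arm :]
            )
        gene_id = f"SYNG{g:05d}"
        genes.append(GeneRecord(gene_id, sequence))
        base = float(rng.lognormal(config.abundance_mu, config.abundance_sigma))
        jitter = rng.lognormal(0.0, config.replicate_sigma, size=config.n_replicates)
        row = {
            "gene_id": gene_id,
            "class": label,
            "stem_fraction": sf,
            "length": length,
            "base_abundance": base,
        }
        for r in range(config.n_replicates):
            row[f"abundance_rep{r + 1}"] = base * float(jitter[r])
        rows.append(row)
    truth = pd.DataFrame(rows).set_index("gene_id")
    return genes, truth


def _abundance_matrix(truth: pd.DataFrame) -> np.ndarray:
    cols = [c for c in truth.columns if c.startswith("abundance_rep")]
    return truth[cols].to_numpy(dtype=float)


def simulate_array(
    genes: list[GeneRecord],
    truth: pd.DataFrame,
    noise_sd: float = 0.2,
    seed: int = 0,
    gain: float = 100.0,
) -> ExpressionMatrix:
    """Structure-independent fluorescence readout on the log2 scale."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    abund = _abundance_matrix(truth)
    signal = np.log2(abund * gain) + rng.normal(0.0, noise_sd, size=abund.shape)
    return ExpressionMatrix(
        platform="array",
        gene_ids=list(truth.index),
        sample_ids=[f"array_rep{r + 1}" for r in range(abund.shape[1])],
        values=signal,
        log_transformed=True,
    )


def _draw_reads(
    rng: np.random.Generator,
    genes_by_id: dict[str, GeneRecord],
    counts: np.ndarray,
    gene_ids: list[str],
    config: SyntheticConfig,
) -> list[ReadPair]:
    pairs: list[ReadPair] = []
    rl = config.read_length
    ins_lo, ins_hi = config.insert_range
    idx = 0
    for gi, gene_id in enumerate(gene_ids):
        n = int(counts[gi])
        if n == 0:
            continue
        seq = genes_by_id[gene_id].sequence.replace("U", "T")
        L = len(seq)
        frag_hi = min(ins_hi, L)
        frag_lens = rng.integers(min(ins_lo, frag_hi), frag_hi + 1, size=n)
        starts = rng.integers(0, L - frag_lens + 1)
        for fl, st in zip(frag_lens, starts):
            frag = seq[st : st + fl]
            m1 = frag[:rl]
            m2 = _revcomp_dna(frag[-rl:])
            if config.error_rate > 0:
                m1 = _mutate(rng, m1, config.error_rate)
                m2 = _mutate(rng, m2, config.error_rate)
            pairs.append(ReadPair(f"sim:{gene_id}:{idx}", m1, m2))
            idx += 1
    return pairs


_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA_BASES = np.array(list("ACGT"))


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        arr[hit] = rng.choice(_DNA_BASES, size=int(hit.sum()))
    return "".join(arr)


def simulate_rnaseq(
    genes: list[GeneRecord],
    truth: pd.DataFrame,
    quotients: dict[str, float],
    frag: FragmentationModel,
    config: SyntheticConfig,
    seed: int = 0,
    with_fastq: bool = False,
) -> tuple[ExpressionMatrix, list[ReadPair] | None]:
    """Counts (and optionally reads) under a fragmentation model.

    Expected reads for gene g are proportional to
    ``abundance_g * L_g * efficiency(q_g)``; each sample's counts are a
    multinomial draw totalling ``config.depth``. FASTQ reads, when
    requested, are 75 bp mates of uniformly placed 200-500 bp fragments of
    replicate 1's transcripts, mate 2 reverse-complemented.
    """
    missing = [g.gene_id for g in genes if g.gene_id not in quotients]
    if missing:
        raise ValidationError(f"genes without a structure quotient: {missing[:10]}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gene_ids = [g.gene_id for g in genes]
    truth = truth.loc[gene_ids]
    abund = _abundance_matrix(truth)
    lengths = truth["length"].to_numpy(dtype=float)
    eff = np.array([frag.efficiency(quotients[g]) for g in gene_ids])
    weights = abund * (lengths * eff)[:, None]
    counts = np.zeros_like(weights, dtype=np.int64)
    for r in range(weights.shape[1]):
        p = weights[:, r] / weights[:, r].sum()
        counts[:, r] = rng.multinomial(config.depth, p)
    matrix = ExpressionMatrix(
        platform="rnaseq",
        gene_ids=gene_ids,
        sample_ids=[f"rnaseq_rep{r + 1}" for r in range(weights.shape[1])],
        values=counts.astype(float),
    )
    reads = None
    if with_fastq:
        genes_by_id = {g.gene_id: g for g in genes}
        reads = _draw_reads(rng, genes_by_id, counts[:, 0], gene_ids, config)
    return matrix, reads


@dataclass
class StudyBundle:
    """In-memory handles plus on-disk paths of one simulated study."""

    directory: Path
    genes: list[GeneRecord]
    truth: pd.DataFrame
    quotients: dict[str, float]
    array_matrix: ExpressionMatrix
    rnaseq_matrix: ExpressionMatrix
    paths: dict[str, Path] = field(default_factory=dict)


def compute_quotients(
    genes: list[GeneRecord], model: EnergyModel = EnergyModel()
) -> dict[str, float]:
    """Fold every gene (cached) and return its structure quotient."""
    return {
        g.gene_id: structure_quotient(_cached_fold(g, model).energy, g.length)
        for g in genes
    }


def simulate_study(
    config: SyntheticConfig,
    frag: FragmentationModel,
    out_dir: str | Path,
    *,
    force: bool = False,
    model: EnergyModel = EnergyModel(),
    quotients: dict[str, float] | None = None,
    genes_truth: tuple[list[GeneRecord], pd.DataFrame] | None = None,
    with_fastq: bool = True,
    array_noise_sd: float = 0.2,
) -> StudyBundle:
    """Generate and write a complete study bundle plus manifest.

    Precomputed ``quotients`` (and a prebuilt ``genes_truth`` pair, e.g.
    with diagnostic patterns embedded) may be passed to reuse genes and
    folds across matched chemical/mechanical runs.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise ValidationError(
            f"output directory {out_dir} is not empty (use force to overwrite)"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(config.seed).generate_state(3)
    genes, truth = genes_truth if genes_truth is not None else make_genes(config)
    if quotients is None:
        quotients = compute_quotients(genes, model)
    array = simulate_array(genes, truth, noise_sd=array_noise_sd, seed=int(seeds[1]))
    rnaseq, reads = simulate_rnaseq(
        genes, truth, quotients, frag, config, seed=int(seeds[2]), with_fastq=with_fastq
    )

    paths = {
        "fasta": out_dir / "genes.fasta",
        "truth": out_dir / "truth.tsv",
        "array": out_dir / "array.tsv",
        "rnaseq": out_dir / "rnaseq.tsv",
        "manifest": out_dir / "manifest.json",
    }
    write_fasta(genes, paths["fasta"])
    truth_out = truth.copy()
    truth_out["quotient"] = [quotients[g] for g in truth.index]
    truth_out.to_csv(paths["truth"], sep="\t")
    write_expression_table(array, paths["array"])
    write_expression_table(rnaseq, paths["rnaseq"])
    if reads is not None:
        paths["fastq1"] = out_dir / "reads_1.fastq"
        paths["fastq2"] = out_dir / "reads_2.fastq"
        write_fastq_pairs(reads, paths["fastq1"], paths["fastq2"])

    cfg_dict = asdict(config)
    cfg_dict["structure_classes"] = [list(c) for c in config.structure_classes]
    manifest = {
        "seed": config.seed,
        "mode": frag.mode,
        "config": cfg_dict,
        "fragmentation": asdict(frag),
        "param_hash": hashlib.sha1(
            json.dumps([cfg_dict, asdict(frag)], sort_keys=True).encode()
        ).hexdigest(),
        "files": {k: p.name for k, p in paths.items() if k != "manifest"},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return StudyBundle(
        directory=out_dir,
        genes=genes,
        truth=truth,
        quotients=quotients,
        array_matrix=array,
        rnaseq_matrix=rnaseq,
        paths=paths,
    )
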
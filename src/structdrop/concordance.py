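"""Cross-platform detection concordance.

A gene measured on a cDNA microarray always yields some fluorescence
signal, whereas an RNA-seq experiment can return exactly zero reads for a
transcript that is demonstrably present in the cell. This module classifies
per-gene detection status on each platform, partitions the shared gene
universe into detected-both / array-only / seq-only / neither, and measures
the Spearman rank correlation of mean log2 signal over co-detected genes.

Detection rules
---------------
* RNA-seq: detected iff the total (normalized) count across all replicates
  exceeds ``rnaseq_min_total`` (default 0, i.e. any read at all counts).
* Array: arrays have no natural zero, so detection is thresholded at a
  configurable mean-log2-signal cutoff ``tau_array``; by default the 25th
  percentile of the matrix's per-gene mean log2 signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix, ValidationError

__all__ = [
    "DetectionPolicy",
    "DetectionCall",
    "DetectionCallSet",
    "ConcordanceTable",
    "detection_calls",
    "log2_transform",
    "cross_platform_classify",
    "spearman_codetected",
    "relative_expression",
]


@dataclass(frozen=True)
class DetectionPolicy:
    """Per-platform detection rules.

    tau_array: mean-log2-signal threshold for arrays; ``None`` means use
        the ``array_quantile`` percentile of the per-gene means.
    rnaseq_min_total: a gene is seq-detected iff its summed counts across
        samples strictly exceed this (default 0: "no read counts" = dropout).
    """

    tau_array: float | None = None
    array_quantile: float = 0.25
    rnaseq_min_total: float = 0.0


@dataclass(frozen=True)
class DetectionCall:
    detected: bool
    mean_signal: float


@dataclass
class DetectionCallSet:
    platform: str
    calls: dict[str, DetectionCall]
    threshold: float | None = None

    @property
    def universe(self) -> set[str]:
        return set(self.calls)

    def detected_genes(self) -> set[str]:
        return {g for g, c in self.calls.items() if c.detected}


@dataclass
class ConcordanceTable:
    """Partition of the shared gene universe plus co-detected correlation."""

    both: set[str]
    array_only: set[str]
    seq_only: set[str]
    neither: set[str]
    private_array: set[str] = field(default_factory=set)
    private_seq: set[str] = field(default_factory=set)
    spearman_rho: float = float("nan")
    n_codetected: int = 0

    @property
    def universe(self) -> set[str]:
        return self.both | self.array_only | self.seq_only | self.neither


def log2_transform(matrix: ExpressionMatrix, pseudocount: float | None = None) -> ExpressionMatrix:
    """Return a log2-transformed copy; errors if already transformed.

    Default pseudocount is 1 for counts and 0 for array signals.
    """
    if matrix.log_transformed:
        raise ValidationError("matrix is already log2-transformed")
    if pseudocount is None:
        pseudocount = 1.0 if matrix.platform == "rnaseq" else 0.0
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    shifted = matrix.values + pseudocount
    if np.any(shifted <= 0):
        raise ValidationError(
            "value + pseudocount <= 0 encountered; increase the pseudocount"
        )
    return ExpressionMatrix(
        platform=matrix.platform,
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=np.log2(shifted),
        log_transformed=True,
    )


def detection_calls(
    matrix: ExpressionMatrix, policy: DetectionPolicy = DetectionPolicy()
) -> DetectionCallSet:
    """Call per-gene detection status under the platform's rule."""
    if matrix.n_genes == 0 or matrix.n_samples == 0:
        raise ValidationError("cannot call detection on an empty matrix")
    means = matrix.mean_per_gene()
    if matrix.platform == "rnaseq":
        totals = matrix.values.sum(axis=1)
        if matrix.log_transformed:
            raise ValidationError(
                "rnaseq detection operates on raw normalized counts, not log2"
            )
        detected = totals > policy.rnaseq_min_total
        threshold = policy.rnaseq_min_total
    else:
        if matrix.log_transformed:
            log_means = means.to_numpy()
        else:
            log_means = np.log2(matrix.values + 1.0).mean(axis=1)
        tau = (
            policy.tau_array
            if policy.tau_array is not None
            else float(np.percentile(log_means, 100 * policy.array_quantile))
        )
        detected = log_means > tau
        threshold = tau
    calls = {
        g: DetectionCall(bool(d), float(m))
        for g, d, m in zip(matrix.gene_ids, detected, means.to_numpy())
    }
    return DetectionCallSet(matrix.platform, calls, threshold=threshold)


def cross_platform_classify(
    array_calls: DetectionCallSet, seq_calls: DetectionCallSet
) -> ConcordanceTable:
    """Partition the shared gene universe into the four Fig-1-style classes.

    Genes private to one platform's universe (e.g. probes with no Ensembl
    mapping) are reported separately, never silently dropped.
    """
    if array_calls.platform != "array" or seq_calls.platform != "rnaseq":
        raise ValidationError(
            "expected (array, rnaseq) call sets, got "
            f"({array_calls.platform}, {seq_calls.platform})"
        )
    shared = array_calls.universe & seq_calls.universe
    if not shared:
        raise ValidationError("platform gene universes do not overlap")
    a_det = array_calls.detected_genes()
    s_det = seq_calls.detected_genes()
    return ConcordanceTable(
        both={g for g in shared if g in a_det and g in s_det},
        array_only={g for g in shared if g in a_det and g not in s_det},
        seq_only={g for g in shared if g not in a_det and g in s_det},
        neither={g for g in shared if g not in a_det and g not in s_det},
        private_array=array_calls.universe - shared,
        private_seq=seq_calls.universe - shared,
    )


def spearman_codetected(
    array_matrix: ExpressionMatrix,
    seq_matrix: ExpressionMatrix,
    table: ConcordanceTable,
) -> float:
    """Spearman rho of mean log2 signal over co-detected genes.

    Both matrices must already be log2-transformed; ties get average ranks
    (scipy's default). Updates ``table.spearman_rho`` in place and returns it.
    """
    if not (array_matrix.log_transformed and seq_matrix.log_transformed):
        raise ValidationError("both matrices must be log2-transformed first")
    genes = sorted(table.both)
    if len(genes) < 3:
        raise ValidationError(
            f"need >= 3 co-detected genes for a rank correlation, have {len(genes)}"
        )
    a = array_matrix.mean_per_gene().loc[genes].to_numpy()
    b = seq_matrix.mean_per_gene().loc[genes].to_numpy()
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    if np.array_equal(ra, rb):  # perfectly concordant ranks: exactly +1
        rho = 1.0
    elif np.array_equal(ra + rb, np.full_like(ra, len(ra) + 1.0)):
        rho = -1.0  # perfectly reversed ranks: exactly -1
    else:
        rho = float(stats.spearmanr(a, b).statistic)
    table.spearman_rho = rho
    table.n_codetected = len(genes)
    return rho


def relative_expression(
    matrix: ExpressionMatrix, gene_id: str, housekeeper_id: str
) -> float:
    """Mean across samples of gene / housekeeper on the native scale.

    This is the standard housekeeper normalization used when comparing
    expression of a gene of interest (e.g. SOX3) against a reference such
    as GAPDH across a deposited count matrix.
    """
    if matrix.log_transformed:
        raise ValidationError("relative expression requires the linear scale")
    frame = matrix.to_frame()
    for g in (gene_id, housekeeper_id):
        if g not in frame.index:
            raise KeyError(f"gene {g!r} not present in the matrix")
    hk = frame.loc[housekeeper_id]
    if np.any(hk.to_numpy() <= 0):
        raise ValidationError("housekeeper has a zero signal in some sample")
    return float((frame.loc[gene_id] / hk).mean())
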
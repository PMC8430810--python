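"""Per-gene structure statistics and the detected-vs-undetected contrast.

The central statistic is the structure quotient q = |MFE| / L, the folding
free-energy magnitude normalized by transcript length. Genes that drop out
of RNA-seq after chemical fragmentation are expected to carry higher q than
genes that remain detectable; GC content, in contrast, should not separate
the groups. Both contrasts are made falsifiable with a two-sided
Mann-Whitney U test (average-rank ties).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .concordance import DetectionCallSet
from .folding import EnergyModel, FoldResult, fold_mfe
from .io_formats import GeneRecord, ValidationError

__all__ = [
    "GeneProfile",
    "GroupComparison",
    "gc_content",
    "structure_quotient",
    "profile_genes",
    "compare_quotients",
    "gc_association_check",
    "clear_fold_cache",
]

# fold results are expensive; cache across calls keyed by (sequence, model)
_FOLD_CACHE: dict[tuple[str, EnergyModel], FoldResult] = {}


def clear_fold_cache() -> None:
    _FOLD_CACHE.clear()


def _cached_fold(gene: GeneRecord, model: EnergyModel) -> FoldResult:
    digest = hashlib.sha1(gene.sequence.encode()).hexdigest()
    key = (digest, model)
    if key not in _FOLD_CACHE:
        # energy-only: |MFE|/L profiling never needs the witness structure
        _FOLD_CACHE[key] = fold_mfe(gene, model, with_structure=False)
    return _FOLD_CACHE[key]


@dataclass(frozen=True)
class GeneProfile:
    gene_id: str
    length: int
    gc_fraction: float
    mfe: float
    quotient: float
    detected_rnaseq: bool
    engine: str = "internal"


@dataclass(frozen=True)
class GroupComparison:
    n_detected: int
    n_undetected: int
    median_detected: float
    median_undetected: float
    statistic_u: float
    p_value: float
    variable: str = "quotient"

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def gc_content(gene: GeneRecord | str) -> float:
    """(#G + #C) / L of a normalized (RNA or DNA) sequence."""
    seq = gene.sequence if isinstance(gene, GeneRecord) else gene.upper()
    if not seq:
        raise ValidationError("empty sequence has no GC content")
    return (seq.count("G") + seq.count("C")) / len(seq)


def structure_quotient(mfe: float, length: int) -> float:
    """|MFE| / L in kcal/(mol*nt); the length-adjusted structure score."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    if mfe > 0:
        raise ValidationError(f"MFE must be <= 0, got {mfe}")
    return abs(mfe) / length


def profile_genes(
    genes: list[GeneRecord],
    calls: DetectionCallSet,
    model: EnergyModel = EnergyModel(),
) -> list[GeneProfile]:
    """Fold every gene once (cached by sequence) and join detection calls."""
    missing = [g.gene_id for g in genes if g.gene_id not in calls.calls]
    if missing:
        raise ValidationError(f"genes without a detection call: {missing[:10]}")
    profiles = []
    for gene in genes:
        fold = _cached_fold(gene, model)
        profiles.append(
            GeneProfile(
                gene_id=gene.gene_id,
                length=gene.length,
                gc_fraction=gene.gc_fraction,
                mfe=fold.energy,
                quotient=structure_quotient(fold.energy, gene.length),
                detected_rnaseq=calls.calls[gene.gene_id].detected,
                engine=fold.provenance,
            )
        )
    return profiles


def _rank_compare(det: np.ndarray, undet: np.ndarray, variable: str) -> GroupComparison:
    if len(det) < 3 or len(undet) < 3:
        raise ValidationError(
            f"need >= 3 genes per group for the rank test "
            f"(detected={len(det)}, undetected={len(undet)}); "
            "report descriptive medians only"
        )
    if np.ptp(np.concatenate([det, undet])) == 0:
        # all values identical: no separation by definition
        u = len(det) * len(undet) / 2.0
        p = 1.0
    else:
        res = stats.mannwhitneyu(undet, det, alternative="two-sided")
        u, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        n_detected=len(det),
        n_undetected=len(undet),
        median_detected=float(np.median(det)),
        median_undetected=float(np.median(undet)),
        statistic_u=u,
        p_value=p,
        variable=variable,
    )


def _split(profiles: list[GeneProfile], attr: str) -> tuple[np.ndarray, np.ndarray]:
    engines = {p.engine for p in profiles}
    if len(engines) > 1:
        raise ValidationError(
            f"profiles mix folding engines {sorted(engines)}; energies are "
            "not comparable across engines"
        )
    det = np.array([getattr(p, attr) for p in profiles if p.detected_rnaseq])
    undet = np.array([getattr(p, attr) for p in profiles if not p.detected_rnaseq])
    return det, undet


def compare_quotients(profiles: list[GeneProfile]) -> GroupComparison:
    """Two-sided Mann-Whitney U on q between detected and undetected genes.

    U is reported for the undetected group ranked against the detected one,
    so large U with small p means undetected genes carry the higher q.
    """
    det, undet = _split(profiles, "quotient")
    return _rank_compare(det, undet, "quotient")


def gc_association_check(profiles: list[GeneProfile]) -> GroupComparison:
    """Same rank test applied to GC fraction (expected non-significant)."""
    det, undet = _split(profiles, "gc_fraction")
    return _rank_compare(det, undet, "gc_fraction")
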
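import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from structdrop.io_formats import ExpressionMatrix
from structdrop.synthetic_data import (
    FragmentationModel,
    SyntheticConfig,
    make_genes,
    simulate_rnaseq,
    simulate_study,
)

RNA = list("ACGU")
DNA = list("ACGT")


def random_rna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(RNA, size=length, p=p))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(DNA, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_array_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        platform="array",
        gene_ids=["g1", "g2", "g3", "g4"],
        sample_ids=["s1", "s2"],
        values=np.array([[2.0, 2.0], [4.0, 4.0], [6.0, 6.0], [8.0, 8.0]]),
        log_transformed=True,
    )


@pytest.fixture(scope="session")
def small_study(tmp_path_factory) -> dict:
    """One small chemical-mode study bundle, shared across tests.

    Short transcripts keep folding fast; depth is desk-scale.
    """
    config = SyntheticConfig(
        n_genes=30, length_range=(200, 400), depth=20_000, seed=42
    )
    frag = FragmentationModel(mode="chemical")
    out = tmp_path_factory.mktemp("study") / "chemical"
    bundle = simulate_study(config, frag, out, with_fastq=True)
    return {"config": config, "frag": frag, "bundle": bundle}
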
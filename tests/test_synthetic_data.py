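import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from structdrop.io_formats import (
    ValidationError,
    read_expression_table,
    read_fasta,
    read_fastq_pairs,
)
from structdrop.synthetic_data import (
    FragmentationModel,
    SyntheticConfig,
    make_genes,
    simulate_array,
    simulate_rnaseq,
    simulate_study,
)

_RNA_RC = str.maketrans("ACGU", "UGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RNA_RC)[::-1]


class TestFragmentationModel:
    def test_mechanical_is_constant(self):
        frag = FragmentationModel(mode="mechanical")
        assert all(frag.efficiency(q) == 1.0 for q in (0.0, 0.1, 0.5, 2.0))

    @settings(max_examples=100, derandomize=True)
    @given(q1=st.floats(0, 2), q2=st.floats(0, 2))
    def test_chemical_non_increasing_and_bounded(self, q1, q2):
        frag = FragmentationModel(mode="chemical")
        lo, hi = sorted((q1, q2))
        assert 0 < frag.efficiency(hi) <= frag.efficiency(lo) <= 1.0

    def test_below_threshold_unpenalized(self):
        frag = FragmentationModel(mode="chemical", beta=40.0, q0=0.02)
        assert frag.efficiency(0.01) == 1.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            FragmentationModel(mode="sonic")


class TestMakeGenes:
    def test_deterministic(self):
        config = SyntheticConfig(n_genes=12, length_range=(100, 300), insert_range=(50, 150), seed=5)
        genes1, truth1 = make_genes(config)
        genes2, truth2 = make_genes(config)
        assert genes1 == genes2
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_inverted_repeat_planted(self):
        config = SyntheticConfig(
            n_genes=3,
            length_range=(1000, 1000),
            structure_classes=(("high", 0.35),),
            seed=3,
        )
        genes, truth = make_genes(config)
        for gene in genes:
            seq = gene.sequence
            arm = 175  # 0.35 * 1000 / 2
            found = any(
                _revcomp(seq[s : s + arm]) in seq[s + arm :]
                for s in range(0, 1000 - 2 * arm)
            )
            assert found, f"no {arm} nt inverted repeat in {gene.gene_id}"

    def test_classes_rotate_evenly(self):
        config = SyntheticConfig(n_genes=9, length_range=(100, 200), insert_range=(50, 150), seed=0)
        _, truth = make_genes(config)
        assert truth["class"].value_counts().to_dict() == {
            "low": 3, "mid": 3, "high": 3
        }

    def test_abundances_lognormal_scale(self):
        config = SyntheticConfig(n_genes=400, length_range=(100, 120), insert_range=(50, 100), seed=7)
        _, truth = make_genes(config)
        logs = np.log(truth["base_abundance"])
        assert abs(logs.mean() - 4.0) < 0.25
        assert abs(logs.std() - 1.5) < 0.2

    def test_infeasible_insert_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(length_range=(100, 300), insert_range=(200, 500))


class TestSimulateArray:
    def test_noise_free_signal_monotone_in_abundance(self):
        config = SyntheticConfig(n_genes=30, length_range=(100, 200), insert_range=(50, 150), seed=1)
        genes, truth = make_genes(config)
        matrix = simulate_array(genes, truth, noise_sd=0.0, seed=0)
        order_sig = np.argsort(matrix.values[:, 0])
        order_ab = np.argsort(truth["abundance_rep1"].to_numpy())
        np.testing.assert_array_equal(order_sig, order_ab)

    def test_signal_independent_of_structure_class(self):
        config = SyntheticConfig(n_genes=500, length_range=(150, 250), insert_range=(50, 150), seed=2)
        genes, truth = make_genes(config)
        matrix = simulate_array(genes, truth, noise_sd=0.2, seed=3)
        r = np.corrcoef(matrix.values[:, 0], truth["stem_fraction"])[0, 1]
        assert abs(r) < 0.1

    def test_replicates_correlated(self):
        config = SyntheticConfig(n_genes=300, length_range=(150, 250), insert_range=(50, 150), seed=4)
        genes, truth = make_genes(config)
        matrix = simulate_array(genes, truth, noise_sd=0.2, seed=5)
        r = np.corrcoef(matrix.values[:, 0], matrix.values[:, 1])[0, 1]
        assert r > 0.9


def _synthetic_quotients(truth, rng, spread=0.02):
    # plausible class-dependent quotients without paying for folding
    base = {"low": 0.26, "mid": 0.40, "high": 0.55}
    return {
        g: base[c] + float(rng.normal(0, spread))
        for g, c in truth["class"].items()
    }


class TestSimulateRnaseq:
    @pytest.fixture()
    def study(self, rng):
        config = SyntheticConfig(n_genes=500, length_range=(500, 800), seed=6)
        genes, truth = make_genes(config)
        return config, genes, truth, _synthetic_quotients(truth, rng)

    def test_counts_conserve_depth(self, study):
        config, genes, truth, q = study
        matrix, _ = simulate_rnaseq(
            genes, truth, q, FragmentationModel("chemical"), config, seed=0
        )
        np.testing.assert_array_equal(
            matrix.values.sum(axis=0), [config.depth] * config.n_replicates
        )

    def test_mechanical_counts_independent_of_structure(self, study):
        from scipy import stats

        config, genes, truth, q = study
        matrix, _ = simulate_rnaseq(
            genes, truth, q, FragmentationModel("mechanical"), config, seed=1
        )
        ratio = (matrix.values[:, 0] + 1) / (
            truth["abundance_rep1"] * truth["length"]
        )
        rho = stats.spearmanr(ratio, truth["stem_fraction"]).statistic
        assert abs(rho) < 0.1

    def test_chemical_dropout_concentrates_in_high_class(self, study):
        config, genes, truth, q = study
        matrix, _ = simulate_rnaseq(
            genes, truth, q, FragmentationModel("chemical"), config, seed=2
        )
        zero = matrix.values.sum(axis=1) == 0
        zero_rate = pd.Series(zero, index=truth.index).groupby(truth["class"]).mean()
        assert zero_rate["high"] > zero_rate["low"] + 0.5

    def test_fastq_read_count_matches_depth(self):
        config = SyntheticConfig(
            n_genes=10, length_range=(300, 500), depth=500, seed=8
        )
        genes, truth = make_genes(config)
        q = {g.gene_id: 0.0 for g in genes}
        _, reads = simulate_rnaseq(
            genes, truth, q, FragmentationModel("mechanical"), config,
            seed=3, with_fastq=True,
        )
        assert len(reads) == config.depth  # pairs; 2x records across files
        assert all(len(p.mate1) <= config.read_length for p in reads)

    def test_missing_quotient_rejected(self, study):
        config, genes, truth, q = study
        q = dict(q)
        q.pop(genes[0].gene_id)
        with pytest.raises(ValidationError, match="quotient"):
            simulate_rnaseq(
                genes, truth, q, FragmentationModel("chemical"), config
            )


class TestSimulateStudy:
    def test_bundle_files_parse(self, small_study):
        bundle = small_study["bundle"]
        genes = read_fasta(bundle.paths["fasta"])
        assert [g.gene_id for g in genes] == bundle.rnaseq_matrix.gene_ids
        array = read_expression_table(
            bundle.paths["array"], "array", log_transformed=True
        )
        rnaseq = read_expression_table(bundle.paths["rnaseq"], "rnaseq")
        np.testing.assert_allclose(array.values, bundle.array_matrix.values)
        np.testing.assert_allclose(rnaseq.values, bundle.rnaseq_matrix.values)
        n_pairs = sum(1 for _ in read_fastq_pairs(
            bundle.paths["fastq1"], bundle.paths["fastq2"]
        ))
        assert n_pairs == small_study["config"].depth

    def test_manifest_records_seed(self, small_study):
        import json

        manifest = json.loads(small_study["bundle"].paths["manifest"].read_text())
        assert manifest["seed"] == small_study["config"].seed
        assert manifest["mode"] == "chemical"
        assert "param_hash" in manifest

    def test_refuses_nonempty_directory(self, small_study):
        with pytest.raises(ValidationError, match="not empty"):
            simulate_study(
                small_study["config"],
                small_study["frag"],
                small_study["bundle"].directory,
            )

    def test_deterministic_given_seed(self, tmp_path):
        config = SyntheticConfig(
            n_genes=6, length_range=(150, 250), insert_range=(50, 150),
            depth=1000, seed=9,
        )
        frag = FragmentationModel("chemical")
        b1 = simulate_study(config, frag, tmp_path / "a", with_fastq=True)
        b2 = simulate_study(config, frag, tmp_path / "b", with_fastq=True)
        for key in ("fasta", "truth", "array", "rnaseq", "fastq1", "fastq2"):
            assert b1.paths[key].read_bytes() == b2.paths[key].read_bytes()
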
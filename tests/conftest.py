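import numpy as np
import pytest

from epioverlap import simulate


@pytest.fixture(scope="session")
def small_genome():
    """3 chromosomes x 5 Mb, 300 non-overlapping genes."""
    return simulate.generate_genome(
        n_chromosomes=3, chrom_length=5_000_000, n_genes=300,
        gene_length_range=(1_000, 10_000), seed=11,
    )


@pytest.fixture(scope="session")
def annotation(small_genome):
    _, genes = small_genome
    return simulate.generate_genesets(
        genes, n_sets=60, size_range=(10, 120), broad_fraction=0.2, seed=11
    )


@pytest.fixture(scope="session")
def architecture_05(small_genome):
    _, genes = small_genome
    return simulate.generate_architecture(
        genes, n_causal=60, n_associated=60, overlap_proportion=0.5, seed=11
    )


@pytest.fixture(scope="session")
def trait_bundle(tmp_path_factory, small_genome, annotation, architecture_05):
    """A complete on-disk synthetic trait bundle (GWAS + EWAS)."""
    layout, genes = small_genome
    gwas_df, gwas_truth = simulate.generate_study(
        architecture_05, simulate.StudyDesign("gwas", power=0.9),
        layout, genes, seed=21,
    )
    ewas_df, ewas_truth = simulate.generate_study(
        architecture_05, simulate.StudyDesign("ewas", power=0.9),
        layout, genes, seed=22,
    )
    out = tmp_path_factory.mktemp("bundle")
    paths = simulate.write_bundle(
        out, layout, genes, annotation, gwas_df, ewas_df,
        truth={"gwas": gwas_truth.detected_genes, "ewas": ewas_truth.detected_genes},
    )
    paths["gwas_truth"] = gwas_truth
    paths["ewas_truth"] = ewas_truth
    return paths


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
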
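import pytest

from nichestate.simulate import CohortDesign, generate_cohort


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """The default study-condition cohort (2,000 genes, 3 reps/group, seed 1)."""
    out = tmp_path_factory.mktemp("cohort_default")
    return generate_cohort(CohortDesign(seed=1), str(out))


@pytest.fixture(scope="session")
def null_cohort(tmp_path_factory):
    """Cohort with no planted tissue DEGs (type-I error checks)."""
    out = tmp_path_factory.mktemp("cohort_null")
    return generate_cohort(CohortDesign(seed=2, deg_fraction=0.0), str(out))


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A fast small cohort for plumbing tests."""
    out = tmp_path_factory.mktemp("cohort_small")
    design = CohortDesign(
        n_genes=200,
        n_spikeins=20,
        chrom_sizes={"chr1": 11_000_000, "chr2": 11_000_000},
        seed=5,
    )
    return generate_cohort(design, str(out))
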
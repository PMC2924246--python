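import numpy as np
import pytest

import nucbarrier as nb


@pytest.fixture(scope="session")
def tonks_params():
    return nb.TonksParams(b=147.0, dbar=177.0)


@pytest.fixture(scope="session")
def cohort():
    """Mid-size seeded cohort shared by the module-level tests.

    800 genes keeps generation and alignment under a few seconds while the
    gene-averaged profile is clean enough for parameter-recovery checks.
    """
    sc = nb.SyntheticConfig(seed=7, n_genes=800)
    return nb.simulate_cohort(sc)


@pytest.fixture(scope="session")
def cohort_density(cohort):
    chrom_len = cohort.truth.attrs["chrom_length"]
    return nb.reads_to_density(
        cohort.reads, b=cohort.config.b, chrom_sizes={cohort.config.chrom: chrom_len}
    )


@pytest.fixture(scope="session")
def cohort_profiles(cohort, cohort_density):
    anchors = nb.find_flanking(cohort.genes, cohort.calls)
    pp = nb.align_average(cohort_density, anchors, window=2000, anchor_col="plus1")
    pm = nb.align_average(cohort_density, anchors, window=2000, anchor_col="minus1")
    return pp, pm


@pytest.fixture(scope="session")
def model_profile(tonks_params):
    """Noiseless profile generated by the analytic model itself (A=2, x0=0)."""
    p = nb.FitModelParams(A=2.0, x0=0.0, tonks=tonks_params)
    offs = np.arange(-2000, 2001)
    vals = np.asarray(nb.fit_model(offs.astype(float), p))
    return nb.AlignedProfile(
        offsets=offs, mean_weight=vals, n_genes=np.full(len(offs), 100, dtype=int)
    )
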
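import numpy as np
import pandas as pd
import pytest

from lungrisk.io_core import (
    CohortBundle,
    GenotypeMatrix,
    PhenotypeTable,
    VariantRecord,
    packaged_weight_table,
)
from lungrisk.simulate import SimSpec, SimVariant, simulate_cohort, spec_from_weights


@pytest.fixture(scope="session")
def weights():
    return packaged_weight_table()


@pytest.fixture(scope="session")
def table1_cohort(weights):
    """One training-size cohort simulated under the packaged weight set."""
    spec = spec_from_weights(weights, seed=20_001)
    bundle, truth = simulate_cohort(spec)
    return bundle, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 10-SNP cohort (600 cases / 900 controls) for unit tests."""
    variants = [
        SimVariant(f"rs{j}", chrom=str(1 + j // 4), pos=1_000_000 * (j + 1),
                   freq=0.1 + 0.05 * j, or_per_allele=1.0 + 0.08 * (j % 4))
        for j in range(10)
    ]
    spec = SimSpec(n_cases=600, n_controls=900, variants=variants,
                   prevalence=0.05, seed=77)
    bundle, truth = simulate_cohort(spec)
    return bundle, truth


def make_cohort(dosages, status, smoking=None, variants=None):
    """Hand-build a CohortBundle from raw arrays (unit-test helper)."""
    dosages = np.asarray(dosages, float)
    n, p = dosages.shape
    if variants is None:
        variants = [
            VariantRecord(rsid=f"v{j}", chrom="1", pos=1000 + j, allele_a="A",
                          allele_b="B", effect_allele="B", maf=0.3)
            for j in range(p)
        ]
    ids = [f"s{i}" for i in range(n)]
    gm = GenotypeMatrix(ids, variants, dosages)
    frame = pd.DataFrame({"sample_id": ids, "status": np.asarray(status, int)})
    if smoking is not None:
        frame["smoking"] = np.asarray(smoking, int)
    return CohortBundle(genotypes=gm, phenotypes=PhenotypeTable(frame))
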
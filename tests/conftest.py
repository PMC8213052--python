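import numpy as np
import pandas as pd
import pytest

from condgwas.io_qc import GenotypeMatrix, SnpMeta, _annotate_freq


def make_genotypes(calls, subjects=None, snp_ids=None):
    """GenotypeMatrix from a raw (n_subjects x n_snps) dosage array."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    subjects = subjects or [f"s{i}" for i in range(n)]
    snp_ids = snp_ids or [f"snp{j}" for j in range(m)]
    snps = [SnpMeta(sid, j % 22 + 1, 1000 + j, "A", "G") for j, sid in enumerate(snp_ids)]
    g = GenotypeMatrix(subjects, snps, calls)
    _annotate_freq(g)
    return g


def make_cohort(n=None, sex=None, ethnicity=None, y=None, seed=0, **cofactors):
    """Minimal cohort table; omitted columns are filled deterministically."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = len(sex) if sex is not None else len(ethnicity)
    sex = np.asarray(sex) if sex is not None else rng.integers(0, 2, n)
    ethnicity = np.asarray(ethnicity) if ethnicity is not None else rng.choice([1, 2, 3, 4], n)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "sex": sex,
            "ethnicity": ethnicity,
        }
    )
    if y is not None:
        df["bsa"] = np.asarray(y, dtype=float)
    for k, v in cofactors.items():
        df[k] = v
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
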
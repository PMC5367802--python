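import numpy as np
import pytest

from exclucomb import GenotypeDataset


@pytest.fixture
def d0() -> GenotypeDataset:
    """Four-subject, three-SNP dataset small enough to enumerate by hand.

    Patients P1=(0,1,2), P2=(0,1,0); controls C1=(0,0,2), C2=(1,1,0).
    Its minimal patient-exclusive combinations are the three pairs
    {s1:0,s2:1} -> {P1,P2}, {s1:0,s3:0} -> {P2}, {s2:1,s3:2} -> {P1}.
    """
    return GenotypeDataset(
        ["P1", "P2", "C1", "C2"],
        [True, True, False, False],
        ["s1", "s2", "s3"],
        np.array([[0, 1, 2], [0, 1, 0], [0, 0, 2], [1, 1, 0]]),
    )


def random_dataset(
    rng: np.random.Generator,
    max_snps: int = 8,
    max_subjects: int = 20,
    with_missing: bool = True,
) -> GenotypeDataset:
    """A small random dataset with at least one patient and one control."""
    n_sub = int(rng.integers(4, max_subjects + 1))
    n_snps = int(rng.integers(2, max_snps + 1))
    n_pat = int(rng.integers(1, n_sub))
    labels = np.zeros(n_sub, dtype=bool)
    labels[rng.choice(n_sub, n_pat, replace=False)] = True
    low = -1 if with_missing else 0
    geno = rng.integers(low, 3, size=(n_sub, n_snps))
    return GenotypeDataset(
        [f"s{i}" for i in range(n_sub)],
        labels,
        [f"r{j}" for j in range(n_snps)],
        geno,
    )
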
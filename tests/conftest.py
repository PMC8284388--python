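import numpy as np
import pandas as pd
import pytest

from irtpipe.prs import GenotypeMatrix, WeightTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_weights() -> WeightTable:
    return WeightTable(
        pd.DataFrame(
            {
                "id": ["rs1", "rs2", "rs3"],
                "chrom": ["1", "1", "2"],
                "pos": [100, 200, 300],
                "effect_allele": ["A", "C", "G"],
                "other_allele": ["G", "T", "A"],
                "weight": [0.5, -0.2, 0.1],
            }
        )
    )


@pytest.fixture
def toy_genotypes() -> GenotypeMatrix:
    """4 individuals x 3 variants; coded (alt) allele equals the effect allele."""
    dosages = np.array(
        [
            [2.0, 1.0, 0.0],
            [0.0, 2.0, 1.0],
            [1.0, 0.0, 2.0],
            [1.0, 1.0, 1.0],
        ]
    )
    variants = pd.DataFrame(
        {
            "id": ["rs1", "rs2", "rs3"],
            "chrom": ["1", "1", "2"],
            "pos": [100, 200, 300],
            "ref": ["G", "T", "A"],
            "alt": ["A", "C", "G"],
        }
    )
    return GenotypeMatrix(dosages, ["a", "b", "c", "d"], variants)
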
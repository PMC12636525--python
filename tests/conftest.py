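import pandas as pd
import pytest


@pytest.fixture
def toy_meta() -> pd.DataFrame:
    """Three genera of two genomes each, spanning all habitat labels."""
    return pd.DataFrame(
        {
            "genome_id": [f"g{i}" for i in range(1, 7)],
            "genus": ["A", "A", "B", "B", "C", "C"],
            "habitat": ["coastal", "coastal", "offshore", "offshore",
                        "rare", "rare"],
        }
    )


@pytest.fixture
def toy_matrix() -> pd.DataFrame:
    """One cluster per category: core, singleton, genus-specific(A),
    multi-genus-specific(A,B), and a partially shared accessory cluster."""
    genomes = [f"g{i}" for i in range(1, 7)]
    rows = {
        "c_core": [1, 1, 1, 1, 1, 1],
        "c_single": [1, 0, 0, 0, 0, 0],
        "c_genusA": [1, 1, 0, 0, 0, 0],
        "c_multiAB": [1, 1, 1, 1, 0, 0],
        "c_other": [1, 0, 1, 0, 0, 0],
    }
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=genomes)
    matrix.index.name = "cluster_id"
    return matrix
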
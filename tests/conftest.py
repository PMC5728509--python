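import numpy as np
import pytest

from crclassify import LabeledExpressionSet, PipelineConfig, SyntheticSpec, generate_dataset

# The six-sample prostate example: samples as rows, final label column.
TABLE1_ROWS = [
    ("X1", [9, -11.4, 2.7, 0.6, 4.3, 28, 37.3], "Normal"),
    ("X2", [-1, 17, 0, 3, 6, -6, 14], "Cancer"),
    ("X3", [-1, -1, 0, -1, 3, 0, 26], "Normal"),
    ("X4", [-2, 0, -1, -2, 6, 3, 25], "Cancer"),
    ("X5", [-9, -19, 0, 0, 76, 9, -21], "Normal"),
    ("X6", [0, 0, 0, -2, 2, 0, 21], "Cancer"),
]
TABLE1_GENES = ["G1", "G2", "G3", "G4", "G5", "G6", "G7"]


def make_set(values, labels, prefix="g"):
    values = np.asarray(values, dtype=float)
    return LabeledExpressionSet(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        list(labels),
    )


@pytest.fixture
def table1_tsv(tmp_path):
    path = tmp_path / "table1.tsv"
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(TABLE1_GENES) + "\tLabel\n")
        for sid, vals, lab in TABLE1_ROWS:
            fh.write(sid + "\t" + "\t".join(str(v) for v in vals) + f"\t{lab}\n")
    return path


@pytest.fixture
def table1_set(table1_tsv):
    from crclassify import read_expression_table

    return read_expression_table(table1_tsv)


@pytest.fixture(scope="session")
def separable_set():
    """Two well-separated classes: 5-sigma gap on 20 of 500 genes."""
    return generate_dataset(SyntheticSpec(
        n_classes=2, samples_per_class=20, n_features=500, n_informative=20,
        effect_size=5.0, noise_sigma=1.0, seed=101))


@pytest.fixture(scope="session")
def null_set():
    """Same shape as separable_set but zero effect: labels carry no signal."""
    return generate_dataset(SyntheticSpec(
        n_classes=2, samples_per_class=20, n_features=500, n_informative=20,
        effect_size=0.0, noise_sigma=1.0, seed=202))


@pytest.fixture(scope="session")
def lowrank_set():
    """Strongly coherent rank-10 data: many samples, few features."""
    return generate_dataset(SyntheticSpec(
        n_classes=2, samples_per_class=50, n_features=100, n_informative=20,
        effect_size=200.0, noise_sigma=0.05, redundancy_rank=10, seed=303))


@pytest.fixture
def default_config():
    return PipelineConfig()
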
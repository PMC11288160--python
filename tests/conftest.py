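import numpy as np
import pytest

from holdoutsampler import (
    FeatureMatrix,
    GeneratorConfig,
    HyperRanges,
    SamplerConfig,
    generate_dataset,
)


@pytest.fixture
def toy_table(tmp_path):
    """A 4-row feature table in the canonical TSV dialect."""
    from holdoutsampler.dataio import AMINO_ACIDS

    header = ["id", "protein", "position", "wt", "mut", "label"]
    header += [f"mutation.{aa}" for aa in AMINO_ACIDS] + ["structural.asa"]
    rows = []
    muts = [("A", "C", "deleterious"), ("C", "D", "neutral"),
            ("D", "E", "deleterious"), ("W", "Y", "neutral")]
    for i, (wt, mut, lab) in enumerate(muts):
        vec = [0.0] * 20
        vec[AMINO_ACIDS.index(wt)] = -1.0
        vec[AMINO_ACIDS.index(mut)] = 1.0
        rows.append([f"s{i}", f"P{i}", str(i + 1), wt, mut, lab]
                    + [str(v) for v in vec] + [str(0.1 * i)])
    path = tmp_path / "toy.tsv"
    path.write_text("\n".join("\t".join(r) for r in [header] + rows) + "\n")
    return path


@pytest.fixture
def small_matrix():
    """A small labeled matrix with one separable structural attribute."""
    rng = np.random.default_rng(7)
    n = 120
    labels = (np.arange(n) % 2).astype(int)
    X = np.column_stack([
        labels + 0.01 * rng.standard_normal(n),  # separable
        rng.standard_normal(n),                  # noise
    ])
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        X=X,
        attribute_names=["structural.asa", "stability.ddg"],
        attribute_groups={"structural.asa": "structural", "stability.ddg": "stability"},
        labels=labels,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One generated dataset at the default study conditions."""
    matrix, truth = generate_dataset(GeneratorConfig(seed=42))
    return matrix, truth


@pytest.fixture
def fast_config():
    """Small sampler configuration for cheap pipeline tests."""
    return SamplerConfig(
        n_holdouts=8,
        seed=1,
        ranges=HyperRanges(elm_hidden=(5, 30), rf_trees=(10, 10)),
    )
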
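import numpy as np
import pytest

import mlcfa


@pytest.fixture
def toy_dataset():
    """Two clusters {0, 2} and {4, 6} of one indicator: hand-computable."""
    return mlcfa.MultilevelDataset(
        np.array([[0.0], [2.0], [4.0], [6.0]]),
        np.array(["a", "a", "b", "b"]),
        np.array(["1", "2", "1", "2"]),
        ("x",),
    )


@pytest.fixture
def toy_decomposition(toy_dataset):
    return mlcfa.compute_decomposition(toy_dataset)


def make_random_dataset(rng, n_clusters=6, size_range=(1, 8), p=3):
    """Unbalanced clustered data with arbitrary covariance structure."""
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_clusters)
    if (sizes == 1).all():
        sizes[0] = 2
    rows, cl, cs = [], [], []
    for g, n in enumerate(sizes):
        centre = rng.normal(scale=2.0, size=p)
        for i in range(n):
            rows.append(centre + rng.normal(size=p))
            cl.append(f"g{g}")
            cs.append(str(i))
    return mlcfa.MultilevelDataset(
        np.array(rows), np.array(cl), np.array(cs),
        tuple(f"y{j}" for j in range(p)),
    )


@pytest.fixture
def random_dataset_factory():
    return make_random_dataset


def family_within_pattern(marker_value=1.0):
    """Two correlated within factors over six IQ subtests."""
    labels = ["wordst", "cards", "matrix", "figure", "animal", "occpat"]
    return mlcfa.pattern_from_dict(
        {"f1": labels[:3], "f2": labels[3:]}, labels, marker_value
    )


def family_between_pattern(marker_value=1.0):
    """One general between factor over all six subtests."""
    labels = ["wordst", "cards", "matrix", "figure", "animal", "occpat"]
    return mlcfa.pattern_from_dict({"B_f1": labels}, labels, marker_value)


@pytest.fixture
def family_patterns():
    return family_within_pattern(), family_between_pattern()


@pytest.fixture(scope="session")
def benchmark_fit_bundle():
    """One benchmark-design draw with the three standard fits (session cache)."""
    pop = mlcfa.benchmark_population(seed=20240901)
    ds = mlcfa.generate(pop)
    decomp = mlcfa.compute_decomposition(ds)
    w = mlcfa.benchmark_within_pattern(marker_value=0.8)
    b = mlcfa.benchmark_between_pattern(marker_value=0.8)
    fits = {
        "CFA": mlcfa.minimize(mlcfa.build_model("CFA", within_spec=w), decomp),
        "MAX_MCFA": mlcfa.minimize(
            mlcfa.build_model("MAX_MCFA", within_spec=w), decomp
        ),
        "MCFA": mlcfa.minimize(
            mlcfa.build_model("MCFA", within_spec=w, between_spec=b), decomp
        ),
    }
    return {"pop": pop, "dataset": ds, "decomp": decomp,
            "within": w, "between": b, "fits": fits}
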
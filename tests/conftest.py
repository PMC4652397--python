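import numpy as np
import pandas as pd
import pytest

from radonvuln import (
    ForestConfig,
    GeneratorConfig,
    VulnerabilityForest,
    build_training_set,
    covariate_columns,
    generate_study,
)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_parent_areas=120, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    """~300-unit province; cheap enough for most structural tests."""
    return generate_study(small_config)


@pytest.fixture(scope="session")
def province_study():
    """Desk-scale province at the generator defaults (~2,000 units)."""
    return generate_study(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def province_labels(province_study):
    labels, dist = build_training_set(
        province_study.units, province_study.measurements
    )
    return labels, dist


def fit_forest(units, labels, threshold, n_trees=100, seed=3, bootstrap="balanced"):
    merged = labels.merge(units, on="unit_id", how="left", validate="one_to_one")
    X = merged[covariate_columns(units)]
    y = merged[f"class_{threshold:g}"]
    cfg = ForestConfig(n_runs=1, n_trees_per_run=n_trees, seed=seed)
    return VulnerabilityForest(X, y, config=cfg, bootstrap=bootstrap).fit()


@pytest.fixture(scope="session")
def province_forest_200(province_study, province_labels):
    labels, _ = province_labels
    return fit_forest(province_study.units, labels, 200.0, n_trees=150)


def separable_dataset(n=200, flip=0.0, minority_fraction=0.5, seed=0):
    """Binary-labelled frame with one separating binary covariate plus noise.

    ``flip`` mislabels a fraction of points; ``minority_fraction`` sets the
    prevalence of the high class.
    """
    rng = np.random.default_rng(seed)
    y01 = (rng.random(n) < minority_fraction).astype(int)
    sep = np.where(y01 == 1, "a", "b").astype(object)
    do_flip = rng.random(n) < flip
    sep[do_flip] = np.where(sep[do_flip] == "a", "b", "a")
    X = pd.DataFrame(
        {
            "cov_cat_sep": sep,
            "cov_num_signal": y01 + rng.normal(0, 0.8, n),
            "cov_num_noise": rng.normal(0, 1, n),
        }
    )
    y = np.where(y01 == 1, "high", "low")
    return X, y
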
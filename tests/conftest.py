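import numpy as np
import pytest

from ifcl import Dataset, RawTable, SyntheticSpec, sample_anm, zscore_standardize


@pytest.fixture
def chain_data():
    """3-node chain X1 -> X2 -> X3, slope 0.9, uniform noise, m=1000."""
    spec = SyntheticSpec(
        n=3, m=1000, edges=((0, 1), (1, 2)), noise="uniform", noise_scale=0.5, seed=11
    )
    return sample_anm(spec)


@pytest.fixture
def small_data():
    """A standardized 4-variable dataset with mild dependence, m=300."""
    spec = SyntheticSpec(n=4, m=300, edges=((0, 1), (2, 3)), seed=5)
    return sample_anm(spec)[1]


@pytest.fixture
def eight_var_csv(tmp_path):
    """A 9-column CSV shaped like a diabetes file (8 risk factors + class)."""
    rng = np.random.default_rng(42)
    m = 200
    cols = [
        "pregnancies", "glucose", "blood_pressure", "skin_thickness",
        "insulin", "bmi", "pedigree", "age", "class",
    ]
    X = rng.normal(50, 10, size=(m, 8))
    X[:, 1] += 0.5 * X[:, 0]  # inject some correlation
    y = rng.integers(0, 2, size=m)
    lines = [",".join(cols)]
    for j in range(m):
        lines.append(",".join(f"{v:.4f}" for v in X[j]) + f",{y[j]}")
    path = tmp_path / "diabetes.csv"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_dataset(values, names=None) -> Dataset:
    values = np.asarray(values, dtype=float)
    names = names or tuple(f"X{i + 1}" for i in range(values.shape[1]))
    return zscore_standardize(RawTable(tuple(names), values))
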
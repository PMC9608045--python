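import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ddisignal.feature_builder import FeatureMatrix
from ddisignal.synthetic_data import make_worked_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def worked_fixture():
    """The hand-traceable 12-case dataset and its expected outcome."""
    return make_worked_fixture()


def random_feature_matrix(
    rng: np.random.Generator,
    n_cases: int,
    n_drugs: int,
    event_prob: float = 0.2,
    drug_prob: float = 0.3,
) -> FeatureMatrix:
    """Random design used by the split-optimality and tree property tests."""
    X = (rng.random((n_cases, n_drugs)) < drug_prob).astype(np.int8)
    names = sorted(f"drug_{chr(97 + j)}" for j in range(n_drugs))
    return FeatureMatrix(
        case_ids=[f"C{i}" for i in range(n_cases)],
        drug_columns=names,
        indicators=X,
        drug_count=1 + X.sum(axis=1).astype(np.int64),
        event=rng.random(n_cases) < event_prob,
    )


def brute_force_best_stat(matrix: FeatureMatrix, index: np.ndarray, min_node: int):
    """Independent G2 maximum over all admissible candidate splits.

    Enumerates every drug column and every drug-count midpoint threshold,
    scoring each admissible 2x2 table with scipy's log-likelihood-ratio
    chi-square (an implementation independent of the package's splitter).
    Returns the maximum statistic, or None when no candidate is admissible
    or the node is event-pure.
    """
    from scipy.stats import chi2_contingency

    y = matrix.event[index].astype(int)
    n = len(index)
    k = int(y.sum())
    if k == 0 or k == n:
        return None

    def score(n1, k1):
        n0, k0 = n - n1, k - k1
        if n1 < min_node or n0 < min_node:
            return None
        table = np.array([[k1, n1 - k1], [k0, n0 - k0]], dtype=float)
        stat, _, _, _ = chi2_contingency(
            table, correction=False, lambda_="log-likelihood"
        )
        return max(float(stat), 0.0)

    best = None
    for j in range(len(matrix.drug_columns)):
        x = matrix.indicators[index, j]
        s = score(int(x.sum()), int(y[x == 1].sum()))
        if s is not None and (best is None or s > best):
            best = s
    counts = matrix.drug_count[index]
    uniq = np.unique(counts)
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        t = (lo + hi) / 2.0
        right = counts >= t
        s = score(int(right.sum()), int(y[right].sum()))
        if s is not None and (best is None or s > best):
            best = s
    return best
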
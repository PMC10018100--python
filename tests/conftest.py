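import numpy as np
import pytest

from fcendo.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shared by read-only tests."""
    spec = CohortSpec(n_controls=8, n_patients=8, n_siblings=4,
                      n_regions=48, n_timepoints=120, mean_degree=6,
                      n_components=6, seed=1234)
    return generate_cohort(spec)


# ---------------------------------------------------------------------------
# independent oracles (deliberately different algorithms from the package)

def floyd_warshall(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs distances by the Floyd–Warshall recurrence."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k][None, :])
    return d


def ge_oracle(adjacency: np.ndarray) -> float:
    d = floyd_warshall(adjacency)
    n = d.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def apl_oracle(adjacency: np.ndarray) -> float:
    d = floyd_warshall(adjacency)
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals))


def cc_oracle(adjacency: np.ndarray) -> float:
    """Node-average clustering by explicit neighbour-pair enumeration."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for x in range(k) for y in range(x + 1, k)
                    if a[nbrs[x], nbrs[y]])
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals))
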
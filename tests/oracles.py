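"""Independent brute-force oracles used only by the test suite."""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


def minimized_rmsd(a: np.ndarray, b: np.ndarray, restarts: int = 8,
                   seed: int = 0) -> float:
    """Numeric minimization of RMSD over proper rotations (translation removed
    by centering), independent of the SVD route."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def objective(angles):
        r = Rotation.from_euler("xyz", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((a @ r.T - b) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(restarts):
        res = minimize(
            objective,
            rng.uniform(-np.pi, np.pi, 3),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
        )
        best = min(best, res.fun)
    return float(best)


def set_partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def coclustered_pairs(partition):
    pairs = set()
    for block in partition:
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                pairs.add(frozenset((block[i], block[j])))
    return pairs


def jaccard_oracle(p1, p2) -> float:
    s1, s2 = coclustered_pairs(p1), coclustered_pairs(p2)
    union = s1 | s2
    if not union:
        return 1.0
    return len(s1 & s2) / len(union)


def mocm_oracle(partition, labels, include_singletons=True) -> float:
    consistent = 0
    multi = 0
    total = sum(len(block) for block in partition)
    for block in partition:
        if len(block) < 2:
            continue
        multi += len(block)
        if len({labels[x] for x in block}) == 1:
            consistent += len(block)
    denom = total if include_singletons else multi
    return consistent / denom if denom else 0.0


def clustering_from_partition(partition):
    from abclust import Clustering

    assignment = {}
    representatives = {}
    for k, block in enumerate(partition):
        cid = f"c{k}"
        representatives[cid] = block[0]
        for member in block:
            assignment[member] = cid
    return Clustering(assignment=assignment, representatives=representatives)


def random_rigid_motion(rng):
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    rot = Rotation.from_quat(quat).as_matrix()
    trans = rng.uniform(-50, 50, size=3)
    return rot, trans
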
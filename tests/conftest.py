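import numpy as np
import pandas as pd
import pytest

from tapas_ts.expression import TimeCourseMatrix
from tapas_ts.goss import AnnotationSet, GoDag
from tapas_ts.synthdata import simulate_tapas_scenario


@pytest.fixture
def toy_matrix() -> TimeCourseMatrix:
    """Two genes, four stages; gene A has a proportional minor isoform."""
    values = pd.DataFrame(
        {
            "E00-02h": [10.0, 5.0, 0.0, 2.0],
            "E02-04h": [20.0, 10.0, 0.0, 2.0],
            "L1": [10.0, 5.0, 8.0, 2.0],
            "WPP": [0.0, 0.0, 8.0, 2.0],
        },
        index=pd.Index(["A.t1", "A.t2", "B.t1", "B.t2"], name="transcript_id"),
    )
    mapping = {"A.t1": "A", "A.t2": "A", "B.t1": "B", "B.t2": "B"}
    return TimeCourseMatrix(values=values, transcript_to_gene=mapping)


@pytest.fixture
def toy_dag() -> GoDag:
    """root -> {broad1, broad2}; broad1 -> deep1; broad2 -> deep2."""
    parents = {
        "GO:0000001": set(),
        "GO:0000002": {"GO:0000001"},
        "GO:0000003": {"GO:0000001"},
        "GO:0000004": {"GO:0000002"},
        "GO:0000005": {"GO:0000003"},
    }
    namespace = {t: "BP" for t in parents}
    return GoDag(parents=parents, namespace=namespace)


@pytest.fixture
def toy_annotations() -> AnnotationSet:
    """Ten genes: five under deep1, two under deep2, three at the root only."""
    direct = {f"g{i}": {"GO:0000004"} for i in range(5)}
    direct |= {f"g{i}": {"GO:0000005"} for i in range(5, 7)}
    direct |= {f"g{i}": {"GO:0000001"} for i in range(7, 10)}
    return AnnotationSet(direct=direct)


@pytest.fixture(scope="session")
def tapas_scenario():
    return simulate_tapas_scenario(seed=17)


def random_profile_pairs(n_pairs: int, length: int, seed: int):
    """Random non-negative, not-all-zero profile pairs for oracle checks."""
    rng = np.random.default_rng(seed)
    pairs = []
    while len(pairs) < n_pairs:
        p = rng.gamma(shape=1.0, scale=rng.uniform(0.1, 50), size=length)
        q = rng.gamma(shape=1.0, scale=rng.uniform(0.1, 50), size=length)
        if p.any() or q.any():
            pairs.append((p, q))
    return pairs


def gram_svd_oracle(p, q) -> float:
    """TS recomputed from the eigenvalues of the 2x2 Gram matrix X X^T.

    Independent of numpy's SVD path: singular values are the square roots of
    the Gram eigenvalues, obtained in closed form for the 2x2 case.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    a, b, c = p @ p, p @ q, q @ q
    tr, det = a + c, a * c - b * b
    disc = max(tr * tr / 4 - det, 0.0)
    lam1 = tr / 2 + np.sqrt(disc)
    lam2 = max(tr / 2 - np.sqrt(disc), 0.0)
    s1, s2 = np.sqrt(lam1), np.sqrt(lam2)
    return 2.0 * (1.0 - s1 / (s1 + s2))
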
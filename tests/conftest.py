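import numpy as np
import pytest

from combipharm import (
    Conformer,
    FeaturePoint,
    MoleculeRecord,
    PharmacophoreHypothesis,
    make_planted_library,
)


def feature_cloud(mol_id, label, feats):
    """A chemistry-free record holding one conformer of feature points."""
    rec = MoleculeRecord(mol_id=mol_id, structure=None, label=label, mol_weight=300.0)
    coords = np.asarray([f.xyz for f in feats])
    rec.conformers = [Conformer(conf_id=0, coords=coords)]
    rec.features = {0: list(feats)}
    return rec


def triangle_points(types, d01, d02, d12):
    """Three typed feature points realising the given pairwise distances."""
    x2 = (d01**2 + d02**2 - d12**2) / (2 * d01)
    y2 = np.sqrt(max(d02**2 - x2**2, 0.0))
    pos = [(0.0, 0.0, 0.0), (d01, 0.0, 0.0), (x2, y2, 0.0)]
    return [FeaturePoint(t, p) for t, p in zip(types, pos)]


@pytest.fixture
def hhr_hypothesis():
    return PharmacophoreHypothesis(
        hyp_id="HHR1",
        sites=("H", "H", "R"),
        distances=np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
        tol=0.5,
    )


@pytest.fixture
def hhr_cloud():
    return triangle_points(("H", "H", "R"), 3.0, 4.0, 5.0)


@pytest.fixture(scope="session")
def planted_library():
    records, manifest = make_planted_library(
        n_active=20, n_inactive=200, noise_sigma=0.2, decoy_features_per_mol=5, seed=11
    )
    return records, manifest


def random_hypothesis(rng, k):
    """A random realisable k-site hypothesis built from random 3D points."""
    types = [["A", "D", "H", "N", "P", "R"][rng.integers(6)] for _ in range(k)]
    while True:
        pts = rng.uniform(-5, 5, size=(k, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        if D[~np.eye(k, dtype=bool)].min() > 0.5:
            break
    return PharmacophoreHypothesis(
        hyp_id="RND", sites=tuple(sorted(types)), distances=D, tol=float(rng.uniform(0.5, 1.5))
    )


def random_cloud(rng, n_points, box=8.0):
    types = ["A", "D", "H", "N", "P", "R"]
    return [
        FeaturePoint(types[rng.integers(6)], tuple(rng.uniform(-box / 2, box / 2, 3)))
        for _ in range(n_points)
    ]
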
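"""Deterministic synthetic libraries with planted pharmacophores.

The generator emulates a labeled inhibitor screen at the level the matching
and selection machinery sees it: each molecule is a cloud of typed feature
points.  Actives carry one planted hypothesis geometry (inter-site distances
fixed, positions jittered by isotropic Gaussian noise) buried among decoy
features; inactives carry decoys only and are rejection-sampled so that none
matches any planted hypothesis at the library tolerance.  A manifest records
the ground truth so that every downstream module can be tested against it
without external data.

A small real-SMILES library covering all six feature types ships as package
data for end-to-end chemistry tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_core import FEATURE_TYPES, Conformer, FeaturePoint, MoleculeRecord
from .hypothesis_engine import PharmacophoreHypothesis
from .matcher import match_conformer


@dataclass
class PlantManifest:
    """Ground truth for a planted library: which active carries which plant."""

    planted_hyps: list[PharmacophoreHypothesis]
    molecules: list[dict]  # mol_id, label, planted (hyp_id or None), mol_weight
    noise_sigma: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "planted_hyps": [h.to_dict() for h in self.planted_hyps],
            "molecules": self.molecules,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_hyps=[PharmacophoreHypothesis.from_dict(h) for h in d["planted_hyps"]],
            molecules=d["molecules"],
            noise_sigma=float(d["noise_sigma"]),
            seed=int(d["seed"]),
        )

    def planted_column(self, hyp_id: str) -> dict[str, bool]:
        """mol_id -> was this hypothesis planted in that molecule."""
        return {m["mol_id"]: m.get("planted") == hyp_id for m in self.molecules}


def embed_distance_matrix(D: np.ndarray) -> np.ndarray:
    """3D coordinates realising a Euclidean distance matrix (classical MDS)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order[:3]], V[:, order[:3]]
    if np.any(w < -1e-6 * max(1.0, abs(w[0]))):
        raise ValueError("distance matrix is not realisable in 3D")
    X = V * np.sqrt(np.clip(w, 0.0, None))
    out = np.zeros((n, 3))
    out[:, : X.shape[1]] = X
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def _feature_cloud_record(mol_id: str, label: str, feats: list[FeaturePoint], mol_weight: float) -> MoleculeRecord:
    coords = np.asarray([f.xyz for f in feats])
    rec = MoleculeRecord(mol_id=mol_id, structure=None, label=label, mol_weight=mol_weight)
    rec.conformers = [Conformer(conf_id=0, coords=coords)]
    rec.features = {0: feats}
    return rec


def make_planted_library(
    n_active: int,
    n_inactive: int,
    planted_hyps: Optional[Sequence[PharmacophoreHypothesis]] = None,
    noise_sigma: float = 0.2,
    decoy_features_per_mol: int = 5,
    seed: int = 0,
    tol: float = 1.0,
    box_size: float = 12.0,
    max_retries: int = 500,
) -> tuple[list[MoleculeRecord], PlantManifest]:
    """Build a feature-cloud library with planted common pharmacophores.

    Each active carries one planted hypothesis (assigned round-robin): the
    hypothesis distance matrix is embedded in 3D, randomly rotated and
    translated, and each site position jittered with isotropic Gaussian noise
    of scale ``noise_sigma`` (A).  ``decoy_features_per_mol`` uniformly placed
    random-type features are added to every molecule.  Inactives contain only
    decoys and are resampled until they match no planted hypothesis at
    ``tol``; exceeding ``max_retries`` raises with advice to reduce decoys or
    widen the tolerance margin.  Identical seeds give identical libraries.
    Synthetic molecular weights are drawn once per molecule for report tests.
    """
    if n_active < 1:
        raise ValueError("n_active must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if planted_hyps is None:
        planted_hyps = default_planted_hypotheses(tol=tol)
    planted_hyps = list(planted_hyps)

    base_coords = {h.hyp_id: embed_distance_matrix(h.distance_matrix) for h in planted_hyps}
    records: list[MoleculeRecord] = []
    manifest_rows: list[dict] = []

    def decoys(n: int) -> list[FeaturePoint]:
        out = []
        for _ in range(n):
            ftype = FEATURE_TYPES[rng.integers(len(FEATURE_TYPES))]
            pos = rng.uniform(-box_size / 2, box_size / 2, size=3)
            out.append(FeaturePoint(ftype, tuple(pos)))
        return out

    for i in range(n_active):
        hyp = planted_hyps[i % len(planted_hyps)]
        X = base_coords[hyp.hyp_id].copy()
        X = X @ _random_rotation(rng).T + rng.uniform(-box_size / 4, box_size / 4, size=3)
        X = X + rng.normal(scale=noise_sigma, size=X.shape)
        feats = [FeaturePoint(s, tuple(X[j])) for j, s in enumerate(hyp.sites)]
        feats += decoys(decoy_features_per_mol)
        mw = float(rng.uniform(200.0, 700.0))
        mol_id = f"act{i + 1:03d}"
        records.append(_feature_cloud_record(mol_id, "active", feats, mw))
        manifest_rows.append({"mol_id": mol_id, "label": "active", "planted": hyp.hyp_id, "mol_weight": mw})

    for i in range(n_inactive):
        mol_id = f"inact{i + 1:03d}"
        for attempt in range(max_retries):
            feats = decoys(max(decoy_features_per_mol, 1))
            if not any(match_conformer(feats, h).matched for h in planted_hyps):
                break
        else:
            raise RuntimeError(
                "rejection sampling failed for an inactive; use fewer decoy "
                "features or a larger margin between geometry and tolerance"
            )
        mw = float(rng.uniform(200.0, 700.0))
        records.append(_feature_cloud_record(mol_id, "inactive", feats, mw))
        manifest_rows.append({"mol_id": mol_id, "label": "inactive", "planted": None, "mol_weight": mw})

    manifest = PlantManifest(
        planted_hyps=planted_hyps, molecules=manifest_rows, noise_sigma=noise_sigma, seed=seed
    )
    return records, manifest


def default_planted_hypotheses(tol: float = 1.0) -> list[PharmacophoreHypothesis]:
    """Two well-separated 3-site plants: an HHR triangle and a DRR triangle."""
    return [
        PharmacophoreHypothesis(
            hyp_id="HHR1",
            sites=("H", "H", "R"),
            distances=np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
            tol=tol,
            provenance="planted",
        ),
        PharmacophoreHypothesis(
            hyp_id="DRR1",
            sites=("D", "R", "R"),
            distances=np.array([[0.0, 6.0, 7.5], [6.0, 0.0, 5.0], [7.5, 5.0, 0.0]]),
            tol=tol,
            provenance="planted",
        ),
    ]


# ---------------------------------------------------------------------------
# Feature-cloud CSV round trip
# ---------------------------------------------------------------------------

def write_feature_cloud_csv(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for fp in rec.features.get(0, []):
            rows.append((rec.mol_id, fp.ftype, *fp.position, rec.label, rec.mol_weight))
    pd.DataFrame(rows, columns=["mol_id", "ftype", "x", "y", "z", "label", "mol_weight"]).to_csv(
        path, index=False
    )


def read_feature_cloud_csv(path: str | Path) -> list[MoleculeRecord]:
    df = pd.read_csv(path, dtype={"mol_id": str})
    records = []
    for mol_id, grp in df.groupby("mol_id", sort=False):
        feats = [
            FeaturePoint(row.ftype, (row.x, row.y, row.z)) for row in grp.itertuples()
        ]
        records.append(
            _feature_cloud_record(
                str(mol_id), grp["label"].iloc[0], feats, float(grp["mol_weight"].iloc[0])
            )
        )
    return records


# ---------------------------------------------------------------------------
# Real-SMILES fixture
# ---------------------------------------------------------------------------

def make_smiles_fixture() -> tuple[Path, Path]:
    """Paths to the bundled ~20-molecule labeled SMILES library.

    The set spans all six feature types (amines for P, acids for N, aromatics
    for R, alkyl chains for H, plus donors/acceptors) with the kind of
    cationic-amphiphilic scaffolds typical of organic-cation transporter
    inhibitors; labels are illustrative, not literature activities.
    """
    data = resources.files("combipharm.data")
    return Path(str(data.joinpath("fixture_library.smi"))), Path(str(data.joinpath("fixture_labels.csv")))
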
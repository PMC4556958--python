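"""Structure/label I/O, conformer ensembles, and pharmacophore feature perception.

The feature vocabulary is the six-letter set used throughout ligand-based
pharmacophore modeling: hydrogen-bond acceptor (A), donor (D), hydrophobe (H),
negative charge (N), positive charge (P) and aromatic ring (R).  Perception is
driven by an explicit, versioned SMARTS pattern table shipped as package data
(``data/feature_definitions.yaml``) so that results are reproducible and the
table is auditable/replaceable.  Ionisation follows a rule-based pH 7.4
convention: carboxylic/sulfonic/phosphonic acids are treated as deprotonated,
aliphatic amines, amidines and guanidines as protonated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.warning")

FEATURE_TYPES = ("A", "D", "H", "N", "P", "R")
VALID_LABELS = ("active", "inactive", "unknown")


class LibraryValidationError(ValueError):
    """Raised for invalid library input (e.g. duplicate molecule ids)."""


@dataclass
class Conformer:
    """One 3D geometry of a molecule; ``coords`` is (n_atoms, 3) in Angstrom."""

    conf_id: int
    coords: np.ndarray
    energy: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("conformer coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("conformer coords must be finite")


@dataclass(frozen=True)
class FeaturePoint:
    """A typed pharmacophore site at the centroid of its source atoms."""

    ftype: str
    position: tuple[float, float, float]
    atom_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        object.__setattr__(self, "position", tuple(float(x) for x in self.position))

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class MoleculeRecord:
    """One ligand: structure, activity label, conformer ensemble, features.

    ``structure`` may be an RDKit Mol, a SMILES string, or ``None`` for
    chemistry-free feature-cloud records produced by the synthetic generator.
    ``features`` caches perceived feature points per conformer id.
    """

    mol_id: str
    structure: object = None
    label: str = "unknown"
    mol_weight: float = 0.0
    conformers: list[Conformer] = field(default_factory=list)
    features: dict[int, list[FeaturePoint]] = field(default_factory=dict)
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        if isinstance(self.structure, str):
            mol = Chem.MolFromSmiles(self.structure)
            if mol is None:
                raise ValueError(f"unparsable SMILES for {self.mol_id}: {self.structure}")
            self.structure = mol
        if self.structure is not None and not self.mol_weight:
            self.mol_weight = float(Descriptors.MolWt(self.structure))

    @property
    def mol(self) -> Optional[Chem.Mol]:
        return self.structure

    def feature_sets(self) -> list[tuple[int, list[FeaturePoint]]]:
        """Perceived features per conformer, ordered by conformer id."""
        return sorted(self.features.items())


# ---------------------------------------------------------------------------
# Feature definitions
# ---------------------------------------------------------------------------

def load_feature_definitions(path: Optional[str | Path] = None) -> dict:
    """Load the SMARTS feature-pattern table (package default if no path).

    The table maps each feature letter to a list of SMARTS patterns; matched
    atoms are averaged into a centroid site.  Raises ``ValueError`` for
    feature letters outside the A/D/H/N/P/R vocabulary.
    """
    if path is None:
        text = resources.files("combipharm.data").joinpath("feature_definitions.yaml").read_text()
    else:
        text = Path(path).read_text()
    defs = yaml.safe_load(text)
    unknown = set(defs["patterns"]) - set(FEATURE_TYPES)
    if unknown:
        raise ValueError(f"unknown feature type(s) in definitions: {sorted(unknown)}")
    compiled = {}
    for ftype, patterns in defs["patterns"].items():
        compiled[ftype] = []
        for smarts in patterns:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"invalid SMARTS for {ftype}: {smarts}")
            compiled[ftype].append((smarts, patt))
    defs["_compiled"] = compiled
    return defs


_PH74_DEPROTONATE = [
    "[CX3](=[OX1])[OX2H1]",            # carboxylic acid -> carboxylate
    "[SX4](=[OX1])(=[OX1])[OX2H1]",    # sulfonic acid
    "[PX4](=[OX1])[OX2H1]",            # phosphonic/phosphate OH (first only)
]
_PH74_PROTONATE = [
    # aliphatic amine: N bonded only to C/H, not aromatic-attached, not amide
    "[NX3;+0;!$([NX3][!#6;!#1]);!$([NX3]a);!$([NX3][CX3]=[OX1,SX1,NX2])]",
]


def standardize_ph74(mol: Chem.Mol) -> Chem.Mol:
    """Apply the rule-based pH 7.4 ionisation convention.

    Acids are deprotonated, basic aliphatic amines protonated.  This is a
    fixed functional-group rule table, not a pKa calculator.
    """
    mol = Chem.Mol(mol)
    for smarts in _PH74_DEPROTONATE:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            atom = mol.GetAtomWithIdx(match[-1])
            if atom.GetFormalCharge() == 0 and atom.GetTotalNumHs() > 0:
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
                atom.SetNoImplicit(True)
    for smarts in _PH74_PROTONATE:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            atom = mol.GetAtomWithIdx(match[0])
            if atom.GetFormalCharge() == 0:
                atom.SetFormalCharge(1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
    Chem.SanitizeMol(mol)
    return mol


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_labels(label_path: str | Path) -> dict[str, str]:
    df = pd.read_csv(label_path, dtype=str)
    if not {"mol_id", "label"} <= set(df.columns):
        raise LibraryValidationError("label file must have columns mol_id,label")
    labels = {}
    for _, row in df.iterrows():
        mid, lab = str(row["mol_id"]), str(row["label"]).strip().lower()
        if lab not in VALID_LABELS:
            raise LibraryValidationError(f"invalid label {lab!r} for {mid}")
        labels[mid] = lab
    return labels


def _iter_structures(structure_path: Path):
    """Yield (mol_id, mol_or_None, raw) from a .smi or .sdf file."""
    suffix = structure_path.suffix.lower()
    if suffix in (".smi", ".smiles", ".txt"):
        with open(structure_path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                mol_id = parts[1].strip() if len(parts) > 1 else f"mol{i + 1}"
                yield mol_id, Chem.MolFromSmiles(smiles), smiles
    elif suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(structure_path), removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                yield f"sdf_record_{i + 1}", None, ""
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i + 1}"
            yield mol_id, mol, Chem.MolToSmiles(mol)
    else:
        raise LibraryValidationError(f"unsupported structure format: {suffix}")


def read_labeled_library(structure_path: str | Path, label_path: Optional[str | Path] = None) -> list[MoleculeRecord]:
    """Read a labeled compound library (SMILES or SDF structures + CSV labels).

    Records that fail to parse are reported via the module logger and skipped;
    structures without a label entry get ``label='unknown'``.  Duplicate
    molecule ids raise :class:`LibraryValidationError`.
    """
    structure_path = Path(structure_path)
    if not structure_path.exists():
        raise FileNotFoundError(structure_path)
    labels = _read_labels(label_path) if label_path is not None else {}

    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    n_failed = 0
    for mol_id, mol, raw in _iter_structures(structure_path):
        if mol is None:
            n_failed += 1
            logger.warning("failed to parse structure %s (%r)", mol_id, raw)
            continue
        if mol_id in seen:
            raise LibraryValidationError(f"duplicate mol_id: {mol_id}")
        seen.add(mol_id)
        # pre-existing SDF conformers are carried over
        confs = [
            Conformer(conf_id=c.GetId(), coords=np.asarray(c.GetPositions(), dtype=float))
            for c in mol.GetConformers()
            if c.Is3D()
        ]
        records.append(
            MoleculeRecord(
                mol_id=mol_id,
                structure=mol,
                label=labels.get(mol_id, "unknown"),
                conformers=confs,
            )
        )
    if n_failed:
        logger.warning("%d structure(s) failed to parse and were skipped", n_failed)
    return records


def write_library_sdf(records: Sequence[MoleculeRecord], sdf_path: str | Path, label_path: Optional[str | Path] = None) -> None:
    """Write structures (first conformer if present) to SDF and labels to CSV."""
    writer = Chem.SDWriter(str(sdf_path))
    try:
        for rec in records:
            if rec.mol is None:
                continue
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.mol_id)
            writer.write(mol)
    finally:
        writer.close()
    if label_path is not None:
        pd.DataFrame(
            {"mol_id": [r.mol_id for r in records], "label": [r.label for r in records]}
        ).to_csv(label_path, index=False)


def write_feature_table(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write perceived features as CSV (mol_id, conf_id, ftype, x, y, z)."""
    rows = []
    for rec in records:
        for conf_id, feats in rec.feature_sets():
            for fp in feats:
                rows.append((rec.mol_id, conf_id, fp.ftype, *fp.position))
    pd.DataFrame(rows, columns=["mol_id", "conf_id", "ftype", "x", "y", "z"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Conformer generation
# ---------------------------------------------------------------------------

def generate_conformers(
    record: MoleculeRecord,
    max_confs: int = 1000,
    seed: int = 0,
    energy_window: float = 10.0,
    prune_rms: float = 0.5,
    optimize: bool = True,
) -> MoleculeRecord:
    """Generate a low-energy conformer ensemble for ``record`` in place.

    Standardises ionisation at pH 7.4, embeds up to ``max_confs`` conformers
    with ETKDG (fixed ``seed`` gives bit-stable output), optionally MMFF94-
    minimises them, prunes by heavy-atom RMSD and keeps conformers within
    ``energy_window`` (arbitrary force-field units) of the minimum.  Embedding
    failure flags the record and leaves the ensemble empty.
    """
    if max_confs < 1:
        raise ValueError("max_confs must be >= 1")
    if record.mol is None:
        raise ValueError(f"record {record.mol_id} has no structure")
    try:
        mol = standardize_ph74(record.mol)
        record.structure = mol
        record.mol_weight = float(Descriptors.MolWt(mol))
        molh = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed)
        params.numThreads = 1
        params.pruneRmsThresh = float(prune_rms)
        params.useRandomCoords = False
        conf_ids = list(AllChem.EmbedMultipleConfs(molh, numConfs=int(max_confs), params=params))
        if not conf_ids:
            raise RuntimeError("embedding produced no conformers")
        energies: dict[int, Optional[float]] = {cid: None for cid in conf_ids}
        if optimize:
            results = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500, numThreads=1)
            for cid, (converged, energy) in zip(conf_ids, results):
                energies[cid] = float(energy) if converged >= 0 else None
        molh = Chem.RemoveHs(molh)
        known = [e for e in energies.values() if e is not None]
        e_min = min(known) if known else None
        conformers = []
        for new_id, cid in enumerate(conf_ids):
            e = energies[cid]
            if e_min is not None and e is not None and e - e_min > energy_window:
                continue
            coords = np.asarray(molh.GetConformer(cid).GetPositions(), dtype=float)
            conformers.append(Conformer(conf_id=new_id, coords=coords, energy=e))
        record.conformers = conformers
        record.flagged = False
    except Exception as exc:  # embedding failures are data, not crashes
        logger.warning("conformer generation failed for %s: %s", record.mol_id, exc)
        record.conformers = []
        record.flagged = True
    return record


# ---------------------------------------------------------------------------
# Feature perception
# ---------------------------------------------------------------------------

def perceive_features(structure: Chem.Mol, conformer: Conformer, defs: Optional[dict] = None) -> list[FeaturePoint]:
    """Map the SMARTS pattern table onto one conformer's coordinates.

    Returns typed feature points positioned at the arithmetic centroid of the
    matched atoms, deterministically sorted by (ftype, atom_indices).  An
    aromatic ring yields R only (H patterns exclude aromatic carbons) and a
    protonated amine yields P only (amines are absent from the D table) — the
    no-double-counting overlap policy.
    """
    if structure is None:
        return []
    if defs is None:
        defs = load_feature_definitions()
    coords = conformer.coords
    if coords.shape[0] != structure.GetNumAtoms():
        raise ValueError("conformer atom count does not match structure")
    if structure.GetNumAtoms() == 0:
        return []

    h_cluster = bool(defs.get("h_cluster", True))
    points: list[FeaturePoint] = []
    seen: set[tuple[str, frozenset[int]]] = set()
    h_atoms: set[int] = set()

    for ftype, compiled in defs["_compiled"].items():
        for _smarts, patt in compiled:
            for match in structure.GetSubstructMatches(patt, uniquify=True):
                if ftype == "H" and h_cluster:
                    h_atoms.update(match)
                    continue
                key = (ftype, frozenset(match))
                if key in seen:
                    continue
                seen.add(key)
                centroid = coords[list(match)].mean(axis=0)
                points.append(FeaturePoint(ftype, tuple(centroid), tuple(sorted(match))))

    if h_atoms:
        # merge bond-connected hydrophobic atoms into one site per cluster
        for cluster in _connected_components(structure, h_atoms):
            centroid = coords[sorted(cluster)].mean(axis=0)
            points.append(FeaturePoint("H", tuple(centroid), tuple(sorted(cluster))))

    points.sort(key=lambda fp: (fp.ftype, fp.atom_indices))
    return points


def _connected_components(mol: Chem.Mol, atoms: set[int]) -> list[set[int]]:
    remaining = set(atoms)
    components = []
    while remaining:
        stack = [min(remaining)]
        comp: set[int] = set()
        while stack:
            a = stack.pop()
            if a in comp:
                continue
            comp.add(a)
            remaining.discard(a)
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                if nb.GetIdx() in remaining:
                    stack.append(nb.GetIdx())
        components.append(comp)
    return components


def perceive_library(records: Iterable[MoleculeRecord], defs: Optional[dict] = None) -> list[MoleculeRecord]:
    """Perceive features on every conformer of every record (in place)."""
    if defs is None:
        defs = load_feature_definitions()
    for rec in records:
        if rec.mol is None:
            continue
        for conf in rec.conformers:
            rec.features[conf.conf_id] = perceive_features(rec.mol, conf, defs)
    return list(records)
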
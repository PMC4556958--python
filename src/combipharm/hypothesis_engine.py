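"""Common-pharmacophore hypothesis generation, scoring, and filtering.

From the actives' perceived feature clouds, every k-subset (k in {3, 4}) of
features on every conformer is reduced to a canonical (type multiset,
inter-site distance vector) signature.  Signatures sharing a type multiset
are pooled by distance binning under the Chebyshev metric: a candidate
hypothesis center is supported by every active owning a tuple whose
inter-site distances all agree with the center's to within ``bin_width``.
Centers reaching the ``min_actives`` support quota are emitted greedily by
support, retiring tuples within ``bin_width`` of an emitted center so that
duplicate geometries merge onto one representative.

Hypotheses are ranked by a survival score (fraction of actives matched), a
survival-inactive score (survival penalised by the inactive match fraction)
and a selectivity score (-log10 empirical rarity with an add-one pseudocount).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .chem_core import FEATURE_TYPES, FeaturePoint, MoleculeRecord

logger = logging.getLogger(__name__)


@dataclass
class PharmacophoreHypothesis:
    """A k-site pharmacophore: typed sites plus an inter-site distance matrix.

    ``sites`` is the ordered feature-letter list (length 3 or 4), ``distances``
    the symmetric k x k matrix in Angstrom, ``tol`` the per-pair matching
    tolerance.  Geometry is fully determined by the distances up to chirality
    (which distance-based matching ignores).
    """

    hyp_id: str
    sites: tuple[str, ...]
    distances: np.ndarray
    tol: float = 1.0
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        self.sites = tuple(self.sites)
        if not (3 <= len(self.sites) <= 4):
            raise ValueError("hypothesis must have 3 or 4 sites")
        for s in self.sites:
            if s not in FEATURE_TYPES:
                raise ValueError(f"unknown site type {s!r}")
        D = np.asarray(self.distances, dtype=float)
        if D.shape != (len(self.sites),) * 2:
            raise ValueError("distance matrix shape must be k x k")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        off = D[~np.eye(len(self.sites), dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("off-diagonal distances must be positive")
        k = len(self.sites)
        for i, j, l in permutations(range(k), 3):
            if D[i, j] > D[i, l] + D[l, j] + 1e-9:
                raise ValueError("distance matrix violates the triangle inequality")
        self.distances = D
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    @property
    def k(self) -> int:
        return len(self.sites)

    @property
    def distance_matrix(self) -> np.ndarray:
        return self.distances

    def to_dict(self) -> dict:
        return {
            "hyp_id": self.hyp_id,
            "sites": list(self.sites),
            "distances": self.distances.tolist(),
            "tol": self.tol,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreHypothesis":
        required = {"hyp_id", "sites", "distances", "tol"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"hypothesis JSON missing fields: {sorted(missing)}")
        return cls(
            hyp_id=str(d["hyp_id"]),
            sites=tuple(d["sites"]),
            distances=np.asarray(d["distances"], dtype=float),
            tol=float(d["tol"]),
            provenance=d.get("provenance"),
        )


@dataclass
class HypothesisScore:
    survival: float
    survival_inactive: float
    selectivity: float
    n_active_matched: int
    n_inactive_matched: int


@dataclass
class GenerationParams:
    """Knobs for common-pharmacophore generation.

    ``bin_width`` (A) is the distance agreement required to pool feature
    tuples into one hypothesis; ``min_actives`` the support quota (default:
    half the actives, rounded up); ``tol`` the matching tolerance stamped on
    emitted hypotheses; ``max_features_per_conf`` caps the combinatorics on
    feature-rich conformers (largest-first truncation is avoided — the first
    N in the deterministic perception order are kept).
    """

    bin_width: float = 1.0
    min_actives: Optional[int] = None
    tol: float = 1.0
    max_features_per_conf: int = 16


def hypotheses_to_json(hyps: Sequence[PharmacophoreHypothesis], path: str | Path) -> None:
    Path(path).write_text(json.dumps([h.to_dict() for h in hyps], indent=2))


def hypotheses_from_json(path: str | Path) -> list[PharmacophoreHypothesis]:
    data = json.loads(Path(path).read_text())
    if not isinstance(data, list):
        raise ValueError("hypothesis JSON must be a list")
    return [PharmacophoreHypothesis.from_dict(d) for d in data]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _canonical_signature(feats: Sequence[FeaturePoint]) -> tuple[tuple[str, ...], tuple[float, ...]]:
    """Canonical (sorted types, distance vector) signature of a feature tuple.

    Sites are ordered by feature letter; among orderings consistent with the
    sorted letters the one with the lexicographically smallest upper-triangle
    distance vector is chosen, making the signature permutation-invariant.
    """
    k = len(feats)
    pos = np.asarray([f.xyz for f in feats])
    D = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    letters = tuple(sorted(f.ftype for f in feats))
    best: Optional[tuple[float, ...]] = None
    for perm in permutations(range(k)):
        if tuple(feats[i].ftype for i in perm) != letters:
            continue
        vec = tuple(
            round(float(D[perm[i], perm[j]]), 6) for i in range(k) for j in range(i + 1, k)
        )
        if best is None or vec < best:
            best = vec
    assert best is not None
    return letters, best


def _signature_to_matrix(letters: tuple[str, ...], vec: tuple[float, ...]) -> np.ndarray:
    k = len(letters)
    D = np.zeros((k, k))
    it = iter(vec)
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = next(it)
    return D


def enumerate_candidate_hypotheses(
    actives: Sequence[MoleculeRecord],
    k_values: set[int] = frozenset({3, 4}),
    params: Optional[GenerationParams] = None,
) -> list[PharmacophoreHypothesis]:
    """Find common k-site pharmacophores among the actives' feature clouds.

    Deterministic and invariant to the order of ``actives``; duplicate
    geometries (same type multiset, all inter-site distances within
    ``bin_width``) are merged to the cluster medoid.
    """
    if not set(k_values) <= {3, 4}:
        raise ValueError(f"k_values must be a subset of {{3, 4}}, got {sorted(k_values)}")
    params = params or GenerationParams()
    min_actives = params.min_actives
    if min_actives is None:
        min_actives = math.ceil(0.5 * len(actives))

    # tuples: (letters, vec, mol_id, conf_id)
    tuples: list[tuple[tuple[str, ...], tuple[float, ...], str, int]] = []
    for rec in actives:
        if not rec.features or all(not f for f in rec.features.values()):
            warnings.warn(f"active {rec.mol_id} has no perceived features; excluded")
            continue
        for conf_id, feats in rec.feature_sets():
            feats = feats[: params.max_features_per_conf]
            for k in sorted(k_values):
                for combo in combinations(feats, k):
                    letters, vec = _canonical_signature(combo)
                    if min(vec) <= 0:  # coincident features give a degenerate tuple
                        continue
                    tuples.append((letters, vec, rec.mol_id, conf_id))

    # group by type multiset, cluster distance vectors within bin_width
    by_letters: dict[tuple[str, ...], list[tuple[tuple[float, ...], str, int]]] = {}
    for letters, vec, mol_id, conf_id in tuples:
        by_letters.setdefault(letters, []).append((vec, mol_id, conf_id))

    # Mode seeking per type multiset: every observed tuple is a candidate
    # hypothesis center, supported by the distinct actives that own a tuple
    # whose distance vector lies within bin_width (Chebyshev) of it.  Centers
    # are emitted greedily by support; tuples within bin_width of an emitted
    # center are retired, which merges duplicate geometries onto the most
    # central (medoid-like) representative.  Deterministic and insensitive to
    # decoy tuples scattered around a planted geometry.
    raw_hyps: list[tuple[tuple[str, ...], tuple[float, ...], int, str]] = []
    for letters, entries in sorted(by_letters.items()):
        entries = sorted(entries)  # permutation invariance
        vecs = np.asarray([e[0] for e in entries])
        mol_ids = [e[1] for e in entries]
        uniq_mols = sorted(set(mol_ids))
        mol_index = np.asarray([uniq_mols.index(m) for m in mol_ids])
        within = np.abs(vecs[:, None, :] - vecs[None, :, :]).max(-1) <= params.bin_width
        alive = np.ones(len(entries), dtype=bool)
        while True:
            support = np.zeros(len(entries), dtype=int)
            cost = np.zeros(len(entries))
            for i in np.where(alive)[0]:
                nb = within[i] & alive
                support[i] = len(set(mol_index[nb]))
                cost[i] = np.abs(vecs[nb] - vecs[i]).max(-1).sum()
            best_i = None
            for i in np.where(alive & (support >= min_actives))[0]:
                key = (-support[i], cost[i], tuple(vecs[i]))
                if best_i is None or key < best_key:
                    best_i, best_key = i, key
            if best_i is None:
                break
            vec_c, mol_c, conf_c = entries[best_i]
            raw_hyps.append((letters, vec_c, support[best_i], f"{mol_c}/conf{conf_c}"))
            alive &= ~within[best_i]

    # canonical naming: sorted letters + 1-based index within the letter group
    raw_hyps.sort(key=lambda h: (h[0], h[1]))
    counter: dict[tuple[str, ...], int] = {}
    out: list[PharmacophoreHypothesis] = []
    for letters, vec, _support, prov in raw_hyps:
        counter[letters] = counter.get(letters, 0) + 1
        hyp_id = "".join(letters) + str(counter[letters])
        try:
            out.append(
                PharmacophoreHypothesis(
                    hyp_id=hyp_id,
                    sites=letters,
                    distances=_signature_to_matrix(letters, vec),
                    tol=params.tol,
                    provenance=prov,
                )
            )
        except ValueError:
            # medoid geometry can violate validation only for degenerate inputs
            logger.warning("skipping degenerate hypothesis geometry %s", hyp_id)
    return out


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

MatchFn = Callable[[MoleculeRecord, PharmacophoreHypothesis], object]


def _match_fraction(hyp, records, match_fn) -> tuple[float, int]:
    n = sum(1 for rec in records if match_fn(rec, hyp).matched)
    return n / len(records), n


def survival_score(hyp: PharmacophoreHypothesis, actives: Sequence[MoleculeRecord], match_fn: MatchFn) -> float:
    """Fraction of actives whose best conformer matches the hypothesis."""
    if not actives:
        raise ValueError("actives must be non-empty")
    frac, _ = _match_fraction(hyp, actives, match_fn)
    return frac


def survival_inactive_score(
    hyp: PharmacophoreHypothesis,
    actives: Sequence[MoleculeRecord],
    inactives: Sequence[MoleculeRecord],
    penalty_lambda: float = 1.0,
    match_fn: MatchFn = None,
) -> float:
    """Survival penalised by the inactive match fraction: S_a - lambda * S_i."""
    if penalty_lambda < 0:
        raise ValueError("penalty_lambda must be >= 0")
    s = survival_score(hyp, actives, match_fn)
    if not inactives:
        warnings.warn("no inactives supplied; survival-inactive equals survival")
        return s
    f_inact, _ = _match_fraction(hyp, inactives, match_fn)
    return s - penalty_lambda * f_inact


def selectivity_score(hyp: PharmacophoreHypothesis, reference_set: Sequence[MoleculeRecord], match_fn: MatchFn) -> float:
    """Empirical rarity: -log10((n_matched + 1) / (N + 1)); higher = rarer."""
    if not reference_set:
        raise ValueError("reference_set must be non-empty")
    _, n = _match_fraction(hyp, reference_set, match_fn)
    return -math.log10((n + 1) / (len(reference_set) + 1))


def score_hypothesis(
    hyp: PharmacophoreHypothesis,
    actives: Sequence[MoleculeRecord],
    inactives: Sequence[MoleculeRecord],
    match_fn: MatchFn,
    penalty_lambda: float = 1.0,
    reference_set: Optional[Sequence[MoleculeRecord]] = None,
) -> HypothesisScore:
    """All three scores plus match counts; reference defaults to actives+inactives."""
    f_act, n_act = _match_fraction(hyp, actives, match_fn)
    if inactives:
        f_inact, n_inact = _match_fraction(hyp, inactives, match_fn)
    else:
        f_inact, n_inact = 0.0, 0
    ref = list(reference_set) if reference_set is not None else list(actives) + list(inactives)
    _, n_ref = _match_fraction(hyp, ref, match_fn) if ref else (0.0, 0)
    sel = -math.log10((n_ref + 1) / (len(ref) + 1)) if ref else 0.0
    return HypothesisScore(
        survival=f_act,
        survival_inactive=f_act - penalty_lambda * f_inact,
        selectivity=sel,
        n_active_matched=n_act,
        n_inactive_matched=n_inact,
    )


def filter_hypotheses(
    scored: Sequence[tuple[PharmacophoreHypothesis, HypothesisScore]],
    survival_inactive_min: float = -math.inf,
    selectivity_min: float = -math.inf,
    inactive_match_top_k: int = 1,
) -> list[PharmacophoreHypothesis]:
    """Two-stage ranking filter.

    Stage 1 keeps hypotheses with survival-inactive and selectivity at or
    above the thresholds; stage 2 keeps the ``inactive_match_top_k`` with the
    fewest inactive matches (ties: higher survival-inactive, then hyp_id).
    Output sorted by hyp_id.
    """
    if inactive_match_top_k < 1:
        raise ValueError("inactive_match_top_k must be >= 1")
    stage1 = [
        (h, s)
        for h, s in scored
        if s.survival_inactive >= survival_inactive_min and s.selectivity >= selectivity_min
    ]
    stage2 = sorted(stage1, key=lambda hs: (hs[1].n_inactive_matched, -hs[1].survival_inactive, hs[0].hyp_id))
    kept = [h for h, _ in stage2[:inactive_match_top_k]]
    return sorted(kept, key=lambda h: h.hyp_id)
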
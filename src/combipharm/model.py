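"""Model/Results facade over the combinatorial-pharmacophore pipeline.

``CombinatorialPharmacophore`` is constructed from a labeled, feature-
perceived library; ``fit()`` runs the full protocol — common-pharmacophore
generation from the calibration actives, survival/selectivity scoring and
filtering, match-matrix construction, exhaustive 3/4-member model enumeration
and highest-BACC selection — and returns a ``CPResults`` object carrying the
selected model, the hypothesis pool with scores, the ranked candidate table
and calibration/test confusion metrics, with a ``summary()`` in the style of
a performance-comparison table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cp_select, hypothesis_engine, matcher, report_analysis
from .chem_core import MoleculeRecord
from .cp_select import CPModel, ConfusionMetrics
from .hypothesis_engine import GenerationParams, HypothesisScore, PharmacophoreHypothesis


@dataclass
class CPConfig:
    """Tunable parameters of the CP modeling protocol (units: Angstrom)."""

    k_values: tuple[int, ...] = (3, 4)
    sizes: tuple[int, ...] = (3, 4)
    bin_width: float = 1.0
    tol: float = 1.0
    min_actives: Optional[int] = None
    penalty_lambda: float = 1.0
    survival_inactive_min: float = 0.0
    selectivity_min: float = 0.0
    inactive_match_top_k: int = 27
    calibration_fraction: float = 0.5
    allow_smaller_models: bool = True
    max_features_per_conf: int = 16


class CombinatorialPharmacophore:
    """Combinatorial pharmacophore classifier fitted by exhaustive selection.

    Parameters
    ----------
    library:
        Labeled molecule records with perceived features per conformer
        (chemistry-backed or synthetic feature clouds).
    config:
        Protocol parameters; see :class:`CPConfig`.
    calibration_ids, test_ids:
        Explicit split by mol_id.  If omitted, ``fit`` performs a seeded
        stratified random split (``calibration_fraction`` per class).
    """

    def __init__(
        self,
        library: Sequence[MoleculeRecord],
        config: Optional[CPConfig] = None,
        calibration_ids: Optional[Sequence[str]] = None,
        test_ids: Optional[Sequence[str]] = None,
    ) -> None:
        self.library = list(library)
        ids = [r.mol_id for r in self.library]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate mol_id in library")
        labels = {r.label for r in self.library}
        if "active" not in labels or "inactive" not in labels:
            raise ValueError("library must contain both active and inactive records")
        self.config = config or CPConfig()
        self.calibration_ids = list(calibration_ids) if calibration_ids is not None else None
        self.test_ids = list(test_ids) if test_ids is not None else None

    @classmethod
    def from_feature_cloud_csv(cls, path, config: Optional[CPConfig] = None) -> "CombinatorialPharmacophore":
        from .fixtures import read_feature_cloud_csv

        return cls(read_feature_cloud_csv(path), config=config)

    # -- split ---------------------------------------------------------------

    def _split(self, seed: int) -> tuple[list[str], list[str]]:
        if self.calibration_ids is not None:
            cal = set(self.calibration_ids)
            test = (
                set(self.test_ids)
                if self.test_ids is not None
                else {r.mol_id for r in self.library} - cal
            )
            return sorted(cal), sorted(test)
        rng = np.random.default_rng(seed)
        cal: list[str] = []
        test: list[str] = []
        for label in ("active", "inactive"):
            ids = sorted(r.mol_id for r in self.library if r.label == label)
            rng.shuffle(ids)
            n_cal = int(round(self.config.calibration_fraction * len(ids)))
            cal.extend(ids[:n_cal])
            test.extend(ids[n_cal:])
        return sorted(cal), sorted(test)

    # -- fit -----------------------------------------------------------------

    def fit(self, seed: int = 0) -> "CPResults":
        """Run the full protocol and return the fitted results."""
        cfg = self.config
        cal_ids, test_ids = self._split(seed)
        by_id = {r.mol_id: r for r in self.library}
        cal = [by_id[i] for i in cal_ids]
        test = [by_id[i] for i in test_ids]
        cal_act = [r for r in cal if r.label == "active"]
        cal_inact = [r for r in cal if r.label == "inactive"]
        if not cal_act or not cal_inact:
            raise ValueError("calibration set must contain both classes")

        gen_params = GenerationParams(
            bin_width=cfg.bin_width,
            min_actives=cfg.min_actives,
            tol=cfg.tol,
            max_features_per_conf=cfg.max_features_per_conf,
        )
        hyps = hypothesis_engine.enumerate_candidate_hypotheses(
            cal_act, set(cfg.k_values), gen_params
        )
        if not hyps:
            raise ValueError("no common pharmacophore hypotheses found on the calibration actives")

        scores = {
            h.hyp_id: hypothesis_engine.score_hypothesis(
                h, cal_act, cal_inact, matcher.match_molecule, penalty_lambda=cfg.penalty_lambda
            )
            for h in hyps
        }
        pool = hypothesis_engine.filter_hypotheses(
            [(h, scores[h.hyp_id]) for h in hyps],
            survival_inactive_min=cfg.survival_inactive_min,
            selectivity_min=cfg.selectivity_min,
            inactive_match_top_k=cfg.inactive_match_top_k,
        )
        if not pool:
            raise ValueError("all hypotheses were filtered out; relax the score thresholds")

        matrix = matcher.build_match_matrix(self.library, pool)
        truth = pd.Series({r.mol_id: r.label for r in self.library})

        sizes = tuple(cfg.sizes)
        feasible = [s for s in sizes if s <= len(pool)]
        if not feasible and cfg.allow_smaller_models:
            warnings.warn(
                f"hypothesis pool of {len(pool)} supports no {sizes}-member model; "
                f"falling back to {len(pool)}-member models"
            )
            sizes = (len(pool),)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            candidates = cp_select.enumerate_cp_models([h.hyp_id for h in pool], sizes)
        if not candidates:
            raise ValueError("no candidate CP models could be enumerated")

        cal_matrix = matrix.loc[cal_ids]
        ranked = cp_select.rank_candidates(candidates, cal_matrix, truth)
        best = cp_select.select_best(candidates, cal_matrix, truth)
        if test_ids:
            best.metrics_test = cp_select.evaluate_on_set(best, matrix.loc[test_ids], truth)

        return CPResults(
            model=best,
            hypotheses=hyps,
            pool=pool,
            scores=scores,
            match_matrix=matrix,
            ranked_candidates=ranked,
            truth=truth,
            calibration_ids=cal_ids,
            test_ids=test_ids,
            config=replace(cfg),
            seed=seed,
            library=self.library,
        )


@dataclass
class CPResults:
    """Fitted combinatorial pharmacophore model plus diagnostics."""

    model: CPModel
    hypotheses: list[PharmacophoreHypothesis]
    pool: list[PharmacophoreHypothesis]
    scores: dict[str, HypothesisScore]
    match_matrix: pd.DataFrame
    ranked_candidates: pd.DataFrame
    truth: pd.Series
    calibration_ids: list[str]
    test_ids: list[str]
    config: CPConfig
    seed: int
    library: list[MoleculeRecord] = field(default_factory=list)

    @property
    def member_hypotheses(self) -> list[PharmacophoreHypothesis]:
        by_id = {h.hyp_id: h for h in self.pool}
        return [by_id[i] for i in self.model.member_ids]

    def scores_frame(self) -> pd.DataFrame:
        rows = [
            {
                "hyp_id": hid,
                "survival": s.survival,
                "survival_inactive": s.survival_inactive,
                "selectivity": s.selectivity,
                "n_active_matched": s.n_active_matched,
                "n_inactive_matched": s.n_inactive_matched,
            }
            for hid, s in sorted(self.scores.items())
        ]
        return pd.DataFrame(rows).set_index("hyp_id")

    def _eval(self, members: Sequence[str], ids: Sequence[str]) -> ConfusionMetrics:
        return cp_select.evaluate_on_set(
            CPModel(members=frozenset(members)), self.match_matrix.loc[list(ids)], self.truth
        )

    def performance_table(self) -> pd.DataFrame:
        """Per-member and CP-model SE/SP/ACC/BACC on calibration and test sets."""
        rows = []
        entries = [((hid,), hid) for hid in self.model.member_ids] + [
            (self.model.member_ids, "CP model")
        ]
        for members, name in entries:
            row = {"model": name}
            for setname, ids in (("calibration", self.calibration_ids), ("test", self.test_ids)):
                if not ids:
                    continue
                m = self._eval(members, ids)
                for metric, val in m.rounded().items():
                    row[f"{setname}_{metric}"] = val
            rows.append(row)
        return pd.DataFrame(rows).set_index("model")

    def mw_by_hypothesis(self) -> pd.DataFrame:
        """Molecular-weight summary per selected hypothesis (matched molecules)."""
        cols = list(self.model.member_ids)
        summaries = report_analysis.mw_by_hypothesis(self.library, self.match_matrix[cols])
        return report_analysis.mw_summary_frame(summaries)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Combinatorial Pharmacophore Model Results",
            "=" * 57,
            f"Library: {len(self.truth)} molecules "
            f"({int((self.truth == 'active').sum())} active / "
            f"{int((self.truth == 'inactive').sum())} inactive)",
            f"Split: {len(self.calibration_ids)} calibration / {len(self.test_ids)} test (seed {self.seed})",
            f"Hypotheses generated: {len(self.hypotheses)}; retained pool: {len(self.pool)}",
            f"Candidate CP models scored: {len(self.ranked_candidates)}",
            f"Selected members: {', '.join(self.model.member_ids)}",
            f"(bin_width {cfg.bin_width} A, tol {cfg.tol} A, lambda {cfg.penalty_lambda})",
            "",
            self.performance_table().to_string(),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CPResults members={self.model.member_ids} "
            f"bacc_cal={self.model.metrics_calibration.bacc:.3f}>"
        )
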
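"""Applying trained models: piecemeal imputation, staircases and testing.

At test time every cluster with a selected marker contributes one *piece*:
an add-one two-step run through T∪{m_i*} whose calls are recorded only at
the cluster's tract TC_i.  Tracts may overlap, so each (sample, marker) call
is decided by a majority vote over the covering pieces, with the direct
one-step call both as the fallback for uncovered markers and as the
tie-breaker.  Chaining piecemeal steps across nested density tiers gives
multi-step "staircase" imputation; a leg may also be a plain one-step run
(the usual final leg up to sequence density).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .cluster import PiecemealModel, train_piecemeal
from .features import addone_two_step
from .genotypes import (
    MISSING,
    AccuracyReport,
    GenotypeMatrix,
    evaluate_accuracy,
    expand_to_panel,
    typed_ids_of,
)
from .imputers import GenotypeImputer, KNNGenotypeImputer, _as_imputer, one_step
from .markers import MarkerPanel


class _OneStepSentinel:
    """Marks a staircase leg imputed directly in one step (no trained model)."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ONE_STEP"


#: Sentinel accepted in staircase step lists in place of a trained model.
ONE_STEP = _OneStepSentinel()


def majority_vote(calls: Iterable[int], fallback: int) -> int:
    """Strict plurality over piece calls; ties resolved by the fallback call.

    If the top count is tied, the fallback dosage wins when it is among the
    tied values, otherwise the smallest tied dosage does.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("majority_vote requires at least one call")
    if fallback not in (0, 1, 2):
        raise ValueError(f"fallback dosage must be in {{0,1,2}}, got {fallback}")
    if any(c not in (0, 1, 2) for c in calls):
        raise ValueError("piece calls must be dosages in {0,1,2}")
    counts = Counter(calls)
    top = max(counts.values())
    tied = sorted(v for v, n in counts.items() if n == top)
    if len(tied) == 1:
        return tied[0]
    return fallback if fallback in tied else tied[0]


@dataclass
class PieceCallSet:
    """Per-piece imputed calls, restricted to each cluster's tract.

    ``pieces[cluster]`` holds the tract's marker ids and a samples x tract
    dosage array; entries exist only for clusters with a selected marker.
    """

    sample_ids: tuple
    pieces: Dict[int, Tuple[tuple, np.ndarray]]

    def get(self, cluster: int, sample_id: str, marker_id: str) -> int:
        marker_ids, calls = self.pieces[cluster]
        return int(calls[self.sample_ids.index(sample_id), marker_ids.index(marker_id)])

    def items(self):
        for cluster, (marker_ids, calls) in self.pieces.items():
            for s, sid in enumerate(self.sample_ids):
                for m, mid in enumerate(marker_ids):
                    yield (cluster, sid, mid), int(calls[s, m])


def collect_pieces(
    model: PiecemealModel,
    reference: GenotypeMatrix,
    study: GenotypeMatrix,
    engine=None,
) -> PieceCallSet:
    """Run one add-one two-step per selected marker, keeping tract calls only."""
    engine = engine if engine is not None else model.base_spec.build()
    pieces: Dict[int, Tuple[tuple, np.ndarray]] = {}
    for cluster in range(model.clustering.k):
        m_star = model.selected_marker.get(cluster)
        if m_star is None:
            continue
        tract = [m for m in model.untyped_ids if m in model.target_clusters[cluster]]
        piece = addone_two_step(engine, reference, study, m_star)
        cols = [piece.panel.index(m) for m in tract]
        pieces[cluster] = (tuple(tract), piece.calls[:, cols].copy())
    return PieceCallSet(tuple(study.sample_ids), pieces)


def _validate_model_panels(model: PiecemealModel, reference: GenotypeMatrix,
                           study: GenotypeMatrix) -> None:
    ref_ids = set(reference.panel.ids)
    if not set(model.typed_panel.ids) <= ref_ids:
        raise ValueError("model typed panel is not covered by the reference panel")
    if not set(model.untyped_ids) <= ref_ids:
        raise ValueError("model untyped markers are not covered by the reference panel")
    typed = set(typed_ids_of(study, reference.panel))
    if typed != set(model.typed_panel.ids):
        raise ValueError("study must be typed exactly on the model's typed panel")


def piecemeal_impute(
    model: PiecemealModel,
    reference: GenotypeMatrix,
    study: GenotypeMatrix,
    engine=None,
) -> GenotypeMatrix:
    """Two-step piecemeal imputation of study samples to the reference panel.

    A single one-step run provides the fallback call for every untyped
    marker; each cluster with a selected marker contributes tract calls via
    its add-one two-step run; each (sample, untyped marker) covered by at
    least one piece is decided by majority vote with the fallback as
    tie-breaker, uncovered markers keep the fallback call.  Typed calls pass
    through unchanged.
    """
    engine = engine if engine is not None else model.base_spec.build()
    _validate_model_panels(model, reference, study)
    fallback, _ = one_step(engine, reference, study)
    pieces = collect_pieces(model, reference, study, engine=engine)
    out = fallback.calls.copy()
    n_samples = fallback.n_samples
    vote_counts: Dict[str, np.ndarray] = {}
    for _cluster, (marker_ids, calls) in pieces.pieces.items():
        for m, mid in enumerate(marker_ids):
            cnt = vote_counts.setdefault(mid, np.zeros((n_samples, 3), dtype=np.int32))
            col = calls[:, m]
            for d in (0, 1, 2):
                cnt[:, d] += col == d
    rows = np.arange(n_samples)
    for mid, cnt in vote_counts.items():
        j = fallback.panel.index(mid)
        top = cnt.max(axis=1)
        is_tied = cnt == top[:, None]
        n_tied = is_tied.sum(axis=1)
        first_tied = is_tied.argmax(axis=1)  # smallest tied dosage
        fb = fallback.calls[:, j].astype(int)
        fb_among = is_tied[rows, fb]
        voted = np.where(n_tied == 1, first_tied, np.where(fb_among, fb, first_tied))
        out[:, j] = voted.astype(np.int8)
    return GenotypeMatrix(fallback.sample_ids, fallback.panel, out)


def two_step_pseudo_array(
    model: PiecemealModel,
    reference: GenotypeMatrix,
    study: GenotypeMatrix,
    engine=None,
) -> GenotypeMatrix:
    """Plain two-step imputation through the joint pseudo-array T∪M.

    Comparison mode: all selected markers are imputed jointly in the first
    step and the remaining untyped markers in a single second step, with no
    per-tract assembly or voting.
    """
    engine = engine if engine is not None else model.base_spec.build()
    _validate_model_panels(model, reference, study)
    selected = {m for m in model.selected_marker.values() if m is not None}
    if not selected:
        imputed, _ = one_step(engine, reference, study)
        return imputed
    typed = set(model.typed_panel.ids)
    step1_ids = [i for i in reference.panel.ids if i in typed or i in selected]
    ref1 = reference.restrict_markers(step1_ids)
    study_typed = study.restrict_markers([i for i in study.panel.ids if i in typed])
    from .imputers import impute

    step1 = impute(engine, ref1, expand_to_panel(study_typed, ref1.panel))
    return impute(engine, reference, expand_to_panel(step1, reference.panel))


@dataclass
class IndependentTestResult:
    """Side-by-side piecemeal and one-step accuracy on held-out samples."""

    piecemeal: AccuracyReport
    one_step: AccuracyReport

    @property
    def improvement(self) -> float:
        return self.piecemeal.overall - self.one_step.overall


def independent_test(
    model: PiecemealModel,
    reference: GenotypeMatrix,
    study: GenotypeMatrix,
    truth: GenotypeMatrix,
    engine=None,
) -> IndependentTestResult:
    """Evaluate a trained model on held-out study samples against the truth.

    Warns when study samples overlap the model's training samples (reported
    accuracies could then be biased upward).
    """
    engine = engine if engine is not None else model.base_spec.build()
    overlap = set(study.sample_ids) & set(model.training_sample_ids)
    if overlap:
        warnings.warn(
            f"{len(overlap)} study sample(s) were used in training; "
            "accuracies may be slightly biased"
        )
    u_panel = reference.panel.restrict(model.untyped_ids)
    imputed = piecemeal_impute(model, reference, study, engine=engine)
    acc_pi = evaluate_accuracy(imputed, truth, u_panel)
    _, acc1 = one_step(engine, reference, study, truth)
    return IndependentTestResult(acc_pi, acc1)


def staircase_impute(
    steps: Sequence,
    references: Sequence[GenotypeMatrix],
    study: GenotypeMatrix,
    engine=None,
) -> GenotypeMatrix:
    """Chain imputation legs across nested density tiers.

    ``steps[t]`` is either a trained :class:`PiecemealModel` mapping tier t
    to tier t+1 or the :data:`ONE_STEP` sentinel (direct base imputation,
    requiring ``engine``).  ``references[t]`` covers leg t's higher tier.
    The output of each leg becomes the typed input of the next.
    """
    steps = list(steps)
    references = list(references)
    if len(steps) != len(references):
        raise ValueError("need exactly one reference matrix per staircase step")
    if not steps:
        raise ValueError("staircase needs at least one step")
    # validate tier nesting before any imputation
    current_ids = set(study.panel.ids)
    for t, (step, ref) in enumerate(zip(steps, references)):
        ref_ids = set(ref.panel.ids)
        if not current_ids < ref_ids:
            raise ValueError(f"staircase step {t}: panels do not nest strictly")
        if isinstance(step, PiecemealModel):
            if set(step.typed_panel.ids) != current_ids:
                raise ValueError(
                    f"staircase step {t}: model typed panel does not match the incoming tier"
                )
        elif step is not ONE_STEP:
            raise ValueError(f"staircase step {t}: expected a PiecemealModel or ONE_STEP")
        elif engine is None:
            raise ValueError(f"staircase step {t} is ONE_STEP and needs a base engine")
        current_ids = ref_ids
    current = study
    for step, ref in zip(steps, references):
        if step is ONE_STEP:
            current, _ = one_step(engine, ref, current)
        else:
            current = piecemeal_impute(step, ref, current, engine=engine)
    return current


class PiecemealImputer(BaseEstimator):
    """Scikit-learn style estimator wrapping piecemeal training and imputation.

    ``fit`` runs cross-validated training on a fully genotyped training
    matrix (the sequenced animals) given the typed (low-density) panel;
    ``transform`` piecemeal-imputes new study samples typed on that panel,
    using the training matrix as the reference.

    Parameters
    ----------
    base_imputer:
        Base engine (default :class:`KNNGenotypeImputer` with its defaults).
    n_folds, k_grid, threshold_mode, n_restarts, max_iter, random_state:
        Training-protocol knobs; see :func:`piecemeal.cluster.train_piecemeal`.
    """

    def __init__(
        self,
        base_imputer: Optional[GenotypeImputer] = None,
        n_folds: int = 5,
        k_grid: Sequence[int] = (5, 10, 15, 20, 25, 30),
        threshold_mode: str = "global_acc1",
        n_restarts: int = 10,
        max_iter: int = 300,
        random_state: int = 0,
    ):
        self.base_imputer = base_imputer
        self.n_folds = n_folds
        self.k_grid = k_grid
        self.threshold_mode = threshold_mode
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def _engine(self) -> GenotypeImputer:
        return self.base_imputer if self.base_imputer is not None else KNNGenotypeImputer()

    def fit(self, X: GenotypeMatrix, typed_panel: MarkerPanel, strata=None):
        """Train on a fully genotyped matrix ``X`` with ``typed_panel`` as T."""
        self.model_, self.cv_accuracy_ = train_piecemeal(
            self._engine(),
            X,
            typed_panel,
            k_grid=self.k_grid,
            n_folds=self.n_folds,
            seed=self.random_state,
            threshold_mode=self.threshold_mode,
            strata=strata,
            n_restarts=self.n_restarts,
            max_iter=self.max_iter,
        )
        self.reference_ = X
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        """Piecemeal-impute study samples typed on the fitted typed panel."""
        if not hasattr(self, "model_"):
            raise RuntimeError("PiecemealImputer is not fitted")
        return piecemeal_impute(self.model_, self.reference_, X, engine=self._engine())

    def predict(self, X: GenotypeMatrix) -> GenotypeMatrix:
        return self.transform(X)

    def score(self, X: GenotypeMatrix, truth: GenotypeMatrix) -> float:
        """Piecemeal genotype concordance over the untyped markers."""
        if not hasattr(self, "model_"):
            raise RuntimeError("PiecemealImputer is not fitted")
        u_panel = self.reference_.panel.restrict(self.model_.untyped_ids)
        return evaluate_accuracy(self.transform(X), truth, u_panel).overall
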
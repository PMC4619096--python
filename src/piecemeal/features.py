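"""Add-one two-step experiments, marker feature vectors and CV folds.

For every untyped marker m_i, an *add-one two-step* imputation — from the
typed set T to T∪{m_i} and then from T∪{m_i} to T∪U — measures how much
knowing m_i helps the imputation of every other untyped marker.  The
per-marker accuracies a_ij of that run form the *feature vector*
v_i = <a_i1, ..., a_i|U|> of m_i; the diagonal a_ii is the one-step accuracy
of imputing m_i itself from T.  Stacking the vectors gives the |U| x |U|
:class:`FeatureMatrix` on which marker clustering and selection operate.

Feature matrices are built per cross-validation fold (study fold rotated,
remaining folds as reference) and averaged entrywise across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotypes import (
    GenotypeMatrix,
    evaluate_accuracy,
    expand_to_panel,
    typed_ids_of,
)
from .imputers import impute, one_step
from .markers import Marker, MarkerPanel

#: Sentinel for a feature entry with no evaluable truth calls.
UNDEFINED = float("nan")

_FORMAT_TAG = "piecemeal-feature-matrix"
_FORMAT_VERSION = 1


@dataclass(eq=False)
class FeatureMatrix:
    """|U| x |U| table of add-one accuracies plus the one-step baseline.

    ``values[i, j]`` is a_ij; rows and columns share ``marker_ids`` order.
    Undefined entries (no evaluable truth calls) are NaN.
    """

    marker_ids: tuple
    values: np.ndarray
    acc1_per_marker: np.ndarray
    acc1_overall: float

    def __post_init__(self) -> None:
        self.marker_ids = tuple(self.marker_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.acc1_per_marker = np.asarray(self.acc1_per_marker, dtype=float)
        n = len(self.marker_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"feature values must be {n}x{n}, got {self.values.shape}")
        if self.acc1_per_marker.shape != (n,):
            raise ValueError("acc1_per_marker must align with marker_ids")
        defined = self.values[~np.isnan(self.values)]
        if defined.size and (defined.min() < -1e-9 or defined.max() > 1 + 1e-9):
            raise ValueError("defined feature entries must lie in [0, 1]")
        self._index = {m: i for i, m in enumerate(self.marker_ids)}

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def index(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not in feature matrix") from None

    def row(self, marker_id: str) -> np.ndarray:
        return self.values[self.index(marker_id)]

    def reorder(self, marker_ids: Sequence[str]) -> "FeatureMatrix":
        """Consistently permute rows and columns to a new marker order."""
        perm = [self.index(m) for m in marker_ids]
        return FeatureMatrix(
            tuple(marker_ids),
            self.values[np.ix_(perm, perm)].copy(),
            self.acc1_per_marker[perm].copy(),
            self.acc1_overall,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.marker_ids), columns=list(self.marker_ids))

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#{_FORMAT_TAG}\tv{_FORMAT_VERSION}\tacc1_overall={self.acc1_overall!r}\n")
            df = self.to_frame()
            df["__acc1__"] = self.acc1_per_marker
            df.to_csv(fh, sep="\t", index_label="marker_id", na_rep="NA")

    @classmethod
    def load_tsv(cls, path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            parts = header.lstrip("#").split("\t")
            if len(parts) != 3 or parts[0] != _FORMAT_TAG:
                raise ValueError(f"{path} is not a feature-matrix file")
            acc1_overall = float(parts[2].split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
        acc1 = df.pop("__acc1__").to_numpy(dtype=float)
        return cls(tuple(df.index), df.to_numpy(dtype=float), acc1, acc1_overall)


def _resolve_marker_id(m) -> str:
    return m.id if isinstance(m, Marker) else str(m)


def addone_two_step(
    engine,
    reference: GenotypeMatrix,
    study: GenotypeMatrix,
    m_i,
) -> GenotypeMatrix:
    """Two-step imputation through the one-marker pseudo-array T∪{m_i}.

    Step 1 imputes the study samples at m_i against the reference restricted
    to T∪{m_i}; step 2 treats that output as typed on T∪{m_i} and imputes the
    remaining untyped markers against the full reference.
    """
    mid = _resolve_marker_id(m_i)
    typed = set(typed_ids_of(study, reference.panel))
    if mid not in reference.panel or mid in typed:
        raise ValueError(f"marker {mid!r} is not an untyped marker of the reference panel")
    step1_ids = [i for i in reference.panel.ids if i in typed or i == mid]
    ref1 = reference.restrict_markers(step1_ids)
    study_typed = study.restrict_markers([i for i in study.panel.ids if i in typed])
    step1 = impute(engine, ref1, expand_to_panel(study_typed, ref1.panel))
    study2 = expand_to_panel(step1, reference.panel)
    return impute(engine, reference, study2)


def feature_row(
    engine,
    reference: GenotypeMatrix,
    study: GenotypeMatrix,
    truth: GenotypeMatrix,
    m_i,
) -> Tuple[np.ndarray, float]:
    """One add-one run for m_i: (a_ij over all m_j in U, a_ii)."""
    mid = _resolve_marker_id(m_i)
    typed = set(typed_ids_of(study, reference.panel))
    untyped = [i for i in reference.panel.ids if i not in typed]
    result = addone_two_step(engine, reference, study, mid)
    report = evaluate_accuracy(result, truth, reference.panel.restrict(untyped))
    row = np.array([report.per_marker[j] for j in untyped], dtype=float)
    # step 2 never alters the (now typed) m_i calls, so the final matrix
    # carries the step-1 accuracy at m_i unchanged
    a_ii = float(row[untyped.index(mid)])
    return row, a_ii


def build_feature_matrix(
    engine,
    reference: GenotypeMatrix,
    study: GenotypeMatrix,
    truth: GenotypeMatrix,
    untyped_ids: Optional[Sequence[str]] = None,
) -> FeatureMatrix:
    """One feature row per untyped marker, plus the one-step baseline.

    Rows are mutually independent: building them in any order (or in
    parallel) yields identical values.
    """
    typed = set(typed_ids_of(study, reference.panel))
    derived = [i for i in reference.panel.ids if i not in typed]
    if untyped_ids is None:
        untyped_ids = derived
    else:
        untyped_ids = [_resolve_marker_id(m) for m in untyped_ids]
        if set(untyped_ids) != set(derived):
            raise ValueError("untyped_ids must equal the reference panel minus the typed set")
    _, acc1 = one_step(engine, reference, study, truth)
    n = len(untyped_ids)
    values = np.full((n, n), UNDEFINED)
    order = {m: i for i, m in enumerate(derived)}
    for i, mid in enumerate(untyped_ids):
        try:
            row, _ = feature_row(engine, reference, study, truth, mid)
        except Exception as exc:
            raise RuntimeError(f"add-one experiment failed for marker {mid!r}") from exc
        values[i] = row[[order[m] for m in untyped_ids]]
    acc1_per_marker = np.array(
        [acc1.per_marker.get(m, UNDEFINED) for m in untyped_ids], dtype=float
    )
    return FeatureMatrix(tuple(untyped_ids), values, acc1_per_marker, acc1.overall)


@dataclass
class FoldAssignment:
    """Mapping of samples to cross-validation folds."""

    fold_of_sample: Dict[str, int]
    n_folds: int

    def __post_init__(self):
        bad = [s for s, f in self.fold_of_sample.items() if not 0 <= f < self.n_folds]
        if bad:
            raise ValueError(f"fold indices out of range for samples: {bad}")

    def samples_in(self, fold: int) -> List[str]:
        return [s for s, f in self.fold_of_sample.items() if f == fold]

    def samples_not_in(self, fold: int) -> List[str]:
        return [s for s, f in self.fold_of_sample.items() if f != fold]

    def sizes(self) -> List[int]:
        return [len(self.samples_in(f)) for f in range(self.n_folds)]


def make_cv_folds(
    sample_ids: Sequence[str],
    n_folds: int,
    seed: int = 0,
    strata: Optional[Dict[str, str]] = None,
) -> FoldAssignment:
    """Seeded shuffle then round-robin assignment into folds of near-equal size.

    With ``strata``, samples are shuffled and dealt round-robin within each
    stratum (continuing the global rotation across strata), spreading every
    label across folds while keeping overall fold sizes within one of each
    other.
    """
    sample_ids = list(sample_ids)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > len(sample_ids):
        raise ValueError(f"n_folds={n_folds} exceeds number of samples ({len(sample_ids)})")
    rng = np.random.default_rng(seed)
    if strata is None:
        groups = [sample_ids]
    else:
        missing = [s for s in sample_ids if s not in strata]
        if missing:
            raise ValueError(f"samples without a stratum label: {missing}")
        labels = sorted(set(strata[s] for s in sample_ids))
        groups = [[s for s in sample_ids if strata[s] == lab] for lab in labels]
    fold_of = {}
    counter = 0
    for group in groups:
        perm = rng.permutation(len(group))
        for offset, g_idx in enumerate(perm):
            fold_of[group[int(g_idx)]] = (counter + offset) % n_folds
        counter += len(group)
    fold_of = {s: fold_of[s] for s in sample_ids}
    return FoldAssignment(fold_of, n_folds)


def average_fold_features(per_fold: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Entrywise mean over folds, ignoring undefined entries.

    An entry undefined in every fold stays undefined; the acc1 baseline
    fields are averaged the same way.
    """
    if not per_fold:
        raise ValueError("need at least one fold feature matrix")
    ids = per_fold[0].marker_ids
    for fm in per_fold[1:]:
        if fm.marker_ids != ids:
            raise ValueError("fold feature matrices disagree on marker order")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(np.stack([fm.values for fm in per_fold]), axis=0)
        acc1_pm = np.nanmean(np.stack([fm.acc1_per_marker for fm in per_fold]), axis=0)
        acc1 = float(np.nanmean([fm.acc1_overall for fm in per_fold]))
    return FeatureMatrix(ids, values, acc1_pm, acc1)
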
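"""Genotype matrices, masking, allele-consistency filtering and concordance.

Genotypes are unphased alt-allele dosages in {0, 1, 2}; phase is discarded on
input.  Missing calls use the sentinel :data:`MISSING` (-1), serialized as
"NA" in text formats.  Accuracy is genotype concordance: an imputed call is
correct iff its dosage equals the truth dosage exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np

from .markers import Marker, MarkerPanel

#: Sentinel for a missing genotype call (outside the valid dosage range).
MISSING: int = -1

_VALID_CALLS = np.array([MISSING, 0, 1, 2], dtype=np.int8)


@dataclass(eq=False)
class GenotypeMatrix:
    """Samples x markers table of biallelic genotype dosages.

    ``calls[s, j]`` is the alt-allele dosage of sample ``s`` at marker ``j``
    (panel order), or :data:`MISSING`.
    """

    sample_ids: tuple
    panel: MarkerPanel
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.panel)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.panel)} markers"
            )
        if not np.isin(self.calls, _VALID_CALLS).all():
            bad = np.unique(self.calls[~np.isin(self.calls, _VALID_CALLS)])
            raise ValueError(f"genotype calls must be in {{0,1,2}} or MISSING; found {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.panel)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.panel.index(marker_id)]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids, self.panel, self.calls.copy())

    def restrict_markers(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        sub = self.panel.restrict(marker_ids)
        cols = [self.panel.index(i) for i in sub.ids]
        return GenotypeMatrix(self.sample_ids, sub, self.calls[:, cols].copy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        sample_ids = list(sample_ids)
        rows = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(tuple(sample_ids), self.panel, self.calls[rows].copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Bit-exact equality of samples, panel and calls."""
        return (
            self.sample_ids == other.sample_ids
            and self.panel == other.panel
            and np.array_equal(self.calls, other.calls)
        )


def expand_to_panel(g: GenotypeMatrix, panel: MarkerPanel) -> GenotypeMatrix:
    """Re-express ``g`` on a superset ``panel``, filling new markers with MISSING."""
    missing_from_target = set(g.panel.ids) - set(panel.ids)
    if missing_from_target:
        raise ValueError(
            f"target panel lacks markers present in matrix: {sorted(missing_from_target)[:5]}"
        )
    calls = np.full((g.n_samples, len(panel)), MISSING, dtype=np.int8)
    cols = [panel.index(i) for i in g.panel.ids]
    calls[:, cols] = g.calls
    return GenotypeMatrix(g.sample_ids, panel, calls)


def mask_to_panel(g: GenotypeMatrix, typed: MarkerPanel) -> GenotypeMatrix:
    """Set calls at all markers outside ``typed`` to MISSING, mimicking untyped SNPs."""
    offenders = [i for i in typed.ids if i not in g.panel]
    if offenders:
        raise ValueError(f"typed panel contains markers absent from matrix: {offenders}")
    typed_ids = set(typed.ids)
    keep = np.array([i in typed_ids for i in g.panel.ids], dtype=bool)
    calls = np.where(keep[None, :], g.calls, np.int8(MISSING)).astype(np.int8)
    return GenotypeMatrix(g.sample_ids, g.panel, calls)


def typed_ids_of(study: GenotypeMatrix, reference_panel: MarkerPanel) -> tuple:
    """The typed marker ids of a study matrix relative to a reference panel.

    If the study panel is a proper subset of the reference panel, the study
    panel itself is the typed set.  If the panels coincide, typed markers are
    those with at least one non-missing call (untyped markers are fully
    masked columns).
    """
    study_ids = set(study.panel.ids)
    ref_ids = set(reference_panel.ids)
    if not study_ids <= ref_ids:
        raise ValueError("study panel is not a subset of the reference panel")
    if study_ids != ref_ids:
        return study.panel.ids
    has_call = (study.calls != MISSING).any(axis=0)
    return tuple(i for i, ok in zip(study.panel.ids, has_call) if ok)


def filter_allele_consistent(
    chip: MarkerPanel, sequence: MarkerPanel
) -> Tuple[MarkerPanel, List[str]]:
    """Keep chip markers whose unordered {ref, alt} pair matches the sequence panel.

    Markers are matched by (chrom, pos).  A chip marker absent from the
    sequence panel, or with a disagreeing allele pair, is excluded.
    """
    seq_alleles = {m.locus: m.alleles for m in sequence}
    kept, excluded = [], []
    for m in chip:
        if seq_alleles.get(m.locus) == m.alleles:
            kept.append(m)
        else:
            excluded.append(m.id)
    return MarkerPanel(kept), excluded


@dataclass
class AccuracyReport:
    """Genotype-concordance summary over a set of evaluated markers.

    ``overall`` is NaN when no call was evaluable (undefined sentinel);
    per-marker entries are likewise NaN when a marker had no evaluable calls.
    """

    overall: float
    per_marker: Dict[str, float]
    n_evaluated: int
    n_correct: int

    @property
    def is_defined(self) -> bool:
        return not math.isnan(self.overall)


def evaluate_accuracy(
    imputed: GenotypeMatrix, truth: GenotypeMatrix, eval_markers: MarkerPanel
) -> AccuracyReport:
    """Exact-dosage concordance between imputed and truth calls.

    Calls where the truth is MISSING are excluded from the denominator; calls
    where the imputed value is MISSING but the truth is not count as
    incorrect.
    """
    if set(imputed.sample_ids) != set(truth.sample_ids):
        raise ValueError("imputed and truth matrices must cover the same samples")
    truth = truth.subset_samples(imputed.sample_ids)
    ids = eval_markers.ids
    icols = [imputed.panel.index(i) for i in ids]
    tcols = [truth.panel.index(i) for i in ids]
    imp = imputed.calls[:, icols]
    tru = truth.calls[:, tcols]
    evaluable = tru != MISSING
    correct = evaluable & (imp == tru)
    n_eval = int(evaluable.sum())
    n_corr = int(correct.sum())
    overall = n_corr / n_eval if n_eval else float("nan")
    col_eval = evaluable.sum(axis=0)
    col_corr = correct.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        col_acc = np.where(col_eval > 0, col_corr / np.maximum(col_eval, 1), np.nan)
    per_marker = {mid: float(a) for mid, a in zip(ids, col_acc)}
    return AccuracyReport(overall, per_marker, n_eval, n_corr)
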
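"""Pluggable base genotype imputers and the one-step imputation wrapper.

The piecemeal framework is model-dependent: it wraps *some* population-based
genotype imputation engine and hunts for improvement on top of it.  The
engine contract is small: given a reference genotyped on a panel and study
samples with untyped markers MISSING, fill every missing study call with a
dosage, never altering a typed call, deterministically.

Two deterministic built-in engines satisfy the contract:

* :class:`MajorityImputer` — per-marker mode of the reference genotypes; the
  LD-blind baseline.
* :class:`KNNGenotypeImputer` — Hamming-nearest reference haplotype windows;
  for each missing call the window of typed markers nearest the target
  position is compared against every reference, the k closest references
  vote, and the dosage mode wins.  This is the LD-aware workhorse used
  throughout the test-bench.

:class:`ExternalCommandImputer` adapts any command-line engine through a VCF
round-trip; it exists for parity experiments with external programs and is
exempt from the determinism contract.

Estimators follow scikit-learn conventions (``fit``/``transform``,
``get_params``, trailing-underscore fitted attributes) and compose with
``sklearn.base.clone``.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, clone

from .genotypes import (
    MISSING,
    AccuracyReport,
    GenotypeMatrix,
    evaluate_accuracy,
    expand_to_panel,
    typed_ids_of,
)
from .markers import Marker, MarkerPanel


def _check_same_panel(a: MarkerPanel, b: MarkerPanel) -> None:
    if a != b:
        raise ValueError("study and reference must share the same marker panel")


class GenotypeImputer(BaseEstimator):
    """Base class for genotype imputation engines."""

    def fit(self, reference: GenotypeMatrix, y=None):
        raise NotImplementedError

    def transform(self, study: GenotypeMatrix) -> GenotypeMatrix:
        raise NotImplementedError


class MajorityImputer(GenotypeImputer):
    """Fill each missing call with the reference's modal dosage at that marker.

    Mode ties break toward the smaller dosage so runs are reproducible.
    """

    def fit(self, reference: GenotypeMatrix, y=None):
        counts = np.stack([(reference.calls == d).sum(axis=0) for d in (0, 1, 2)])
        total = counts.sum(axis=0)
        modes = counts.argmax(axis=0).astype(np.int8)  # argmax -> smallest dosage on ties
        self.reference_ = reference
        self.modes_ = np.where(total > 0, modes, np.int8(MISSING)).astype(np.int8)
        return self

    def transform(self, study: GenotypeMatrix) -> GenotypeMatrix:
        _check_same_panel(study.panel, self.reference_.panel)
        out = study.calls.copy()
        miss = out == MISSING
        for j in np.flatnonzero(miss.any(axis=0)):
            if self.modes_[j] == MISSING:
                raise ValueError(
                    f"reference is entirely missing at marker {study.panel[int(j)].id}"
                )
        out = np.where(miss, self.modes_[None, :], out).astype(np.int8)
        return GenotypeMatrix(study.sample_ids, study.panel, out)


class KNNGenotypeImputer(GenotypeImputer):
    """k-nearest-reference imputation over positional windows of typed markers.

    Parameters
    ----------
    window_typed_markers:
        Odd number of typed markers, nearest to the target marker's position
        on the same chromosome, used for the Hamming distance (truncated at
        chromosome ends).  Counting typed markers rather than base pairs
        keeps the neighborhood semantics stable across density tiers.
    k_neighbors:
        Number of minimal-distance references whose dosages vote; distance
        ties break by reference order, dosage-mode ties toward the smaller
        dosage.
    """

    def __init__(self, window_typed_markers: int = 11, k_neighbors: int = 5):
        self.window_typed_markers = window_typed_markers
        self.k_neighbors = k_neighbors

    def fit(self, reference: GenotypeMatrix, y=None):
        if self.window_typed_markers < 1 or self.window_typed_markers % 2 == 0:
            raise ValueError("window_typed_markers must be an odd integer >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.k_neighbors > reference.n_samples:
            raise ValueError(
                f"k_neighbors={self.k_neighbors} exceeds number of references "
                f"({reference.n_samples})"
            )
        self.reference_ = reference
        return self

    def transform(self, study: GenotypeMatrix) -> GenotypeMatrix:
        _check_same_panel(study.panel, self.reference_.panel)
        ref_calls = self.reference_.calls
        out = study.calls.copy()
        typed_mask = out != MISSING
        if typed_mask.all():
            return GenotypeMatrix(study.sample_ids, study.panel, out)
        positions = study.panel.positions
        chroms = study.panel.chroms
        masks, inverse = np.unique(typed_mask, axis=0, return_inverse=True)
        for g_id in range(masks.shape[0]):
            mask = masks[g_id]
            rows = np.flatnonzero(inverse == g_id)
            missing_idx = np.flatnonzero(~mask)
            if missing_idx.size == 0:
                continue
            typed_idx = np.flatnonzero(mask)
            study_g = out[rows]
            for j in missing_idx:
                cand = np.flatnonzero(ref_calls[:, j] != MISSING)
                if cand.size == 0:
                    raise ValueError(
                        f"reference is entirely missing at marker {study.panel[int(j)].id}"
                    )
                win = self._window(typed_idx, int(j), chroms, positions)
                if win.size:
                    dist = (study_g[:, win][:, None, :] != ref_calls[np.ix_(cand, win)][None, :, :]).sum(
                        axis=-1
                    )
                else:
                    dist = np.zeros((rows.size, cand.size), dtype=int)
                k = min(self.k_neighbors, cand.size)
                order = np.argsort(dist, axis=1, kind="stable")[:, :k]
                dosages = ref_calls[cand[order], j]
                counts = np.stack([(dosages == d).sum(axis=1) for d in (0, 1, 2)])
                out[rows, j] = counts.argmax(axis=0).astype(np.int8)
        return GenotypeMatrix(study.sample_ids, study.panel, out)

    def _window(self, typed_idx, j, chroms, positions) -> np.ndarray:
        same = typed_idx[chroms[typed_idx] == chroms[j]]
        if same.size == 0:
            return same
        dist = np.abs(positions[same] - positions[j])
        order = np.argsort(dist, kind="stable")
        return same[order[: self.window_typed_markers]]


class ExternalCommandImputer(GenotypeImputer):
    """Adapter running an external imputation program through a VCF round-trip.

    ``command_template`` is formatted with ``{ref_vcf}``, ``{study_vcf}`` and
    ``{out_vcf}`` placeholders and run through the shell.  The external
    program owns its own settings and randomness, so this engine is exempt
    from the determinism contract; typed study calls are restored after the
    round-trip to uphold the never-alter-typed contract regardless of the
    engine's behavior.
    """

    def __init__(self, command_template: str = ""):
        self.command_template = command_template

    def fit(self, reference: GenotypeMatrix, y=None):
        if not self.command_template:
            raise ValueError("command_template must be provided")
        self.reference_ = reference
        return self

    def transform(self, study: GenotypeMatrix) -> GenotypeMatrix:
        from .io import read_genotypes, write_genotypes

        _check_same_panel(study.panel, self.reference_.panel)
        with tempfile.TemporaryDirectory() as tmp:
            ref_vcf = Path(tmp) / "reference.vcf"
            study_vcf = Path(tmp) / "study.vcf"
            out_vcf = Path(tmp) / "imputed.vcf"
            write_genotypes(self.reference_, ref_vcf, format="vcf")
            write_genotypes(study, study_vcf, format="vcf")
            cmd = self.command_template.format(
                ref_vcf=ref_vcf, study_vcf=study_vcf, out_vcf=out_vcf
            )
            subprocess.run(cmd, shell=True, check=True)
            imputed, _ = read_genotypes(out_vcf, format="vcf")
        imputed = imputed.subset_samples(study.sample_ids).restrict_markers(study.panel.ids)
        typed = study.calls != MISSING
        calls = np.where(typed, study.calls, imputed.calls).astype(np.int8)
        return GenotypeMatrix(study.sample_ids, study.panel, calls)


@dataclass(frozen=True)
class BaseImputerSpec:
    """Declarative description of a base imputer, for configs and model files."""

    kind: str = "knn"
    window_typed_markers: Optional[int] = 11
    k_neighbors: Optional[int] = 5
    external_command_template: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("majority", "knn", "external"):
            raise ValueError(f"unknown imputer kind {self.kind!r}")
        if self.kind == "knn":
            if self.window_typed_markers is None or self.k_neighbors is None:
                raise ValueError("knn imputer requires window_typed_markers and k_neighbors")
            if self.window_typed_markers % 2 == 0 or self.window_typed_markers < 1:
                raise ValueError("window_typed_markers must be an odd integer >= 1")
            if self.k_neighbors < 1:
                raise ValueError("k_neighbors must be >= 1")
        else:
            if self.window_typed_markers is not None or self.k_neighbors is not None:
                raise ValueError(f"knn fields must be absent for kind={self.kind!r}")
        if self.kind == "external" and not self.external_command_template:
            raise ValueError("external imputer requires a command template")

    def build(self) -> GenotypeImputer:
        if self.kind == "majority":
            return MajorityImputer()
        if self.kind == "knn":
            return KNNGenotypeImputer(self.window_typed_markers, self.k_neighbors)
        return ExternalCommandImputer(self.external_command_template)

    @classmethod
    def from_imputer(cls, imputer: GenotypeImputer) -> "BaseImputerSpec":
        if isinstance(imputer, KNNGenotypeImputer):
            return cls("knn", imputer.window_typed_markers, imputer.k_neighbors)
        if isinstance(imputer, MajorityImputer):
            return cls("majority", None, None)
        if isinstance(imputer, ExternalCommandImputer):
            return cls("external", None, None, imputer.command_template)
        raise TypeError(f"unsupported imputer type {type(imputer).__name__}")

    @classmethod
    def from_mapping(cls, d: dict) -> "BaseImputerSpec":
        kind = d.get("imputer_kind", "knn")
        if kind == "knn":
            return cls(
                "knn",
                int(d.get("window_typed_markers", 11)),
                int(d.get("k_neighbors", 5)),
            )
        if kind == "majority":
            return cls("majority", None, None)
        return cls("external", None, None, d.get("external_command_template"))


def _as_imputer(engine) -> GenotypeImputer:
    if isinstance(engine, BaseImputerSpec):
        return engine.build()
    if isinstance(engine, GenotypeImputer):
        return clone(engine)
    raise TypeError("engine must be a GenotypeImputer or BaseImputerSpec")


def impute(engine, reference: GenotypeMatrix, study: GenotypeMatrix) -> GenotypeMatrix:
    """Fit a fresh copy of ``engine`` on the reference and fill the study matrix."""
    return _as_imputer(engine).fit(reference).transform(study)


def knn_impute_call(
    study_sample: np.ndarray,
    typed_panel: MarkerPanel,
    reference: GenotypeMatrix,
    target_marker: Marker,
    window_typed_markers: int = 11,
    k_neighbors: int = 5,
) -> int:
    """Impute a single genotype call for one study sample.

    ``study_sample`` is the sample's dosage vector aligned to ``typed_panel``.
    """
    if target_marker.id in typed_panel:
        raise ValueError(f"target marker {target_marker.id} is already typed")
    sub_ids = list(typed_panel.ids) + [target_marker.id]
    ref_sub = reference.restrict_markers(sub_ids)
    calls = np.full((1, len(ref_sub.panel)), MISSING, dtype=np.int8)
    for val, mid in zip(study_sample, typed_panel.ids):
        calls[0, ref_sub.panel.index(mid)] = val
    study = GenotypeMatrix(("query",), ref_sub.panel, calls)
    est = KNNGenotypeImputer(window_typed_markers, k_neighbors).fit(ref_sub)
    return int(est.transform(study).column(target_marker.id)[0])


def one_step(
    engine,
    reference: GenotypeMatrix,
    study: GenotypeMatrix,
    truth: Optional[GenotypeMatrix] = None,
) -> Tuple[GenotypeMatrix, Optional[AccuracyReport]]:
    """Direct imputation from the typed set T to the full reference panel.

    The untyped set U is the reference panel minus the study's typed markers.
    When ``truth`` is supplied, the returned report is the one-step accuracy
    acc1 evaluated over U only (NaN overall when U is empty).
    """
    typed = typed_ids_of(study, reference.panel)
    typed_set = set(typed)
    untyped = [i for i in reference.panel.ids if i not in typed_set]
    study_full = study.copy() if study.panel == reference.panel else expand_to_panel(
        study, reference.panel
    )
    if not untyped:
        report = AccuracyReport(float("nan"), {}, 0, 0) if truth is not None else None
        return study_full, report
    imputed = impute(engine, reference, study_full)
    report = None
    if truth is not None:
        report = evaluate_accuracy(imputed, truth, reference.panel.restrict(untyped))
    return imputed, report
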
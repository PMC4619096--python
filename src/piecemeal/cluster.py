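"""Marker clustering, target clusters, pseudo-array selection and training.

Markers of U with similar feature vectors have interchangeable imputation
potential, so k-means groups them and one representative per cluster joins
the intermediate pseudo-array.  For each cluster C_i, the *target cluster*
TC_i collects the untyped markers whose cluster-average add-one accuracy
meets the one-step baseline acc1 — the tract that cluster's representative
will impute.  The representative ("top contribution marker") is the cluster
member with the highest mean add-one accuracy over TC_i.

Training runs the whole procedure inside a cross validation: feature
matrices are built per fold and averaged; candidate cluster counts k are
swept and the model with the best fold-averaged piecemeal accuracy wins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .features import (
    FeatureMatrix,
    average_fold_features,
    build_feature_matrix,
    make_cv_folds,
)
from .genotypes import GenotypeMatrix, evaluate_accuracy, mask_to_panel
from .imputers import BaseImputerSpec, GenotypeImputer, _as_imputer
from .markers import Marker, MarkerPanel

THRESHOLD_MODES = ("global_acc1", "per_marker")


@dataclass
class MarkerClustering:
    """Assignment of every untyped marker to one of k clusters."""

    cluster_of_marker: Dict[str, int]
    k: int

    def __post_init__(self):
        bad = {m: c for m, c in self.cluster_of_marker.items() if not 0 <= c < self.k}
        if bad:
            raise ValueError(f"cluster indices out of range: {bad}")

    def members(self, cluster: int) -> List[str]:
        return [m for m, c in self.cluster_of_marker.items() if c == cluster]

    def sizes(self) -> List[int]:
        counts = [0] * self.k
        for c in self.cluster_of_marker.values():
            counts[c] += 1
        return counts

    def non_empty(self) -> List[int]:
        return [i for i, n in enumerate(self.sizes()) if n > 0]


def filled_feature_values(features: FeatureMatrix) -> np.ndarray:
    """Feature values with undefined entries imputed as column means.

    Used for distance computations (clustering, Davies-Bouldin) only; the
    threshold and contribution means never see imputed entries.  A column
    undefined everywhere becomes a constant 0 column, which cannot affect
    relative distances.
    """
    X = features.values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_means = np.nanmean(X, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_means[nan_c]
    return X


def kmeans_cluster(
    features: FeatureMatrix,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> MarkerClustering:
    """Lloyd's k-means with k-means++ seeding, best of ``n_restarts`` by WCSS."""
    n = features.n_markers
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be between 1 and |U|={n}")
    X = filled_feature_values(features)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    return MarkerClustering(
        {m: int(lab) for m, lab in zip(features.marker_ids, km.labels_)}, k
    )


def davies_bouldin(features: FeatureMatrix, clustering: MarkerClustering) -> float:
    """Davies-Bouldin index of a marker clustering; lower is better.

    DB = (1/k) * sum_i max_{j != i} (s_i + s_j) / d_ij with s_i the mean
    member-to-centroid distance and d_ij the centroid distance.  Empty
    clusters are excluded with a warning; fewer than two non-empty clusters
    is an error.
    """
    X = filled_feature_values(features)
    idx = {m: i for i, m in enumerate(features.marker_ids)}
    members = [
        np.array([idx[m] for m in clustering.members(c)], dtype=int)
        for c in range(clustering.k)
    ]
    non_empty = [c for c in range(clustering.k) if members[c].size > 0]
    if len(non_empty) < clustering.k:
        warnings.warn(
            f"{clustering.k - len(non_empty)} empty cluster(s) excluded from "
            "the Davies-Bouldin index"
        )
    if len(non_empty) < 2:
        raise ValueError("Davies-Bouldin index needs at least 2 non-empty clusters")
    centroids = np.stack([X[members[c]].mean(axis=0) for c in non_empty])
    spreads = np.array(
        [
            np.linalg.norm(X[members[c]] - centroids[i], axis=1).mean()
            for i, c in enumerate(non_empty)
        ]
    )
    total = 0.0
    for i in range(len(non_empty)):
        ratios = []
        for j in range(len(non_empty)):
            if i == j:
                continue
            d = np.linalg.norm(centroids[i] - centroids[j])
            with np.errstate(divide="ignore"):
                ratios.append((spreads[i] + spreads[j]) / d if d > 0 else np.inf)
        total += max(ratios)
    return float(total / len(non_empty))


def sweep_k(
    features: FeatureMatrix,
    k_grid: Sequence[int],
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> Dict[int, Tuple[MarkerClustering, float]]:
    """Independent k-means runs across a grid of cluster counts.

    Each k gets its own derived seed (``seed + k``).  The Davies-Bouldin
    score is reported as a diagnostic (NaN where undefined); the caller may
    pick k by it or by downstream piecemeal accuracy.
    """
    out: Dict[int, Tuple[MarkerClustering, float]] = {}
    for k in k_grid:
        clustering = kmeans_cluster(features, int(k), seed=seed + int(k), n_restarts=n_restarts,
                                    max_iter=max_iter)
        try:
            db = davies_bouldin(features, clustering)
        except ValueError:
            db = float("nan")
        out[int(k)] = (clustering, db)
    return out


def _threshold_vector(features: FeatureMatrix, mode: str) -> np.ndarray:
    if mode == "global_acc1":
        return np.full(features.n_markers, features.acc1_overall)
    if mode == "per_marker":
        return features.acc1_per_marker.copy()
    raise ValueError(f"unknown threshold mode {mode!r}; choose from {THRESHOLD_MODES}")


def target_clusters(
    features: FeatureMatrix,
    clustering: MarkerClustering,
    mode: str = "global_acc1",
) -> Dict[int, FrozenSet[str]]:
    """Untyped markers each cluster imputes at least as well as one-step.

    m_j enters TC_i iff the mean of a_ij over the members m_i of C_i
    (defined entries only) reaches the threshold: the overall one-step
    accuracy acc1 in ``global_acc1`` mode, or m_j's own one-step accuracy in
    ``per_marker`` mode.  Target clusters may overlap across i and may leave
    part of U uncovered.
    """
    thr = _threshold_vector(features, mode)
    ids = np.array(features.marker_ids, dtype=object)
    targets: Dict[int, FrozenSet[str]] = {}
    for c in range(clustering.k):
        rows = [features.index(m) for m in clustering.members(c)]
        if not rows:
            targets[c] = frozenset()
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            col_mean = np.nanmean(features.values[rows], axis=0)
        ok = ~np.isnan(col_mean) & ~np.isnan(thr) & (col_mean >= thr)
        targets[c] = frozenset(ids[ok])
    return targets


def select_markers(
    features: FeatureMatrix,
    clustering: MarkerClustering,
    targets: Dict[int, FrozenSet[str]],
) -> Dict[int, Optional[str]]:
    """Top-contribution marker per cluster (None when the tract is empty).

    A member's contribution is its mean add-one accuracy over the cluster's
    target markers (defined entries only); the argmax wins, ties broken by
    genomic order.  Feature-matrix marker order is genomic panel order, so
    iterating members in that order makes "first strict improvement wins"
    the genomic tie-break.
    """
    selected: Dict[int, Optional[str]] = {}
    for c in range(clustering.k):
        tc = targets.get(c, frozenset())
        members = sorted(clustering.members(c), key=features.index)
        if not tc or not members:
            selected[c] = None
            continue
        tcols = [features.index(t) for t in tc]
        best, best_score = None, -np.inf
        for mid in members:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                score = np.nanmean(features.values[features.index(mid), tcols])
            if not np.isnan(score) and score > best_score:
                best, best_score = mid, score
        # degenerate case: tract non-empty but no member has a defined
        # contribution; fall back to the genomically first member
        selected[c] = best if best is not None else members[0]
    return selected


@dataclass
class PiecemealModel:
    """Trained piecemeal artifact: clusters, tracts, pseudo-array and baseline."""

    typed_panel: MarkerPanel
    untyped_ids: tuple
    clustering: MarkerClustering
    target_clusters: Dict[int, FrozenSet[str]]
    selected_marker: Dict[int, Optional[str]]
    acc1_overall: float
    threshold_mode: str
    base_spec: BaseImputerSpec
    training_sample_ids: tuple = ()
    db_score: float = float("nan")

    def __post_init__(self):
        self.untyped_ids = tuple(self.untyped_ids)
        self.training_sample_ids = tuple(self.training_sample_ids)
        untyped = set(self.untyped_ids)
        if set(self.clustering.cluster_of_marker) != untyped:
            raise ValueError("clustering must cover exactly the untyped markers")
        for c in range(self.clustering.k):
            tc = self.target_clusters.get(c, frozenset())
            sel = self.selected_marker.get(c)
            if not tc - untyped == set():
                raise ValueError(f"target cluster {c} contains unknown markers")
            if (sel is None) != (len(tc) == 0):
                raise ValueError(
                    f"cluster {c}: a marker is selected iff the target cluster is non-empty"
                )
            if sel is not None and self.clustering.cluster_of_marker.get(sel) != c:
                raise ValueError(f"selected marker {sel} is not a member of cluster {c}")
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")

    @property
    def covered_ids(self) -> tuple:
        covered = set().union(*self.target_clusters.values()) if self.target_clusters else set()
        return tuple(m for m in self.untyped_ids if m in covered)

    @property
    def uncovered_ids(self) -> tuple:
        covered = set(self.covered_ids)
        return tuple(m for m in self.untyped_ids if m not in covered)

    @property
    def pseudo_array_ids(self) -> tuple:
        """Typed markers plus the selected markers M — the intermediate pseudo-array."""
        extra = sorted(
            {m for m in self.selected_marker.values() if m is not None},
            key=self.untyped_ids.index,
        )
        return self.typed_panel.ids + tuple(extra)

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format": "piecemeal-model",
            "version": 1,
            "typed_panel": [
                {"id": m.id, "chrom": m.chrom, "pos": m.pos, "ref": m.ref_allele,
                 "alt": m.alt_allele}
                for m in self.typed_panel
            ],
            "untyped_ids": list(self.untyped_ids),
            "k": self.clustering.k,
            "cluster_of_marker": dict(self.clustering.cluster_of_marker),
            "target_clusters": {str(c): sorted(tc) for c, tc in self.target_clusters.items()},
            "selected_marker": {str(c): m for c, m in self.selected_marker.items()},
            "acc1_overall": self.acc1_overall,
            "threshold_mode": self.threshold_mode,
            "base_spec": {
                "kind": self.base_spec.kind,
                "window_typed_markers": self.base_spec.window_typed_markers,
                "k_neighbors": self.base_spec.k_neighbors,
                "external_command_template": self.base_spec.external_command_template,
            },
            "training_sample_ids": list(self.training_sample_ids),
            "db_score": None if np.isnan(self.db_score) else self.db_score,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "PiecemealModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "piecemeal-model":
            raise ValueError(f"{path} is not a piecemeal model file")
        panel = MarkerPanel(
            Marker(m["id"], m["chrom"], int(m["pos"]), m["ref"], m["alt"])
            for m in payload["typed_panel"]
        )
        clustering = MarkerClustering(
            {m: int(c) for m, c in payload["cluster_of_marker"].items()}, int(payload["k"])
        )
        spec = payload["base_spec"]
        base_spec = BaseImputerSpec(
            spec["kind"],
            spec["window_typed_markers"],
            spec["k_neighbors"],
            spec["external_command_template"],
        )
        db = payload.get("db_score")
        return cls(
            typed_panel=panel,
            untyped_ids=tuple(payload["untyped_ids"]),
            clustering=clustering,
            target_clusters={int(c): frozenset(tc) for c, tc in payload["target_clusters"].items()},
            selected_marker={int(c): m for c, m in payload["selected_marker"].items()},
            acc1_overall=float(payload["acc1_overall"]),
            threshold_mode=payload["threshold_mode"],
            base_spec=base_spec,
            training_sample_ids=tuple(payload["training_sample_ids"]),
            db_score=float("nan") if db is None else float(db),
        )

    def diagnostics_tsv(self, path) -> None:
        """Cluster-level diagnostics: size, selected marker, tract size, baseline."""
        import pandas as pd

        rows = []
        for c in range(self.clustering.k):
            rows.append(
                {
                    "cluster": c,
                    "size": len(self.clustering.members(c)),
                    "selected_marker": self.selected_marker.get(c) or "NONE",
                    "n_targets": len(self.target_clusters.get(c, frozenset())),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_model(
    features: FeatureMatrix,
    typed_panel: MarkerPanel,
    k: int,
    base_spec: BaseImputerSpec,
    seed: int = 0,
    threshold_mode: str = "global_acc1",
    n_restarts: int = 10,
    max_iter: int = 300,
    training_sample_ids: tuple = (),
) -> PiecemealModel:
    """Cluster, form tracts and select the pseudo-array for a single k."""
    clustering = kmeans_cluster(features, k, seed=seed, n_restarts=n_restarts, max_iter=max_iter)
    targets = target_clusters(features, clustering, threshold_mode)
    selected = select_markers(features, clustering, targets)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            db = davies_bouldin(features, clustering)
    except ValueError:
        db = float("nan")
    return PiecemealModel(
        typed_panel=typed_panel,
        untyped_ids=features.marker_ids,
        clustering=clustering,
        target_clusters=targets,
        selected_marker=selected,
        acc1_overall=features.acc1_overall,
        threshold_mode=threshold_mode,
        base_spec=base_spec,
        training_sample_ids=training_sample_ids,
        db_score=db,
    )


def train_piecemeal(
    engine,
    genotypes: GenotypeMatrix,
    typed_panel: MarkerPanel,
    k_grid: Sequence[int] = (5, 10, 15, 20, 25, 30),
    n_folds: int = 5,
    seed: int = 0,
    threshold_mode: str = "global_acc1",
    strata: Optional[Dict[str, str]] = None,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> Tuple[PiecemealModel, float]:
    """Cross-validated training of a piecemeal model.

    Per fold, the study fold is masked to the typed panel and a feature
    matrix is built against the remaining folds; feature matrices are
    averaged entrywise.  For every candidate k the clustering, tracts and
    pseudo-array are derived from the averaged features and scored by the
    fold-averaged piecemeal accuracy; the best-scoring model (smallest k on
    ties) is returned together with its CV accuracy.
    """
    from .pipeline import piecemeal_impute  # deferred: avoids an import cycle

    base = _as_imputer(engine)
    base_spec = BaseImputerSpec.from_imputer(base)
    typed_set = set(typed_panel.ids)
    if not typed_set <= set(genotypes.panel.ids):
        raise ValueError("typed panel is not a subset of the genotype panel")
    untyped = [i for i in genotypes.panel.ids if i not in typed_set]
    if not untyped:
        raise ValueError("no untyped markers to train on")
    folds = make_cv_folds(genotypes.sample_ids, n_folds, seed=seed, strata=strata)
    fold_data = []
    per_fold_features = []
    for f in range(n_folds):
        reference = genotypes.subset_samples(folds.samples_not_in(f))
        truth_f = genotypes.subset_samples(folds.samples_in(f))
        study_f = mask_to_panel(truth_f, typed_panel)
        fm = build_feature_matrix(base, reference, study_f, truth_f, untyped)
        fold_data.append((reference, study_f, truth_f))
        per_fold_features.append(fm)
    features = average_fold_features(per_fold_features)
    u_panel = genotypes.panel.restrict(untyped)
    best_model, best_acc = None, -np.inf
    for k in sorted(int(k) for k in k_grid):
        model_k = build_model(
            features,
            genotypes.panel.restrict(typed_panel.ids),
            k,
            base_spec,
            seed=seed + k,
            threshold_mode=threshold_mode,
            n_restarts=n_restarts,
            max_iter=max_iter,
            training_sample_ids=genotypes.sample_ids,
        )
        fold_accs = []
        for reference, study_f, truth_f in fold_data:
            imputed = piecemeal_impute(model_k, reference, study_f, engine=base)
            fold_accs.append(evaluate_accuracy(imputed, truth_f, u_panel).overall)
        acc_pi = float(np.mean(fold_accs))
        if acc_pi > best_acc:
            best_model, best_acc = model_k, acc_pi
    return best_model, best_acc
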
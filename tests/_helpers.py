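"""Shared test construction helpers (panels, matrices, toy models)."""

from __future__ import annotations

import numpy as np

from piecemeal import (
    BaseImputerSpec,
    FeatureMatrix,
    GenotypeMatrix,
    Marker,
    MarkerClustering,
    MarkerPanel,
    PiecemealModel,
)

_ALLELES = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def make_panel(n, chrom="1", start=100, spacing=100, prefix="m"):
    """A panel of n evenly spaced markers m00, m01, ..."""
    return MarkerPanel(
        Marker(f"{prefix}{i:02d}", chrom, start + i * spacing, *_ALLELES[i % 4])
        for i in range(n)
    )


def make_matrix(calls, panel=None, prefix="s"):
    calls = np.asarray(calls, dtype=np.int8)
    if panel is None:
        panel = make_panel(calls.shape[1])
    samples = tuple(f"{prefix}{i}" for i in range(calls.shape[0]))
    return GenotypeMatrix(samples, panel, calls)


def random_matrix(rng, n_samples, n_markers, missing_rate=0.0, panel=None):
    calls = rng.integers(0, 3, size=(n_samples, n_markers)).astype(np.int8)
    if missing_rate:
        calls[rng.random(calls.shape) < missing_rate] = -1
    return make_matrix(calls, panel=panel)


def all_none_model(reference_panel, typed_panel, k=1, base_spec=None):
    """A model whose every target cluster is empty (pure one-step fallback)."""
    typed = set(typed_panel.ids)
    untyped = tuple(i for i in reference_panel.ids if i not in typed)
    clustering = MarkerClustering({m: 0 for m in untyped}, k=k)
    return PiecemealModel(
        typed_panel=reference_panel.restrict(typed_panel.ids),
        untyped_ids=untyped,
        clustering=clustering,
        target_clusters={c: frozenset() for c in range(k)},
        selected_marker={c: None for c in range(k)},
        acc1_overall=0.5,
        threshold_mode="global_acc1",
        base_spec=base_spec or BaseImputerSpec("knn", 5, 3),
    )


def feature_matrix_from(values, marker_ids=None, acc1_overall=0.8, acc1_per_marker=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if marker_ids is None:
        marker_ids = tuple(f"m{i:02d}" for i in range(n))
    if acc1_per_marker is None:
        acc1_per_marker = np.full(n, acc1_overall)
    return FeatureMatrix(tuple(marker_ids), values, acc1_per_marker, acc1_overall)
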
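"""SNP marker and panel domain types.

A :class:`Marker` is a biallelic SNP identified by id and by its 1-based
physical locus ``(chrom, pos)``.  A :class:`MarkerPanel` is an ordered,
genomically sorted set of markers (a "chip"); a :class:`PanelHierarchy` is a
nested series of panels of increasing density, the scaffolding on which
staircase imputation runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with 1-based physical coordinates."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("marker id must be non-empty")
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: position must be >= 1, got {self.pos}")
        for name in ("ref_allele", "alt_allele"):
            allele = getattr(self, name)
            if allele not in _NUCLEOTIDES:
                raise ValueError(
                    f"marker {self.id}: {name} must be a single nucleotide A/C/G/T, got {allele!r}"
                )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"marker {self.id}: ref and alt alleles must differ")

    @property
    def alleles(self) -> frozenset:
        """Unordered {ref, alt} pair, used for cross-panel allele-consistency checks."""
        return frozenset((self.ref_allele, self.alt_allele))

    @property
    def locus(self) -> tuple:
        return (self.chrom, self.pos)


class MarkerPanel(Sequence):
    """An ordered set of markers, sorted by (chrom, pos), with unique ids and loci.

    Chromosomes are ordered lexicographically by their string name, positions
    numerically within a chromosome.
    """

    def __init__(self, markers: Iterable[Marker]):
        self._markers = tuple(markers)
        loci = [m.locus for m in self._markers]
        for a, b in zip(loci, loci[1:]):
            if a >= b:
                raise ValueError(
                    f"panel markers must be strictly sorted by (chrom, pos); "
                    f"found {a} before {b}"
                )
        ids = [m.id for m in self._markers]
        if len(set(ids)) != len(ids):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValueError(f"duplicate marker ids in panel: {sorted(dups)}")
        self._index = {m.id: i for i, m in enumerate(self._markers)}

    @classmethod
    def from_unsorted(cls, markers: Iterable[Marker]) -> "MarkerPanel":
        return cls(sorted(markers, key=lambda m: m.locus))

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._markers)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return MarkerPanel(self._markers[i])
        return self._markers[i]

    def __iter__(self) -> Iterator[Marker]:
        return iter(self._markers)

    def __contains__(self, item) -> bool:
        if isinstance(item, Marker):
            return item.id in self._index
        return item in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, MarkerPanel) and self._markers == other._markers

    def __hash__(self):
        return hash(self._markers)

    def __repr__(self) -> str:
        return f"MarkerPanel(n={len(self)})"

    # -- lookups ------------------------------------------------------------
    @property
    def ids(self) -> tuple:
        return tuple(m.id for m in self._markers)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.pos for m in self._markers], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([m.chrom for m in self._markers], dtype=object)

    def index(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not in panel") from None

    def get(self, marker_id: str) -> Marker:
        return self._markers[self.index(marker_id)]

    def restrict(self, marker_ids: Iterable[str]) -> "MarkerPanel":
        """Sub-panel of the given markers, preserving this panel's genomic order."""
        wanted = set(marker_ids)
        unknown = wanted - set(self._index)
        if unknown:
            raise KeyError(f"markers not in panel: {sorted(unknown)}")
        return MarkerPanel(m for m in self._markers if m.id in wanted)

    def issubset(self, other: "MarkerPanel") -> bool:
        return set(self.ids) <= set(other.ids)

    # -- I/O (sidecar panel TSV: id, chrom, pos, ref, alt) -------------------
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "id": [m.id for m in self._markers],
                "chrom": [m.chrom for m in self._markers],
                "pos": [m.pos for m in self._markers],
                "ref": [m.ref_allele for m in self._markers],
                "alt": [m.alt_allele for m in self._markers],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
        required = {"id", "chrom", "pos", "ref", "alt"}
        if not required <= set(df.columns):
            raise ValueError(f"panel file {path} must have columns {sorted(required)}")
        markers = [
            Marker(r.id, r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)
        ]
        return cls(markers)


class PanelHierarchy:
    """Nested density tiers, from lowest to highest density.

    Each tier must be a strict subset (by marker id) of the next.  A single
    tier is permitted as the degenerate base case.
    """

    def __init__(self, tiers: Sequence[MarkerPanel]):
        tiers = tuple(tiers)
        if len(tiers) < 1:
            raise ValueError("hierarchy needs at least one tier")
        for lo, hi in zip(tiers, tiers[1:]):
            lo_ids, hi_ids = set(lo.ids), set(hi.ids)
            if not (lo_ids < hi_ids):
                raise ValueError(
                    "each tier must be a strict subset of the next "
                    f"(sizes {len(lo)} vs {len(hi)})"
                )
        self.tiers = tiers

    def __len__(self) -> int:
        return len(self.tiers)

    def __getitem__(self, i) -> MarkerPanel:
        return self.tiers[i]

    def __iter__(self):
        return iter(self.tiers)

    @property
    def bottom(self) -> MarkerPanel:
        return self.tiers[0]

    @property
    def top(self) -> MarkerPanel:
        return self.tiers[-1]
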
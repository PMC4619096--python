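"""Synthetic populations with identical-by-descent haplotype sharing.

Every individual carries two haplotypes, each a mosaic of a small founder
haplotype pool: walking along the chromosome, the founder index is redrawn
uniformly with a per-interval probability (a recombination analogue).  A
finite founder pool shared between reference and study individuals is what
creates the linkage disequilibrium that population-based imputation
exploits; the model is agnostic to how that LD arose in real data.

Genotype error is applied per call: with the configured probability a call is
replaced by one of the other two dosages uniformly.  Nested density tiers
mimicking commercial-chip hierarchies (e.g. 6K within 50K within HD) are cut
from the simulated panel with :func:`build_panel_hierarchy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import yaml

from .genotypes import GenotypeMatrix
from .markers import Marker, MarkerPanel, PanelHierarchy

_ACGT = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the mosaic-of-founders population model.

    Defaults define the package's standard synthetic benchmark: a small
    founder pool (strong haplotype sharing), 60 reference and 20 study
    diploids, 300 markers on one chromosome with density tiers 20/80/300,
    2% per-interval recombination and 1% genotype error.
    """

    n_founder_haplotypes: int = 4
    n_reference: int = 60
    n_study: int = 20
    n_markers: int = 300
    chrom_length: int = 1_000_000
    recomb_prob_per_interval: float = 0.02
    error_rate: float = 0.01
    maf_min: float = 0.1
    tier_sizes: tuple = (20, 80, 300)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "tier_sizes", tuple(int(t) for t in self.tier_sizes))
        if self.n_founder_haplotypes < 2:
            raise ValueError("need at least 2 founder haplotypes")
        if any(b <= a for a, b in zip(self.tier_sizes, self.tier_sizes[1:])):
            raise ValueError("tier_sizes must be strictly increasing")
        if self.tier_sizes and self.tier_sizes[-1] > self.n_markers:
            raise ValueError("largest tier exceeds n_markers")
        if self.n_markers > self.chrom_length:
            raise ValueError("more markers than base pairs")
        if not 0.0 <= self.recomb_prob_per_interval <= 1.0:
            raise ValueError("recomb_prob_per_interval must be in [0,1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0,1]")
        if not 0.0 < self.maf_min <= 0.5:
            raise ValueError("maf_min must be in (0, 0.5]")
        # the founder pool must admit an allele count with MAF >= maf_min
        lo = int(np.ceil(self.maf_min * self.n_founder_haplotypes))
        hi = int(np.floor((1 - self.maf_min) * self.n_founder_haplotypes))
        if lo > hi:
            raise ValueError(
                f"maf_min={self.maf_min} unattainable with "
                f"{self.n_founder_haplotypes} founder haplotypes"
            )

    @classmethod
    def from_mapping(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


def load_sim_config(path) -> SimConfig:
    """Read a flat key-value YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig.from_mapping(data)


@dataclass
class SimResult:
    """Full simulation output, including the latent founder pool."""

    founders: np.ndarray  # (n_founder_haplotypes, n_markers) 0/1 alleles
    panel: MarkerPanel
    reference: GenotypeMatrix
    study_truth: GenotypeMatrix


def simulate_details(cfg: SimConfig) -> SimResult:
    """Run the full simulation, exposing the founder haplotypes for inspection."""
    rng = np.random.default_rng(cfg.seed)
    panel = _draw_panel(cfg, rng)
    founders = _draw_founders(cfg, rng)
    n_total = cfg.n_reference + cfg.n_study
    genotypes = _draw_individuals(cfg, rng, founders, n_total)
    genotypes = _apply_errors(cfg, rng, genotypes)
    ref_ids = tuple(f"ref{i:04d}" for i in range(cfg.n_reference))
    stu_ids = tuple(f"study{i:04d}" for i in range(cfg.n_study))
    reference = GenotypeMatrix(ref_ids, panel, genotypes[: cfg.n_reference])
    study_truth = GenotypeMatrix(stu_ids, panel, genotypes[cfg.n_reference :])
    return SimResult(founders, panel, reference, study_truth)


def simulate_truth(cfg: SimConfig) -> Tuple[GenotypeMatrix, GenotypeMatrix, MarkerPanel]:
    """Simulate (reference, study_truth, panel); deterministic for a fixed seed."""
    res = simulate_details(cfg)
    return res.reference, res.study_truth, res.panel


def founder_haplotypes(cfg: SimConfig) -> np.ndarray:
    """The founder haplotype pool the simulation for ``cfg`` draws from."""
    return simulate_details(cfg).founders


def _draw_panel(cfg: SimConfig, rng: np.random.Generator) -> MarkerPanel:
    positions = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_markers, replace=False)) + 1
    markers = []
    for i, pos in enumerate(positions):
        ref, alt = rng.choice(4, size=2, replace=False)
        markers.append(Marker(f"snp{i:05d}", "1", int(pos), str(_ACGT[ref]), str(_ACGT[alt])))
    return MarkerPanel(markers)


def _draw_founders(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Founder alleles with per-marker empirical MAF >= maf_min.

    A target frequency is drawn uniformly on [maf_min, 1 - maf_min]; the
    founder allele count is binomial at that frequency, clipped into the
    feasible MAF band, and alleles are placed by random permutation.
    """
    F = cfg.n_founder_haplotypes
    lo = int(np.ceil(cfg.maf_min * F))
    hi = int(np.floor((1 - cfg.maf_min) * F))
    founders = np.zeros((F, cfg.n_markers), dtype=np.int8)
    for j in range(cfg.n_markers):
        p = rng.uniform(cfg.maf_min, 1 - cfg.maf_min)
        count = int(np.clip(rng.binomial(F, p), lo, hi))
        carriers = rng.permutation(F)[:count]
        founders[carriers, j] = 1
    return founders


def _draw_individuals(
    cfg: SimConfig, rng: np.random.Generator, founders: np.ndarray, n_individuals: int
) -> np.ndarray:
    F, n_markers = founders.shape
    genotypes = np.zeros((n_individuals, n_markers), dtype=np.int8)
    for ind in range(n_individuals):
        dosage = np.zeros(n_markers, dtype=np.int8)
        for _hap in range(2):
            draws = rng.integers(F, size=n_markers)
            if n_markers > 1:
                switch = rng.random(n_markers - 1) < cfg.recomb_prob_per_interval
            else:
                switch = np.zeros(0, dtype=bool)
            segment = np.concatenate(([0], np.cumsum(switch)))
            founder_path = draws[segment]
            dosage += founders[founder_path, np.arange(n_markers)]
        genotypes[ind] = dosage
    return genotypes


def _apply_errors(cfg: SimConfig, rng: np.random.Generator, genotypes: np.ndarray) -> np.ndarray:
    if cfg.error_rate == 0:
        return genotypes
    flip = rng.random(genotypes.shape) < cfg.error_rate
    # replace each flagged call by one of the other two dosages, uniformly
    offset = rng.integers(1, 3, size=genotypes.shape)
    perturbed = (genotypes + offset) % 3
    return np.where(flip, perturbed, genotypes).astype(np.int8)


def build_panel_hierarchy(
    panel: MarkerPanel,
    tier_sizes,
    scheme: str = "uniform_spacing",
    seed: int = 0,
) -> PanelHierarchy:
    """Cut nested density tiers from a panel.

    ``uniform_spacing`` picks evenly indexed markers within the next-denser
    tier; ``random`` samples without replacement (seeded).  The highest tier
    is the panel itself.
    """
    tier_sizes = tuple(int(t) for t in tier_sizes)
    if any(b <= a for a, b in zip(tier_sizes, tier_sizes[1:])):
        raise ValueError("tier_sizes must be strictly increasing")
    if not tier_sizes or tier_sizes[-1] > len(panel):
        raise ValueError("largest tier must be <= panel size (and at least one tier given)")
    rng = np.random.default_rng(seed)
    if tier_sizes[-1] != len(panel):
        tier_sizes = tier_sizes + (len(panel),)
    tiers = [panel]
    for size in reversed(tier_sizes[:-1]):
        parent = tiers[0]
        n = len(parent)
        if scheme == "uniform_spacing":
            idx = np.round(np.linspace(0, n - 1, size)).astype(int)
        elif scheme == "random":
            idx = np.sort(rng.choice(n, size=size, replace=False))
        else:
            raise ValueError(f"unknown tier scheme {scheme!r}")
        tiers.insert(0, MarkerPanel(parent[int(i)] for i in idx))
    return PanelHierarchy(tiers)
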
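"""Synthetic multi-allelic haplotype panels with tunable LD structure.

The generator follows a minimal haplotype-copying model: a handful of
founder haplotypes are drawn site-by-site from per-site allele
frequencies, and every subsequent haplotype is mosaic-copied from the
haplotypes generated before it in blocks of geometric length, with a
small per-site mutation rate.  Finite block lengths induce correlation
between nearby sites (linkage disequilibrium); ``block_length = 1``
re-picks the template at every site and leaves adjacent sites essentially
uncorrelated.

Multi-allelic structure is added afterwards by :func:`multiallelify`,
which mirrors the standard benchmark construction for multi-allelic
haplotype tools: start from a bi-allelic panel and, at a fraction of
sites (30% by default), re-assign the carriers of one of the two alleles
to codes drawn from a larger alphabet.
"""

from __future__ import annotations

import dataclasses
from typing import Tuple

import numpy as np

from .errors import ParameterError
from .panel_io import HaplotypePanel

__all__ = ["SimulationConfig", "simulate_panel", "multiallelify", "simulate_multiallelic_panel"]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the copying-model simulator.

    Defaults are desk-scale: large enough to show LD-driven
    compressibility and match structure, small enough that brute-force
    oracles remain usable.

    M, N
        Haplotype and site counts.
    base_maf
        Range the per-site minor allele frequency of the bi-allelic base
        panel is drawn from (uniformly).
    block_length
        Mean length, in sites, of the geometric copying blocks; larger
        means stronger LD and longer shared segments.
    mutation_rate
        Per-site probability of flipping the copied allele.
    convert_fraction, target_t
        Fraction of sites converted to ``target_t``-allelic after the
        bi-allelic base panel is built (0 keeps the panel bi-allelic).
    seed
        Seed for all randomness; the same config yields the same panel.
    """

    M: int = 200
    N: int = 500
    base_maf: Tuple[float, float] = (0.05, 0.5)
    block_length: float = 20.0
    mutation_rate: float = 0.01
    convert_fraction: float = 0.0
    target_t: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.M < 1 or self.N < 0:
            raise ParameterError("M must be >= 1 and N >= 0")
        lo, hi = self.base_maf
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("base_maf must satisfy 0 < lo <= hi <= 0.5")
        if self.block_length < 1.0:
            raise ParameterError("block_length must be >= 1")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ParameterError("mutation_rate must be in [0, 1)")
        if not 0.0 <= self.convert_fraction <= 1.0:
            raise ParameterError("convert_fraction must be in [0, 1]")
        if self.target_t < 2:
            raise ParameterError("target_t must be >= 2")


def simulate_panel(config: SimulationConfig) -> HaplotypePanel:
    """Generate the bi-allelic copying-model panel (no conversion step)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    M, N = config.M, config.N
    if N == 0:
        return HaplotypePanel(
            alleles=np.zeros((M, 0), dtype=np.int32),
            site_alphabet_sizes=np.zeros(0, dtype=np.int32),
        )
    freqs = rng.uniform(config.base_maf[0], config.base_maf[1], size=N)
    X = np.zeros((M, N), dtype=np.int32)
    n_founders = min(M, 4)
    X[:n_founders] = (rng.random((n_founders, N)) < freqs).astype(np.int32)
    p_switch = 1.0 / config.block_length
    for i in range(n_founders, M):
        # geometric-block mosaic of the previously generated haplotypes
        switches = rng.random(N) < p_switch
        switches[0] = True
        starts = np.nonzero(switches)[0]
        templates = rng.integers(0, i, size=starts.size)
        tmpl_per_site = np.repeat(
            templates, np.diff(np.append(starts, N))
        )
        X[i] = X[tmpl_per_site, np.arange(N)]
        if config.mutation_rate > 0.0:
            flips = rng.random(N) < config.mutation_rate
            X[i, flips] = 1 - X[i, flips]
    sizes = np.full(N, 2, dtype=np.int32)
    return HaplotypePanel(alleles=X, site_alphabet_sizes=sizes)


def multiallelify(
    panel: HaplotypePanel, fraction: float, target_t: int, seed: int = 0
) -> HaplotypePanel:
    """Convert a fraction of a bi-allelic panel's sites to t-allelic.

    At ``ceil(fraction * N)`` seeded-random sites, one of the two alleles
    is chosen and its carriers are re-assigned codes drawn uniformly from
    ``{0..target_t-1}``; the site's alphabet becomes ``target_t``.  Other
    sites are untouched.  Which allele is split, and the new codes, are
    uniform random under the seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError("fraction must be in [0, 1]")
    if target_t < 2:
        raise ParameterError("target_t must be >= 2")
    if panel.N and panel.site_alphabet_sizes.max() > 2:
        raise ParameterError("multiallelify expects a bi-allelic input panel")
    rng = np.random.default_rng(seed)
    X = panel.alleles.copy()
    sizes = panel.site_alphabet_sizes.copy()
    n_convert = int(np.ceil(fraction * panel.N))
    if n_convert == 0:
        return HaplotypePanel(
            alleles=X,
            site_alphabet_sizes=sizes,
            site_ids=panel.site_ids,
            sample_ids=panel.sample_ids,
        )
    sites = rng.choice(panel.N, size=n_convert, replace=False)
    for k in np.sort(sites):
        split_allele = int(rng.integers(0, 2))
        carriers = np.nonzero(X[:, k] == split_allele)[0]
        X[carriers, k] = rng.integers(0, target_t, size=carriers.size)
        sizes[k] = target_t
    return HaplotypePanel(
        alleles=X,
        site_alphabet_sizes=sizes,
        site_ids=panel.site_ids,
        sample_ids=panel.sample_ids,
    )


def simulate_multiallelic_panel(config: SimulationConfig) -> HaplotypePanel:
    """Full experiment pipeline: copying-model base panel, then conversion."""
    panel = simulate_panel(config)
    if config.convert_fraction == 0.0:
        return panel
    return multiallelify(
        panel,
        fraction=config.convert_fraction,
        target_t=config.target_t,
        seed=config.seed + 1,
    )
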
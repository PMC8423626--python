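"""Single-locus calibration experiments on the Wright-Fisher engine.

These drive the exact reproduction code used by :func:`simulate_panel`
(parent choice, selfing, gamete formation) on a one-locus genome with
standing variation, exposing the engine's drift behaviour for statistical
fidelity checks: neutral-frequency martingale, fixation probability, and
heterozygosity decay under selfing.
"""

from __future__ import annotations

import numpy as np

from .config import GenomeConfig
from .engine import _founder_hap, _reproduce

_LOCUS = 0  # position of the tracked allele


def _locus_genome(selfing_rate: float) -> GenomeConfig:
    return GenomeConfig(n_chromosomes=1, chrom_length_bp=100,
                        mutation_rate=0.0, recombination_rate=0.0,
                        selfing_rate=selfing_rate)


def _init_pop(n_diploid: int, carrier_haplotypes: np.ndarray) -> list:
    """Population of *n_diploid* individuals; haplotype slot 2i+h carries the
    derived allele iff carrier_haplotypes[2i+h]."""
    pop = []
    for i in range(n_diploid):
        ind = []
        for h in (0, 1):
            hap = _founder_hap(1, 100, 0)
            if carrier_haplotypes[2 * i + h]:
                hap[0][0] = np.array([_LOCUS], dtype=np.int64)
            ind.append(hap)
        pop.append(ind)
    return pop


def _freq(pop: list) -> float:
    carriers = sum(int(hap[0][0].size > 0) for ind in pop for hap in ind)
    return carriers / (2 * len(pop))


def _het(pop: list) -> float:
    het = sum(int((ind[0][0][0].size > 0) != (ind[1][0][0].size > 0))
              for ind in pop)
    return het / len(pop)


def neutral_trajectories(n_diploid: int, p0: float, generations: int,
                         n_replicates: int, selfing_rate: float = 0.0,
                         seed: int = 0) -> np.ndarray:
    """Allele-frequency trajectories, shape (n_replicates, generations + 1)."""
    rng = np.random.default_rng(seed)
    genome = _locus_genome(selfing_rate)
    k = round(2 * n_diploid * p0)
    out = np.empty((n_replicates, generations + 1))
    for r in range(n_replicates):
        carriers = np.zeros(2 * n_diploid, dtype=bool)
        carriers[rng.choice(2 * n_diploid, size=k, replace=False)] = True
        pops = {0: _init_pop(n_diploid, carriers)}
        out[r, 0] = _freq(pops[0])
        for g in range(generations):
            pops = {0: _reproduce(pops, 0, selfing_rate, None, rng, genome,
                                  used=[set()], mutate=False)}
            out[r, g + 1] = _freq(pops[0])
    return out


def fixation_outcomes(n_diploid: int, p0: float, n_replicates: int,
                      max_generations: int = 10_000, seed: int = 0
                      ) -> np.ndarray:
    """1.0 where the allele fixed, 0.0 where lost, NaN where unresolved."""
    rng = np.random.default_rng(seed)
    genome = _locus_genome(0.0)
    k = round(2 * n_diploid * p0)
    out = np.full(n_replicates, np.nan)
    for r in range(n_replicates):
        carriers = np.zeros(2 * n_diploid, dtype=bool)
        carriers[rng.choice(2 * n_diploid, size=k, replace=False)] = True
        pops = {0: _init_pop(n_diploid, carriers)}
        for _ in range(max_generations):
            pops = {0: _reproduce(pops, 0, 0.0, None, rng, genome,
                                  used=[set()], mutate=False)}
            f = _freq(pops[0])
            if f in (0.0, 1.0):
                out[r] = f
                break
    return out


def heterozygosity_decay(n_diploid: int, generations: int, n_replicates: int,
                         seed: int = 0) -> np.ndarray:
    """Mean fraction of heterozygous individuals per generation under full
    selfing, starting from an all-heterozygous population; shape
    (generations + 1,)."""
    rng = np.random.default_rng(seed)
    genome = _locus_genome(1.0)
    het = np.zeros((n_replicates, generations + 1))
    for r in range(n_replicates):
        carriers = np.zeros(2 * n_diploid, dtype=bool)
        carriers[0::2] = True  # every individual heterozygous
        pops = {0: _init_pop(n_diploid, carriers)}
        het[r, 0] = _het(pops[0])
        for g in range(generations):
            pops = {0: _reproduce(pops, 0, 1.0, None, rng, genome,
                                  used=[set()], mutate=False)}
            het[r, g + 1] = _het(pops[0])
    return het.mean(axis=0)
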
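"""Shared fixtures: hand-built matrices and small simulated panels."""

from __future__ import annotations

import numpy as np
import pytest

from introscan.popsim import (DemographyConfig, GenomeConfig, NoiseConfig,
                              simulate_panel)
from introscan.variants import MISSING, SamplePanel, VariantMatrix


def matrix_from_haplotypes(H, pos=None, chrom="chr1", samples=None,
                           contigs=None, dp=None, gq=None):
    """VariantMatrix from a (2n, S) phased haplotype array (-1 = missing)."""
    H = np.asarray(H, dtype=np.int8)
    n2, S = H.shape
    assert n2 % 2 == 0
    n = n2 // 2
    pos = np.arange(1, S + 1) if pos is None else np.asarray(pos)
    samples = samples or [f"s{i}" for i in range(n)]
    G = np.where((H[0::2] == MISSING) | (H[1::2] == MISSING), MISSING,
                 H[0::2] + H[1::2]).astype(np.int8)
    chroms = np.full(S, chrom, dtype=object) if np.ndim(chrom) == 0 else np.asarray(chrom, dtype=object)
    return VariantMatrix(samples, chroms, pos, np.full(S, "A", dtype=object),
                         np.full(S, "T", dtype=object), G, dp=dp, gq=gq,
                         haplotypes=H, contigs=contigs)


def matrix_from_genotypes(G, pos=None, chrom="chr1", samples=None,
                          contigs=None, dp=None, gq=None):
    """Unphased VariantMatrix from an (n, S) dosage array (-1 = missing)."""
    G = np.asarray(G, dtype=np.int8)
    n, S = G.shape
    pos = np.arange(1, S + 1) if pos is None else np.asarray(pos)
    samples = samples or [f"s{i}" for i in range(n)]
    chroms = np.full(S, chrom, dtype=object)
    return VariantMatrix(samples, chroms, pos, np.full(S, "A", dtype=object),
                         np.full(S, "T", dtype=object), G, dp=dp, gq=gq,
                         contigs=contigs, phased=False)


def panel_for(m, groups):
    """SamplePanel assigning m.samples round-robin to *groups*."""
    return SamplePanel({s: groups[i % len(groups)]
                        for i, s in enumerate(m.samples)})


@pytest.fixture(scope="session")
def two_deme_panel():
    """Small two-deme panel with an old split: strong differentiation,
    no admixture.  Phased, no noise."""
    dem = DemographyConfig(n_demes=2, deme_sizes=(40, 40),
                           split_events=((400, 0, 1),),
                           sample_counts=(12, 12), group_labels=("A", "B"),
                           burnin_generations=200)
    gen = GenomeConfig(n_chromosomes=2, chrom_length_bp=300_000,
                       mutation_rate=4e-7, recombination_rate=2e-7,
                       selfing_rate=0.0)
    m, panel, truth = simulate_panel(dem, gen, NoiseConfig(missing_rate=0.0),
                                     seed=11)
    return m, panel, truth


@pytest.fixture(scope="session")
def tiny_demo_panel(tmp_path_factory):
    """Miniature analogue of the demo scenario (same group labels G5/OUT/G2/G4
    and a donor pulse) written to disk for pipeline/CLI tests."""
    dem = DemographyConfig(
        n_demes=4, deme_sizes=(80, 20, 15, 60),
        split_events=((300, 0, 1), (100, 0, 2), (50, 0, 3)),
        admixture_pulses=((25, 2, 3, 0.2),),
        sample_counts=(8, 8, 8, 8),
        group_labels=("G5", "OUT", "G2", "G4"),
        burnin_generations=200)
    gen = GenomeConfig(n_chromosomes=2, chrom_length_bp=400_000,
                       mutation_rate=1e-6, recombination_rate=5e-8,
                       selfing_rate=0.5)
    m, panel, truth = simulate_panel(dem, gen, NoiseConfig(missing_rate=0.03),
                                     seed=5)
    panel.role = {s: {"G5": "P1", "G4": "P2", "G2": "P3", "OUT": "outgroup"}[g]
                  for s, g in panel.group.items()}
    d = tmp_path_factory.mktemp("tiny_demo")
    from introscan.variants import write_vcf
    write_vcf(m, d / "sim.vcf")
    panel.write(d / "panel.tsv")
    truth.write(d / "truth.tsv")
    return {"matrix": m, "panel": panel, "truth": truth, "dir": d,
            "vcf": d / "sim.vcf", "panel_path": d / "panel.tsv"}
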
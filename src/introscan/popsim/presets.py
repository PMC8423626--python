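"""Default study conditions for the bundled simulator.

The defaults emulate, at desk scale, a mustard-like resequencing panel: a
selfing crop with a leaf-mustard-like background group (G5), a diverged
yellow-seeded donor group (G2), a recently founded recipient group (G4) that
received a donor admixture pulse 50 generations before sampling, and an
outgroup.  Deme sizes are scaled down (tens of diploids) with per-bp rates
raised so the scaled products theta and rho stay in a regime where the scans
have signal; see docs/methods.md for the reasoning behind each number.
"""

from __future__ import annotations

from .config import DemographyConfig, GenomeConfig, NoiseConfig

# deme indices
SOURCE, OUTGROUP, DONOR, RECIPIENT = 0, 1, 2, 3
GROUPS = ("G5", "OUT", "G2", "G4")


def demo_demography(pulse_proportion: float = 0.15,
                    pulse_generation: int = 50) -> DemographyConfig:
    """Source (G5) root; outgroup splits 1200 gen ago, donor (G2) 250,
    recipient (G4) 120; donor -> recipient pulse at *pulse_generation*.
    ``pulse_proportion=0`` gives the matched no-gene-flow null."""
    pulses = ()
    if pulse_proportion > 0:
        pulses = ((pulse_generation, DONOR, RECIPIENT, pulse_proportion),)
    return DemographyConfig(
        n_demes=4,
        deme_sizes=(150, 50, 20, 250),
        split_events=((1200, SOURCE, OUTGROUP),
                      (250, SOURCE, DONOR),
                      (120, SOURCE, RECIPIENT)),
        admixture_pulses=pulses,
        sample_counts=(20, 20, 20, 20),
        group_labels=GROUPS,
        burnin_generations=500,
    )


def demo_genome() -> GenomeConfig:
    """10 x 1 Mb chromosomes; mu=3e-7, r=2e-8 per bp per generation; selfing
    0.9 (multi-generation self-pollinated accessions); 1-year generations."""
    return GenomeConfig(n_chromosomes=10, chrom_length_bp=1_000_000,
                        mutation_rate=3e-7, recombination_rate=2e-8,
                        selfing_rate=0.9, generation_time_years=1.0)


def demo_noise() -> NoiseConfig:
    """~15x depth, 5% missingness (below the study's 10% ceiling)."""
    return NoiseConfig(missing_rate=0.05, depth_mean=15.0,
                       gq_floor=20, gq_ceiling=99)


def calibration_demography(pulse_proportion: float = 0.0,
                           pulse_generation: int = 10) -> DemographyConfig:
    """Four equal demes for D-statistic calibration and power experiments.

    The rIBD-focused demo scenario funnels every chromosome of its tiny
    donor deme through the same few pedigree ancestors, which correlates
    ABBA-BABA genealogies genome-wide and makes jackknife Z badly scaled no
    matter the block size.  Equal medium demes avoid that pathology; the
    default is the no-gene-flow null, a recent pulse P3 -> P2 gives the
    power counterpart.
    """
    pulses = ()
    if pulse_proportion > 0:
        pulses = ((pulse_generation, 2, 3, pulse_proportion),)
    return DemographyConfig(
        n_demes=4, deme_sizes=(80, 80, 80, 80),
        split_events=((600, 0, 1), (200, 0, 2), (100, 0, 3)),
        admixture_pulses=pulses,
        sample_counts=(20, 20, 20, 20),
        group_labels=("P1", "OUT", "P3", "P2"),
        burnin_generations=200)


def calibration_genome() -> GenomeConfig:
    """10 x 1 Mb with enough recombination that chromosomes carry several
    independent genealogies (rho_chrom ~ 100)."""
    return GenomeConfig(n_chromosomes=10, chrom_length_bp=1_000_000,
                        mutation_rate=2.5e-7, recombination_rate=2e-7,
                        selfing_rate=0.5)


def demo_roles() -> dict[str, str]:
    """Analysis roles for the four-taxon tests: (((G5, G4), G2), OUT)."""
    return {"G5": "P1", "G4": "P2", "G2": "P3", "OUT": "outgroup"}
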
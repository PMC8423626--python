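"""Configuration types for the forward Wright-Fisher simulator.

Generations are counted backwards from sampling: an event at generation ``g``
acts ``g`` meioses before the present-day panel is drawn.  Demes that are
never the child of a split exist from the start of the simulation (the oldest
event plus ``burnin_generations``).
"""

from __future__ import annotations

from dataclasses import dataclass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SplitEvent:
    generation: int
    parent: int
    child: int


@dataclass(frozen=True)
class AdmixturePulse:
    generation: int
    source: int
    recipient: int
    proportion: float


def _as_splits(events) -> tuple[SplitEvent, ...]:
    return tuple(e if isinstance(e, SplitEvent) else SplitEvent(*e) for e in events)


def _as_pulses(events) -> tuple[AdmixturePulse, ...]:
    return tuple(e if isinstance(e, AdmixturePulse) else AdmixturePulse(*e)
                 for e in events)


@dataclass(frozen=True)
class DemographyConfig:
    """Split/admixture demography over ``n_demes`` Wright-Fisher demes.

    ``deme_sizes`` are diploid counts held constant per deme;
    ``sample_counts`` diploids per deme are drawn (without replacement) at the
    present.  ``burnin_generations`` of neutral evolution precede the oldest
    event so root demes start near mutation-drift equilibrium.
    """

    n_demes: int
    deme_sizes: tuple[int, ...]
    split_events: tuple[SplitEvent, ...] = ()
    admixture_pulses: tuple[AdmixturePulse, ...] = ()
    sample_counts: tuple[int, ...] = ()
    group_labels: tuple[str, ...] = ()
    burnin_generations: int = 400

    def __post_init__(self):
        object.__setattr__(self, "deme_sizes", tuple(int(x) for x in self.deme_sizes))
        object.__setattr__(self, "split_events", _as_splits(self.split_events))
        object.__setattr__(self, "admixture_pulses", _as_pulses(self.admixture_pulses))
        object.__setattr__(self, "sample_counts",
                           tuple(int(x) for x in self.sample_counts)
                           or tuple(self.deme_sizes))
        object.__setattr__(self, "group_labels",
                           tuple(self.group_labels)
                           or tuple(f"deme{i}" for i in range(self.n_demes)))
        self.validate()

    # -- derived -----------------------------------------------------------
    def founding_generation(self, deme: int) -> int | None:
        """Generation at which *deme* is founded by a split, None for roots."""
        for ev in self.split_events:
            if ev.child == deme:
                return ev.generation
        return None

    @property
    def root_demes(self) -> tuple[int, ...]:
        children = {ev.child for ev in self.split_events}
        return tuple(d for d in range(self.n_demes) if d not in children)

    @property
    def oldest_event(self) -> int:
        gens = [ev.generation for ev in self.split_events]
        gens += [ev.generation for ev in self.admixture_pulses]
        return max(gens, default=0)

    def validate(self) -> None:
        if self.n_demes < 1:
            raise ConfigurationError("need at least one deme")
        for name in ("deme_sizes", "sample_counts", "group_labels"):
            if len(getattr(self, name)) != self.n_demes:
                raise ConfigurationError(f"{name} must have length n_demes={self.n_demes}")
        if any(n <= 0 for n in self.deme_sizes):
            raise ConfigurationError("deme sizes must be positive")
        for d, (n, s) in enumerate(zip(self.deme_sizes, self.sample_counts)):
            if s < 0 or s > n:
                raise ConfigurationError(f"deme {d}: sampled {s} exceeds size {n}")
        children = [ev.child for ev in self.split_events]
        if len(children) != len(set(children)):
            raise ConfigurationError("a deme may be founded by at most one split")
        for ev in self.split_events:
            if not (0 <= ev.parent < self.n_demes and 0 <= ev.child < self.n_demes):
                raise ConfigurationError(f"split {ev} references unknown deme")
            if ev.parent == ev.child:
                raise ConfigurationError(f"split {ev}: parent equals child")
            if ev.generation <= 0:
                raise ConfigurationError(f"split {ev}: generation must be > 0")
            pg = self.founding_generation(ev.parent)
            if pg is not None and pg <= ev.generation:
                raise ConfigurationError(
                    f"split {ev}: parent deme {ev.parent} does not exist yet "
                    f"(founded at generation {pg})")
        for ev in self.admixture_pulses:
            if not (0 <= ev.source < self.n_demes and 0 <= ev.recipient < self.n_demes):
                raise ConfigurationError(f"pulse {ev} references unknown deme")
            if not 0.0 <= ev.proportion <= 1.0:
                raise ConfigurationError(f"pulse {ev}: proportion outside [0, 1]")
            if ev.generation <= 0:
                raise ConfigurationError(f"pulse {ev}: generation must be > 0")
            for d in (ev.source, ev.recipient):
                fg = self.founding_generation(d)
                if fg is not None and fg <= ev.generation:
                    raise ConfigurationError(
                        f"pulse {ev}: deme {d} is founded at generation {fg}, "
                        f"after the pulse")


@dataclass(frozen=True)
class GenomeConfig:
    """Genome geometry and per-bp per-generation rates.

    Desk-scale runs use small deme sizes with correspondingly raised per-bp
    rates; the population-scaled products theta = 4*N*mu and rho = 4*N*r are
    what the statistics respond to.
    """

    n_chromosomes: int = 10
    chrom_length_bp: int = 1_000_000
    mutation_rate: float = 1e-7
    recombination_rate: float = 2e-8
    selfing_rate: float = 0.0
    generation_time_years: float = 1.0

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.chrom_length_bp < 2:
            raise ConfigurationError("need >=1 chromosome of >=2 bp")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ConfigurationError("selfing_rate must lie in [0, 1]")

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    @property
    def contigs(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chromosome_names}


@dataclass(frozen=True)
class NoiseConfig:
    """Sequencing-like decoration of the simulated calls.

    Missingness masks GT, DP and GQ jointly; DP ~ Poisson(depth_mean) and GQ
    uniform integer in [gq_floor, gq_ceiling].  ``seed=None`` continues the
    simulator's random stream, keeping the whole run a function of one seed.
    """

    missing_rate: float = 0.05
    depth_mean: float = 15.0
    gq_floor: int = 20
    gq_ceiling: int = 99
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if self.gq_floor > self.gq_ceiling:
            raise ConfigurationError("gq_floor must be <= gq_ceiling")
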
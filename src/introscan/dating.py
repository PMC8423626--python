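"""Closed-form dating and assembly metrics, and candidate-gene haplotype
grouping with trait comparison.

* Divergence dating: under neutrality Ks ~ 2 mu T, so T = Ks / (2 mu)
  generations (times the generation time in years).  Because T is inverse in
  mu, the *larger* mutation-rate bound gives the *younger* age.
* LAI (LTR Assembly Index): percentage of LTR-retrotransposon sequence
  assembled intact, = 100 * intact / total.
* Haplotype grouping: distinct allele strings over a region's sites among
  fully-called samples, retained when their frequency strictly exceeds a
  minimum (default 0.01), compared across phenotypes by Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import MISSING, SamplePanel, VariantMatrix


def divergence_time(ks: float, mu: float,
                    generation_time_years: float = 1.0) -> float:
    """Divergence time in years: T = (ks / (2 mu)) * generation_time."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    return (ks / (2.0 * mu)) * generation_time_years


@dataclass(frozen=True)
class DivergenceEstimate:
    """Ks-based age bracket from a mutation-rate interval."""
    ks: float
    mu_low: float
    mu_high: float
    generation_time_years: float = 1.0

    def __post_init__(self):
        if not 0 < self.mu_low <= self.mu_high:
            raise ValueError("need 0 < mu_low <= mu_high")

    @property
    def t_low(self) -> float:
        """Younger bound (from the higher mutation rate)."""
        return divergence_time(self.ks, self.mu_high, self.generation_time_years)

    @property
    def t_high(self) -> float:
        """Older bound (from the lower mutation rate)."""
        return divergence_time(self.ks, self.mu_low, self.generation_time_years)


def lai(intact_ltr_bp: float, total_ltr_bp: float) -> float:
    """LTR Assembly Index: 100 * intact / total (percent)."""
    if total_ltr_bp <= 0:
        raise ValueError("total LTR-RT length must be positive")
    if not 0 <= intact_ltr_bp <= total_ltr_bp:
        raise ValueError("intact length must lie in [0, total]")
    return 100.0 * intact_ltr_bp / total_ltr_bp


# ---------------------------------------------------------------------------
# haplotype grouping
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeGroup:
    name: str                 # Hap1, Hap2, ... in descending frequency
    alleles: str              # allele string over the region's sites
    frequency: float
    members: list[str]        # sample ids
    group_counts: dict[str, int]  # panel-group composition


def group_haplotypes(m: VariantMatrix, chrom: str, start: int, end: int,
                     panel: SamplePanel | None = None,
                     min_freq: float = 0.01) -> list[HaplotypeGroup]:
    """Distinct haplotypes over the region [start, end) (0-based), retained
    at frequency strictly greater than *min_freq*.

    With phased input every sample contributes both haplotypes (a sample is a
    member of each haplotype it carries); with unphased input only samples
    homozygous at every region site are grouped and the heterozygous ones are
    set aside.  Frequencies are over the contributing units (haplotypes or
    samples) among fully-called samples; pre-filter they sum to 1.
    """
    in_region = (m.chrom == chrom) & (m.pos > start) & (m.pos <= end)
    idx = np.flatnonzero(in_region)
    if idx.size == 0:
        raise ValueError(f"region {chrom}:{start}-{end} contains no sites")

    units: dict[str, list[str]] = {}
    if m.haplotypes is not None:
        for i, s in enumerate(m.samples):
            h0 = m.haplotypes[2 * i, idx]
            h1 = m.haplotypes[2 * i + 1, idx]
            if MISSING in h0 or MISSING in h1:
                continue
            for h in (h0, h1):
                units.setdefault("".join(map(str, h)), []).append(s)
    else:
        for i, s in enumerate(m.samples):
            g = m.genotypes[i, idx]
            if MISSING in g:
                continue
            if np.any(g == 1):  # heterozygous somewhere: set aside
                continue
            units.setdefault("".join(map(str, g // 2)), []).append(s)
    total = sum(len(v) for v in units.values())
    if total == 0:
        raise ValueError("no fully-called (and, if unphased, fully homozygous) "
                         "samples in the region")
    ranked = sorted(units.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    out = []
    for k, (alleles, members) in enumerate(ranked, start=1):
        freq = len(members) / total
        if freq <= min_freq:
            continue
        comp: dict[str, int] = {}
        if panel is not None:
            for s in members:
                g = panel.group.get(s, "?")
                comp[g] = comp.get(g, 0) + 1
        out.append(HaplotypeGroup(name=f"Hap{k}", alleles=alleles,
                                  frequency=freq,
                                  members=sorted(set(members)),
                                  group_counts=comp))
    return out


def haplotype_trait_compare(groups: list[HaplotypeGroup], traits: pd.DataFrame
                            ) -> pd.DataFrame:
    """Welch two-sided t-tests between every pair of haplotype groups, per
    environment.

    *traits* columns: sample, environment, value.  Each environment is tested
    separately (no pooling); pairs where either group has fewer than two
    phenotyped members are skipped with a note row (t, p = NaN).
    """
    req = {"sample", "environment", "value"}
    if not req.issubset(traits.columns):
        raise ValueError(f"trait table needs columns {sorted(req)}")
    if len(groups) < 2:
        raise ValueError("need at least two haplotype groups")
    rows = []
    for env, chunk in traits.groupby("environment", sort=True):
        by_sample = chunk.set_index("sample")["value"]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = by_sample.reindex(groups[i].members).dropna().to_numpy()
                b = by_sample.reindex(groups[j].members).dropna().to_numpy()
                if len(a) < 2 or len(b) < 2:
                    rows.append((env, groups[i].name, groups[j].name,
                                 len(a), len(b), np.nan, np.nan,
                                 "skipped: <2 phenotyped members"))
                    continue
                if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(a, b, equal_var=False)
                rows.append((env, groups[i].name, groups[j].name,
                             len(a), len(b), float(t), float(p), ""))
    return pd.DataFrame(rows, columns=["environment", "group_a", "group_b",
                                       "n_a", "n_b", "t", "p", "note"])
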
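"""Discrete-generation Wright-Fisher forward simulator.

Haplotypes carry (a) a sorted array of derived-mutation positions under an
infinite-sites model on integer bp coordinates (collisions re-drawn) and (b)
an exact local-ancestry track.  Meiosis draws a Poisson number of crossovers
per chromosome (no interference) and assorts chromosomes independently;
selfing is the probability of using the same parent twice.  Haplotype arrays
are treated as immutable and shared between generations, so a meiosis without
crossover is a reference copy.

Identical (configs, seed) runs are bit-identical: all randomness flows from a
single ``numpy.random.Generator`` consumed in a fixed order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..variants import MISSING, SamplePanel, VariantMatrix
from .config import ConfigurationError, DemographyConfig, GenomeConfig, NoiseConfig
from .truth import AncestryTruth

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# A haplotype is a list over chromosomes of [muts, anc_ends, anc_labels]:
#   muts       sorted int64 positions (0-based) of derived alleles
#   anc_ends   int64 segment end positions, ascending, last == chrom length
#   anc_labels int16 deme label per segment
# An individual is a list [hap0, hap1].


def _founder_hap(n_chrom: int, length: int, label: int) -> list:
    return [[np.empty(0, dtype=np.int64),
             np.array([length], dtype=np.int64),
             np.array([label], dtype=np.int16)] for _ in range(n_chrom)]


def _relabel(ind: list, label: int, length: int) -> list:
    """Founder copy of *ind* whose ancestry is reset to *label* (shares muts)."""
    out = []
    for hap in ind:
        out.append([[c[0],
                     np.array([length], dtype=np.int64),
                     np.array([label], dtype=np.int16)] for c in hap])
    return out


def _insert_sorted(arr: np.ndarray, pos: int) -> np.ndarray:
    """New array with *pos* inserted in sort order (fast np.insert)."""
    k = int(arr.searchsorted(pos))
    out = np.empty(arr.size + 1, dtype=arr.dtype)
    out[:k] = arr[:k]
    out[k] = pos
    out[k + 1:] = arr[k:]
    return out


def _cut_track(ends: np.ndarray, labels: np.ndarray, lo: int, hi: int):
    """Ancestry segments of [lo, hi): piece ends (capped at hi) and labels."""
    i = int(ends.searchsorted(lo, side="right"))
    j = int(ends.searchsorted(hi, side="left"))
    piece_ends = np.empty(j - i + 1, dtype=np.int64)
    piece_ends[:j - i] = ends[i:j]
    piece_ends[j - i] = hi
    return piece_ends, labels[i:j + 1]


def _splice(c0: list, c1: list, first: int, cuts: np.ndarray, length: int) -> list:
    """Recombinant chromosome alternating between parental chromosomes *c0*
    and *c1* at *cuts*, starting from haplotype *first*."""
    bounds = np.empty(cuts.size + 2, dtype=np.int64)
    bounds[0] = 0
    bounds[1:-1] = cuts
    bounds[-1] = length
    m0, e0, l0 = c0
    m1, e1, l1 = c1
    # ancestry untouched when both parents carry one identical label
    same_anc = l0.size == 1 and l1.size == 1 and l0[0] == l1[0]
    i0 = m0.searchsorted(bounds)
    i1 = m1.searchsorted(bounds)
    mut_pieces, end_pieces, lbl_pieces = [], [], []
    cur = first
    for k in range(bounds.size - 1):
        if bounds[k] < bounds[k + 1]:
            if cur == 0:
                mut_pieces.append(m0[i0[k]:i0[k + 1]])
            else:
                mut_pieces.append(m1[i1[k]:i1[k + 1]])
            if not same_anc:
                src = c0 if cur == 0 else c1
                pe, pl = _cut_track(src[1], src[2], int(bounds[k]),
                                    int(bounds[k + 1]))
                end_pieces.append(pe)
                lbl_pieces.append(pl)
        cur ^= 1
    muts = np.concatenate(mut_pieces) if mut_pieces else np.empty(0, dtype=np.int64)
    if same_anc:
        return [muts, e0, l0]
    ends = np.concatenate(end_pieces)
    labels = np.concatenate(lbl_pieces)
    if len(labels) > 1:  # merge adjacent equal-label segments
        keep = np.append(labels[:-1] != labels[1:], True)
        ends, labels = ends[keep], labels[keep]
    return [muts, ends, labels]


def _gamete(ind: list, bits: list, cuts_by_slot: dict, base: int, C: int,
            length: int) -> list:
    h0, h1 = ind
    if not cuts_by_slot:
        return [h0[c] if bits[c] == 0 else h1[c] for c in range(C)]
    hap = []
    for c in range(C):
        cuts = cuts_by_slot.get(base + c)
        if cuts is None:
            hap.append(h0[c] if bits[c] == 0 else h1[c])
        else:
            hap.append(_splice(h0[c], h1[c], bits[c],
                               np.sort(np.asarray(cuts, dtype=np.int64)),
                               length))
    return hap


def _reproduce(pops: dict[int, list], d: int, selfing: float,
               pulse: tuple[int, float] | None, rng: np.random.Generator,
               genome: GenomeConfig, used: list[set], mutate: bool = True
               ) -> list:
    """One generation of offspring for deme *d* (size preserved)."""
    pop_d = pops[d]
    n_off = len(pop_d)
    L = genome.chrom_length_bp
    C = genome.n_chromosomes

    self_draw = (rng.random(n_off) < genome.selfing_rate) \
        if genome.selfing_rate > 0 else np.zeros(n_off, dtype=bool)
    if pulse is not None:
        src, alpha = pulse
        m_deme = np.where(rng.random(n_off) < alpha, src, d)
        f_deme = np.where(rng.random(n_off) < alpha, src, d)
    else:
        m_deme = f_deme = None
    m_pick = rng.random(n_off)
    f_pick = rng.random(n_off)
    bits = rng.integers(0, 2, size=(2 * n_off, C)).tolist()

    # crossovers are rare at desk scale: draw the generation's total count and
    # scatter over (gamete, chromosome) slots
    cuts_by_slot: dict[int, list[int]] = {}
    lam_x = 2 * n_off * C * genome.recombination_rate * L
    if lam_x > 0:
        n_x = int(rng.poisson(lam_x))
        if n_x:
            slots = rng.integers(0, 2 * n_off * C, size=n_x).tolist()
            xpos = rng.integers(1, L, size=n_x).tolist()
            for slot, xp in zip(slots, xpos):
                cuts_by_slot.setdefault(slot, []).append(xp)

    offspring = []
    for i in range(n_off):
        if m_deme is None:
            mpop = fpop = pop_d
        else:
            mpop = pops[int(m_deme[i])]
            fpop = pops[int(f_deme[i])]
        mother = mpop[int(m_pick[i] * len(mpop))]
        father = mother if self_draw[i] else fpop[int(f_pick[i] * len(fpop))]
        offspring.append(
            [_gamete(mother, bits[2 * i], cuts_by_slot, 2 * i * C, C, L),
             _gamete(father, bits[2 * i + 1], cuts_by_slot,
                     (2 * i + 1) * C, C, L)])

    if mutate and genome.mutation_rate > 0:
        lam = 2 * n_off * genome.mutation_rate * L * C
        n_mut = int(rng.poisson(lam))
        if n_mut:
            gidx = rng.integers(0, 2 * n_off, size=n_mut).tolist()
            cidx = rng.integers(0, C, size=n_mut).tolist()
            for g, c in zip(gidx, cidx):
                pos = int(rng.integers(0, L))
                while pos in used[c]:
                    pos = int(rng.integers(0, L))
                used[c].add(pos)
                hap = offspring[g >> 1][g & 1]
                hap[c] = [_insert_sorted(hap[c][0], pos), hap[c][1], hap[c][2]]
    return offspring


def _prune_fixed(pops: dict[int, list], C: int) -> None:
    """Drop mutations fixed in every live haplotype: they can never be
    polymorphic among the samples, and removing them keeps per-haplotype
    arrays (and meiosis cost) bounded over long runs."""
    haps = [h for pop in pops.values() for ind in pop for h in ind]
    for c in range(C):
        common: np.ndarray | None = None
        seen: set[int] = set()
        for h in haps:
            e = h[c]
            if id(e) in seen:
                continue
            seen.add(id(e))
            muts = e[0]
            if common is None:
                common = muts
            else:
                common = common[np.isin(common, muts, assume_unique=True)]
            if common.size == 0:
                break
        if common is None or common.size == 0:
            continue
        cache: dict[int, list] = {}
        for h in haps:
            e = h[c]
            ne = cache.get(id(e))
            if ne is None:
                keep = e[0][np.isin(e[0], common, assume_unique=True,
                                    invert=True)]
                ne = [keep, e[1], e[2]]
                cache[id(e)] = ne
            h[c] = ne


def _run_forward(demography: DemographyConfig, genome: GenomeConfig,
                 rng: np.random.Generator) -> dict[int, list]:
    """Run the demography forward; returns present-day populations."""
    L = genome.chrom_length_bp
    foundings: dict[int, list] = {}
    for ev in demography.split_events:
        foundings.setdefault(ev.generation, []).append(ev)
    pulses: dict[int, dict[int, tuple[int, float]]] = {}
    for ev in demography.admixture_pulses:
        pulses.setdefault(ev.generation, {})[ev.recipient] = (ev.source, ev.proportion)

    t_start = demography.oldest_event + demography.burnin_generations
    pops: dict[int, list] = {}
    for d in demography.root_demes:
        pops[d] = [[_founder_hap(genome.n_chromosomes, L, d),
                    _founder_hap(genome.n_chromosomes, L, d)]
                   for _ in range(demography.deme_sizes[d])]
    used: list[set] = [set() for _ in range(genome.n_chromosomes)]

    for t in range(t_start, 0, -1):
        for ev in foundings.get(t, []):
            if ev.parent not in pops:
                raise ConfigurationError(
                    f"split {ev}: parent deme {ev.parent} not alive at "
                    f"generation {t}")
            parent_pop = pops[ev.parent]
            n = demography.deme_sizes[ev.child]
            idx = rng.choice(len(parent_pop), size=n, replace=n > len(parent_pop))
            pops[ev.child] = [_relabel(parent_pop[int(i)], ev.child, L)
                              for i in np.sort(idx)]
        step_pulses = pulses.get(t, {})
        for rcp in step_pulses:
            if rcp not in pops or step_pulses[rcp][0] not in pops:
                ev = step_pulses[rcp]
                raise ConfigurationError(
                    f"admixture pulse into deme {rcp} from deme {ev[0]} at "
                    f"generation {t}: a deme does not exist yet")
        pops = {d: _reproduce(pops, d, genome.selfing_rate,
                              step_pulses.get(d), rng, genome, used)
                for d in sorted(pops)}
        if t % 150 == 0:
            _prune_fixed(pops, genome.n_chromosomes)
    return pops


def _collect_matrix(sampled: list[tuple[str, int, list]], genome: GenomeConfig,
                    demography: DemographyConfig, rng: np.random.Generator
                    ) -> tuple[VariantMatrix, AncestryTruth]:
    """Build the phased variant matrix (polymorphic sites only) and the
    ancestry truth from sampled individuals."""
    names = [s for s, _, _ in sampled]
    n = len(names)
    L = genome.chrom_length_bp
    chrom_names = genome.chromosome_names

    chroms, poss, refs, alts, hap_cols = [], [], [], [], []
    for c, cname in enumerate(chrom_names):
        allpos = np.unique(np.concatenate(
            [ind[h][c][0] for _, _, ind in sampled for h in (0, 1)]
            or [np.empty(0, dtype=np.int64)]))
        if allpos.size == 0:
            continue
        H = np.zeros((2 * n, allpos.size), dtype=np.int8)
        for i, (_, _, ind) in enumerate(sampled):
            for h in (0, 1):
                H[2 * i + h, np.isin(allpos, ind[h][c][0], assume_unique=True)] = 1
        counts = H.sum(axis=0)
        poly = (counts > 0) & (counts < 2 * n)
        if not poly.any():
            continue
        allpos, H = allpos[poly], H[:, poly]
        ref_i = rng.integers(0, 4, size=allpos.size)
        alt_i = (ref_i + 1 + rng.integers(0, 3, size=allpos.size)) % 4
        chroms.append(np.full(allpos.size, cname, dtype=object))
        poss.append(allpos + 1)  # 1-based
        refs.append(_BASES[ref_i])
        alts.append(_BASES[alt_i])
        hap_cols.append(H)

    if chroms:
        chrom = np.concatenate(chroms)
        pos = np.concatenate(poss)
        ref = np.concatenate(refs)
        alt = np.concatenate(alts)
        H = np.concatenate(hap_cols, axis=1)
    else:
        chrom = np.empty(0, dtype=object)
        pos = np.empty(0, dtype=np.int64)
        ref = alt = np.empty(0, dtype=object)
        H = np.zeros((2 * n, 0), dtype=np.int8)
    G = (H[0::2] + H[1::2]).astype(np.int8)
    m = VariantMatrix(names, chrom, pos, ref, alt, G, haplotypes=H,
                      contigs=genome.contigs)

    rows = []
    labels = demography.group_labels
    for name, d, ind in sampled:
        for h in (0, 1):
            for c, cname in enumerate(chrom_names):
                ends, labs = ind[h][c][1], ind[h][c][2]
                start = 0
                for e, lab in zip(ends, labs):
                    rows.append((cname, start, int(e), name, h, labels[int(lab)]))
                    start = int(e)
    tracts = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                         "sample", "hap", "label"])
    sample_group = {name: labels[d] for name, d, _ in sampled}
    truth = AncestryTruth(tracts, sample_group, genome.contigs)
    return m, truth


def _decorate(m: VariantMatrix, noise: NoiseConfig, rng: np.random.Generator
              ) -> VariantMatrix:
    """Simulated DP/GQ and joint GT/DP/GQ missingness."""
    n, S = m.n_samples, m.n_sites
    nrng = np.random.default_rng(noise.seed) if noise.seed is not None else rng
    dp = nrng.poisson(noise.depth_mean, size=(n, S)).astype(np.int16)
    gq = nrng.integers(noise.gq_floor, noise.gq_ceiling + 1,
                       size=(n, S)).astype(np.int16)
    H = m.haplotypes.copy()
    G = m.genotypes.copy()
    if noise.missing_rate > 0 and S:
        miss = nrng.random((n, S)) < noise.missing_rate
        G[miss] = MISSING
        dp[miss] = MISSING
        gq[miss] = MISSING
        H[np.repeat(miss, 2, axis=0)] = MISSING
    return VariantMatrix(m.samples, m.chrom, m.pos, m.ref, m.alt, G,
                         dp, gq, H, contigs=m.contigs)


def simulate_panel(demography: DemographyConfig, genome: GenomeConfig,
                   noise: NoiseConfig | None = None, seed: int = 0
                   ) -> tuple[VariantMatrix, SamplePanel, AncestryTruth]:
    """Simulate a phased diploid panel under the given demography.

    Returns the phased biallelic variant matrix (monomorphic sites excluded),
    the sample panel (group = deme label) and the exact ancestry truth.
    Identical (configs, seed) give bit-identical results.
    """
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    pops = _run_forward(demography, genome, rng)

    sampled: list[tuple[str, int, list]] = []
    for d in range(demography.n_demes):
        k = demography.sample_counts[d]
        if k == 0:
            continue
        idx = np.sort(rng.choice(demography.deme_sizes[d], size=k, replace=False))
        for j, i in enumerate(idx):
            name = f"{demography.group_labels[d]}_{j:03d}"
            sampled.append((name, d, pops[d][int(i)]))

    m, truth = _collect_matrix(sampled, genome, demography, rng)
    m = _decorate(m, noise, rng)
    panel = SamplePanel(group=dict(truth.sample_group))
    logger.info("simulate_panel: %d samples, %d polymorphic sites",
                m.n_samples, m.n_sites)
    return m, panel, truth
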
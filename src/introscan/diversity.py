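"""Windowed nucleotide diversity, Weir-Cockerham F_ST, between-group D_xy,
LD decay and genotype PCA.

Estimator choices follow the common resequencing-pipeline conventions:

* per-site pi is the unbiased pairwise estimator ``2 j (n - j) / (n (n - 1))``
  and window pi sums site values over the window's bp length;
* F_ST is the Weir & Cockerham (1984) theta with ratio-of-sums (weighted)
  aggregation over windows;
* LD is the squared Pearson correlation of unphased allele dosages;
* PCA standardizes dosages by sqrt(p(1-p)) with mean imputation of missing
  calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import (MISSING, GenomicWindow, SamplePanel, VariantMatrix,
                       assign_sites, site_allele_stats)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(alt_count, called_alleles):
    """Unbiased per-site pairwise diversity 2 j (n - j) / (n (n - 1)).

    Vectorized; sites with fewer than two called alleles yield NaN and are
    skipped by the windowed aggregator.
    """
    j = np.asarray(alt_count, dtype=np.float64)
    n = np.asarray(called_alleles, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def windowed_pi(m: VariantMatrix, panel: SamplePanel, group: str,
                windows: Sequence[GenomicWindow]) -> pd.DataFrame:
    """Per-window pi (per bp) for *group*: sum of site pi over window length."""
    samples = panel.samples_in_group(group)
    alt, n, _ = site_allele_stats(m, samples)
    pi = site_pi(alt, n)
    site_idx = assign_sites(m, windows)
    rows = []
    for w, idx in zip(windows, site_idx):
        vals = pi[idx]
        vals = vals[~np.isnan(vals)]
        rows.append((w.chrom, w.start, w.end, len(vals),
                     float(vals.sum()) / (w.end - w.start)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "pi"])


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST (two populations, biallelic)
# ---------------------------------------------------------------------------

def _wc_components(m: VariantMatrix, panel: SamplePanel, group_a: str,
                   group_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components for two
    populations: returns (a, a + b + c) arrays; NaN where undefined."""
    ia = m.sample_indices(panel.samples_in_group(group_a))
    ib = m.sample_indices(panel.samples_in_group(group_b))
    r = 2.0
    comp_num = np.full(m.n_sites, np.nan)
    comp_den = np.full(m.n_sites, np.nan)

    Ga, Gb = m.genotypes[ia], m.genotypes[ib]
    na = (Ga != MISSING).sum(axis=0).astype(float)   # diploids called
    nb = (Gb != MISSING).sum(axis=0).astype(float)
    ok = (na >= 2) & (nb >= 2)

    pa = np.where(Ga != MISSING, Ga, 0).sum(axis=0) / np.maximum(2 * na, 1)
    pb = np.where(Gb != MISSING, Gb, 0).sum(axis=0) / np.maximum(2 * nb, 1)
    ha = (Ga == 1).sum(axis=0) / np.maximum(na, 1)   # observed het freq
    hb = (Gb == 1).sum(axis=0) / np.maximum(nb, 1)

    n_bar = (na + nb) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (na + nb - (na ** 2 + nb ** 2) / (na + nb)) / (r - 1.0)
        p_bar = (na * pa + nb * pb) / (na + nb)
        s2 = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (na * ha + nb * hb) / (na + nb)

        a = (n_bar / n_c) * (s2 - (1.0 / (n_bar - 1.0))
                             * (p_bar * (1.0 - p_bar)
                                - s2 * (r - 1.0) / r
                                - h_bar / 4.0))
        b = (n_bar / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar)
                                       - s2 * (r - 1.0) / r
                                       - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar))
        c = h_bar / 2.0
        total = a + b + c
    comp_num[ok] = a[ok]
    comp_den[ok] = total[ok]
    return comp_num, comp_den


def weir_cockerham_fst(m: VariantMatrix, panel: SamplePanel, group_a: str,
                       group_b: str, windows: Sequence[GenomicWindow] | None = None
                       ) -> tuple[pd.DataFrame | None, float]:
    """Weir-Cockerham theta per window (ratio of summed components) and
    genome wide.  Windows whose denominator sums to zero are emitted as NaN.
    Returns (window frame or None, genome-wide theta)."""
    num, den = _wc_components(m, panel, group_a, group_b)
    valid = ~np.isnan(den)
    total = float(np.nansum(num[valid]) / np.nansum(den[valid])) \
        if np.nansum(den[valid]) != 0 else float("nan")
    if windows is None:
        return None, total
    rows = []
    for w, idx in zip(windows, assign_sites(m, windows)):
        v = idx[valid[idx]]
        d = num[v].sum(), den[v].sum()
        theta = float(d[0] / d[1]) if d[1] != 0 else float("nan")
        rows.append((w.chrom, w.start, w.end, len(v), theta))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                       "fst"]), total


# ---------------------------------------------------------------------------
# D_xy
# ---------------------------------------------------------------------------

def dxy(m: VariantMatrix, panel: SamplePanel, group_a: str, group_b: str,
        windows: Sequence[GenomicWindow]) -> pd.DataFrame:
    """Mean between-group per-bp difference: sum over sites of
    p_a(1-p_b) + p_b(1-p_a), divided by window length."""
    _, _, pa = site_allele_stats(m, panel.samples_in_group(group_a))
    _, _, pb = site_allele_stats(m, panel.samples_in_group(group_b))
    per_site = pa * (1 - pb) + pb * (1 - pa)
    rows = []
    for w, idx in zip(windows, assign_sites(m, windows)):
        vals = per_site[idx]
        vals = vals[~np.isnan(vals)]
        rows.append((w.chrom, w.start, w.end, len(vals),
                     float(vals.sum()) / (w.end - w.start)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "dxy"])


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(dosage_x, dosage_y) -> float:
    """Squared Pearson correlation of two allele-dosage vectors over
    pairwise-complete observations; NaN if fewer than two complete pairs or
    either site is invariant among them."""
    x = np.asarray(dosage_x, dtype=np.float64)
    y = np.asarray(dosage_y, dtype=np.float64)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return float("nan")
    vx = x - x.mean()
    vy = y - y.mean()
    sx = (vx ** 2).sum()
    sy = (vy ** 2).sum()
    if sx == 0 or sy == 0:
        return float("nan")
    return float((vx * vy).sum() ** 2 / (sx * sy))


@dataclass
class LDDecayCurve:
    """Mean r^2 by physical-distance bin."""
    bin_edges: np.ndarray          # (n_bins + 1,) bp
    mean_r2: np.ndarray            # (n_bins,), NaN where empty
    pair_counts: np.ndarray        # (n_bins,)

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dist_lo": self.bin_edges[:-1].astype(int),
                             "dist_hi": self.bin_edges[1:].astype(int),
                             "mean_r2": self.mean_r2,
                             "n_pairs": self.pair_counts.astype(int)})


def ld_decay(m: VariantMatrix, panel: SamplePanel, group: str,
             max_dist: int = 500_000, n_bins: int = 50,
             min_maf: float = 0.05, max_missing: float = 0.1) -> LDDecayCurve:
    """LD decay for *group*: all intra-chromosome site pairs within
    *max_dist* aggregated into equal-width distance bins.

    Group-level MAF/missingness thresholds are re-applied before pairing, as
    LD-decay tools do.
    """
    samples = panel.samples_in_group(group)
    if len(samples) < 2:
        raise ValueError(f"group {group!r} has fewer than two samples")
    sub = VariantMatrix(samples, m.chrom, m.pos, m.ref, m.alt,
                        m.genotypes[m.sample_indices(samples)],
                        contigs=m.contigs, phased=False)
    keep = (sub.maf() >= min_maf) & (sub.missing_fraction() <= max_missing)
    sub = sub.take_sites(keep)

    edges = np.linspace(0, max_dist, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    G = sub.genotypes.astype(np.float64)
    G[G == MISSING] = np.nan
    for c in sub.contigs:
        idx = np.flatnonzero(sub.chrom == c)
        pos = sub.pos[idx]
        X = G[:, idx]
        for a in range(len(idx)):
            far = np.searchsorted(pos, pos[a] + max_dist, side="right")
            for b in range(a + 1, far):
                ok = ~np.isnan(X[:, a]) & ~np.isnan(X[:, b])
                if ok.sum() < 2:
                    continue
                r2 = ld_r2(np.where(ok, X[:, a], MISSING),
                           np.where(ok, X[:, b], MISSING))
                if np.isnan(r2):
                    continue
                d = pos[b] - pos[a]
                k = min(int(d / max_dist * n_bins), n_bins - 1)
                sums[k] += r2
                counts[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(edges, mean, counts)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def genotype_pca(m: VariantMatrix, k: int = 10
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Top-*k* principal components of the frequency-standardized dosage
    matrix (GCTA-style).  Returns (coords (n, k), explained-variance
    fractions (k,)); deterministic up to sign."""
    if k >= m.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    G = m.genotypes.astype(np.float64)
    G[G == MISSING] = np.nan
    p = np.nanmean(G, axis=0) / 2.0
    sd = np.sqrt(p * (1.0 - p))
    keep = (sd > 0) & ~np.isnan(sd)
    G = G[:, keep]
    Z = (G - 2.0 * p[keep]) / sd[keep]
    Z = np.where(np.isnan(Z), 0.0, Z)  # mean imputation after centering
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    ev = s ** 2
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    coords = U[:, :k] * s[:k]
    explained = ev[:k] / ev.sum()
    return coords, explained
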
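"""Gene-flow machinery: Patterson's D (ABBA-BABA) with block-jackknife
significance, windowed f_d, IBD tract detection on phased haplotypes, the
binned nIBD/rIBD introgression scan with segment calling and per-accession
introgressed proportions, and top-quantile sweep-window selection.

Sign conventions: with taxa (((P1, P2), P3), O) and alleles polarized so the
outgroup major allele is ancestral, D > 0 means excess derived-allele sharing
between P2 and P3.  f_d follows the dynamic-donor formulation (the donor at
each site is whichever of P2/P3 has the higher derived frequency) and signals
gene flow when 0 < f_d < 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import (MISSING, GenomicWindow, SamplePanel, VariantMatrix,
                       make_windows, site_allele_stats)

logger = logging.getLogger(__name__)

TRACT_COLUMNS = ["sample_a", "hap_a", "sample_b", "hap_b", "chrom",
                 "start", "end", "n_snps", "n_mismatches"]


# ---------------------------------------------------------------------------
# Patterson's D and f_d
# ---------------------------------------------------------------------------

@dataclass
class IntrogressionStats:
    d: float
    se: float
    z: float
    n_sites: int
    n_blocks: int
    degenerate: bool = False
    fd: pd.DataFrame | None = None


def _polarized_freqs(m: VariantMatrix, panel: SamplePanel, p1: str, p2: str,
                     p3: str, outgroup: str, max_outgroup_poly: float = 0.1):
    """Derived-allele frequencies for the four roles with the outgroup major
    allele taken as ancestral.  Sites where any role has no calls, or the
    outgroup is polymorphic above *max_outgroup_poly*, are masked out."""
    freqs = []
    for g in (p1, p2, p3, outgroup):
        _, n, f = site_allele_stats(m, panel.samples_in_group(g))
        freqs.append((n, f))
    nO, fO = freqs[3]
    valid = np.ones(m.n_sites, dtype=bool)
    for n, f in freqs:
        valid &= (n > 0) & ~np.isnan(f)
    flip = fO > 0.5
    out = []
    for n, f in freqs:
        out.append(np.where(flip, 1.0 - f, f))
    pO = out[3]
    valid &= ~(np.minimum(fO, 1.0 - fO) > max_outgroup_poly)
    return out[0], out[1], out[2], pO, valid


def _d_terms(p1, p2, p3, pO):
    abba = (1.0 - p1) * p2 * p3 * (1.0 - pO)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - pO)
    return abba - baba, abba + baba


def patterson_d(m: VariantMatrix, panel: SamplePanel, p1: str, p2: str,
                p3: str, outgroup: str, block_size: int = 500
                ) -> IntrogressionStats:
    """Genome-wide ABBA-BABA D with block-jackknife SE and Z.

    *p1..outgroup* are panel group labels; ``D > 0`` indicates gene flow
    between P3 and P2, ``D < 0`` between P3 and P1.
    """
    f1, f2, f3, fO, valid = _polarized_freqs(m, panel, p1, p2, p3, outgroup)
    num, den = _d_terms(f1[valid], f2[valid], f3[valid], fO[valid])
    tot_den = float(den.sum())
    if tot_den == 0.0:
        raise ValueError("no informative sites: ABBA + BABA weights sum to zero")
    d = float(num.sum()) / tot_den
    se, z, n_blocks, degenerate = block_jackknife(num, den, block_size)
    return IntrogressionStats(d=d, se=se, z=z, n_sites=int(valid.sum()),
                              n_blocks=n_blocks, degenerate=degenerate)


def block_jackknife(numerators, denominators, block_size: int = 500
                    ) -> tuple[float, float, int, bool]:
    """Delete-one-block jackknife for the ratio sum(num)/sum(den) over
    contiguous site blocks of *block_size* sites.

    Returns (SE, Z, n_blocks, degenerate).  All-identical blocks give SE = 0
    and are flagged degenerate (Z is NaN).
    """
    num = np.asarray(numerators, dtype=np.float64)
    den = np.asarray(denominators, dtype=np.float64)
    if num.shape != den.shape or num.ndim != 1:
        raise ValueError("numerators and denominators must be equal-length 1-D")
    n_blocks = max(1, int(np.ceil(num.size / block_size)))
    if n_blocks < 10:
        logger.warning("block_jackknife: only %d blocks; SE may be unstable",
                       n_blocks)
    tot_n, tot_d = num.sum(), den.sum()
    if tot_d == 0:
        return float("nan"), float("nan"), n_blocks, True
    theta = tot_n / tot_d
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        d = tot_d - den[sl].sum()
        loo[b] = (tot_n - num[sl].sum()) / d if d != 0 else theta
    se = float(np.sqrt((n_blocks - 1) / n_blocks
                       * ((loo - loo.mean()) ** 2).sum()))
    if se == 0.0:
        return 0.0, float("nan"), n_blocks, True
    return se, float(theta / se), n_blocks, False


def fd_windows(m: VariantMatrix, panel: SamplePanel, p1: str, p2: str,
               p3: str, outgroup: str, window_snps: int = 100) -> pd.DataFrame:
    """f_d in consecutive non-overlapping windows of exactly *window_snps*
    usable sites per chromosome (trailing partial windows dropped).

    f_d = S(P1,P2,P3,O) / S(P1,P_D,P_D,O) with the per-site dynamic donor
    P_D = argmax(p2, p3) by derived frequency.  Windows with a zero
    denominator get NaN; values outside (0, 1) are retained but flagged
    ``gene_flow=False``.
    """
    f1, f2, f3, fO, valid = _polarized_freqs(m, panel, p1, p2, p3, outgroup)
    num, _ = _d_terms(f1, f2, f3, fO)
    pD = np.maximum(f2, f3)
    num_max, _ = _d_terms(f1, pD, pD, fO)
    rows = []
    for c in m.contigs:
        idx = np.flatnonzero((m.chrom == c) & valid)
        n_win = len(idx) // window_snps
        for w in range(n_win):
            sl = idx[w * window_snps:(w + 1) * window_snps]
            den = num_max[sl].sum()
            fd = float(num[sl].sum() / den) if den != 0 else float("nan")
            rows.append((c, int(m.pos[sl[0]] - 1), int(m.pos[sl[-1]]),
                         window_snps, fd, bool(0.0 < fd < 1.0)))
    if not rows:
        logger.warning("fd_windows: fewer than %d usable sites; no windows",
                       window_snps)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                       "fd", "gene_flow"])


# ---------------------------------------------------------------------------
# IBD tract detection
# ---------------------------------------------------------------------------

def group_hap_pairs(m: VariantMatrix, panel: SamplePanel, group_a: str,
                    group_b: str) -> list[tuple[str, int, str, int]]:
    """All (sample_a, hap_a, sample_b, hap_b) haplotype pairs between two
    groups (a sample paired with itself is excluded)."""
    pairs = []
    for sa in panel.samples_in_group(group_a):
        for sb in panel.samples_in_group(group_b):
            if sa == sb:
                continue
            for ha in (0, 1):
                for hb in (0, 1):
                    pairs.append((sa, ha, sb, hb))
    return pairs


def detect_ibd(m: VariantMatrix, pairs: Iterable[tuple[str, int, str, int]],
               min_snps: int = 50, min_bp: int = 100_000,
               max_mismatch: int = 1) -> pd.DataFrame:
    """Deterministic identity-run scan for IBD tracts on phased haplotypes.

    For each haplotype pair and chromosome, maximal runs of identity over the
    pair's jointly-called sites containing at most *max_mismatch* mismatching
    sites are enumerated; runs spanning >= *min_bp* with >= *min_snps* sites
    are kept, and a non-overlapping subset is chosen greedily by bp length.
    Tract bounds are [first site pos - 1, last site pos) half-open and runs
    are trimmed to matching end sites.
    """
    if m.haplotypes is None:
        raise ValueError("IBD detection needs phased haplotypes; provide a "
                         "phased VCF")
    if min_snps < 1 or min_bp < 1 or max_mismatch < 0:
        raise ValueError("min_snps, min_bp must be positive; max_mismatch >= 0")
    H = m.haplotypes
    sample_row = {s: 2 * i for i, s in enumerate(m.samples)}
    chrom_data = []
    for c in m.contigs:
        idx = np.flatnonzero(m.chrom == c)
        if idx.size:
            chrom_data.append((c, np.ascontiguousarray(H[:, idx]), m.pos[idx]))
    rows_out = []
    for sa, ha, sb, hb in pairs:
        ra = sample_row[sa] + ha
        rb = sample_row[sb] + hb
        for c, Hc, cpos in chrom_data:
            x, y = Hc[ra], Hc[rb]
            ok = (x != MISSING) & (y != MISSING)
            if int(ok.sum()) < min_snps:
                continue
            pos = cpos[ok]
            mism = np.flatnonzero(x[ok] != y[ok])
            rows_out.extend(
                _pair_tracts(pos, mism, sa, ha, sb, hb, c,
                             min_snps, min_bp, max_mismatch))
    return pd.DataFrame(rows_out, columns=TRACT_COLUMNS)


def _pair_tracts(pos: np.ndarray, mism: np.ndarray, sa, ha, sb, hb, chrom,
                 min_snps: int, min_bp: int, max_mismatch: int) -> list[tuple]:
    """Candidate maximal <=max_mismatch runs for one pair/chromosome, then a
    greedy non-overlapping selection by bp length."""
    n = pos.size
    k = mism.size
    q = max_mismatch
    if k <= q:
        lo = np.array([0])
        hi = np.array([n - 1])
        inc_lo = np.array([0])
        inc_hi = np.array([k - 1])
        trims = k
    else:
        bounded = np.concatenate(([-1], mism, [n]))
        n_cand = k - q + 1
        lo = bounded[:n_cand] + 1
        hi = bounded[q + 1:] - 1
        inc_lo = np.arange(n_cand)
        inc_hi = inc_lo + q - 1
        trims = q
    # trim candidate edges to matching sites (edge mismatches carry no
    # identity evidence); each trim removes one included mismatch
    for _ in range(trims):
        cond = (inc_lo <= inc_hi) & (mism[np.clip(inc_lo, 0, max(k - 1, 0))] == lo)
        lo = lo + cond
        inc_lo = inc_lo + cond
        cond = (inc_lo <= inc_hi) & (mism[np.clip(inc_hi, 0, max(k - 1, 0))] == hi)
        hi = hi - cond
        inc_hi = inc_hi - cond
    n_mm = np.maximum(inc_hi - inc_lo + 1, 0)
    ok = hi >= lo
    n_snps = hi - lo + 1
    span = pos[np.clip(hi, 0, n - 1)] - pos[np.clip(lo, 0, n - 1)] + 1
    ok &= (n_snps >= min_snps) & (span >= min_bp)
    cands = list({(int(l), int(h)): (int(l), int(h), int(mm), int(sp))
                  for l, h, mm, sp in zip(lo[ok], hi[ok], n_mm[ok], span[ok])
                  }.values())
    # greedy non-overlap by (length desc, start asc)
    cands.sort(key=lambda t: (-t[3], t[0]))
    chosen: list[tuple] = []
    taken: list[tuple[int, int]] = []
    for lo, hi, nm, span in cands:
        if any(not (hi < a or lo > b) for a, b in taken):
            continue
        taken.append((lo, hi))
        chosen.append((sa, ha, sb, hb, chrom,
                       int(pos[lo] - 1), int(pos[hi]), hi - lo + 1, nm))
    chosen.sort(key=lambda t: t[5])
    return chosen


# ---------------------------------------------------------------------------
# rIBD scan
# ---------------------------------------------------------------------------

@dataclass
class RIBDProfile:
    """Per-bin normalized IBD sharing of the target group with the donor and
    source groups, and their difference rIBD = nIBD_donor - nIBD_source."""
    bins: pd.DataFrame  # chrom, start, end, nibd_donor, nibd_source, ribd
    n_pairs_donor: int
    n_pairs_source: int


def _pair_bin_counts(tracts: pd.DataFrame, windows: Sequence[GenomicWindow]
                     ) -> np.ndarray:
    """Number of distinct haplotype pairs with >=1 bp of tract overlapping
    each window (a pair is counted once per window)."""
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    offset: dict[str, int] = {}
    for i, w in enumerate(windows):
        starts.setdefault(w.chrom, [])
        ends.setdefault(w.chrom, [])
    pos = 0
    grouped: dict[str, list[GenomicWindow]] = {}
    for w in windows:
        grouped.setdefault(w.chrom, []).append(w)
    for c, ws in grouped.items():
        offset[c] = pos
        starts[c] = np.array([w.start for w in ws])
        ends[c] = np.array([w.end for w in ws])
        pos += len(ws)
    diff = np.zeros(pos + 1)
    if len(tracts):
        key = ["sample_a", "hap_a", "sample_b", "hap_b"]
        for _, pair_tracts in tracts.groupby(key, sort=False):
            hit: dict[str, set] = {}
            for t in pair_tracts.itertuples():
                c = t.chrom
                if c not in offset:
                    continue
                lo = int(np.searchsorted(ends[c], t.start, side="right"))
                hi = int(np.searchsorted(starts[c], t.end, side="left"))
                if hi > lo:
                    hit.setdefault(c, set()).update(range(lo, hi))
            for c, idxs in hit.items():
                for merged in _as_ranges(sorted(idxs)):
                    diff[offset[c] + merged[0]] += 1
                    diff[offset[c] + merged[1] + 1] -= 1
    return np.cumsum(diff)[:-1]


def _as_ranges(idxs: list[int]):
    """Consecutive-integer runs as (first, last) pairs."""
    out = []
    for i in idxs:
        if out and i == out[-1][1] + 1:
            out[-1][1] = i
        else:
            out.append([i, i])
    return [(a, b) for a, b in out]


def ribd_scan(donor_tracts: pd.DataFrame, source_tracts: pd.DataFrame,
              panel: SamplePanel, target_group: str, donor_group: str,
              source_group: str, contigs: Mapping[str, int],
              bin_size: int = 10_000, step: int = 5_000) -> RIBDProfile:
    """Binned rIBD profile: per 10-kb bin (5-kb step), the fraction of
    target x donor haplotype pairs sharing an IBD tract overlapping the bin
    (nIBD_donor), likewise for the source group, and their difference."""
    n_t = 2 * len(panel.samples_in_group(target_group))
    n_d = 2 * len(panel.samples_in_group(donor_group))
    n_s = 2 * len(panel.samples_in_group(source_group))
    if min(n_t, n_d, n_s) == 0:
        raise ValueError("target/donor/source groups must be non-empty")
    windows = make_windows(dict(contigs), bin_size, step)
    cd = _pair_bin_counts(donor_tracts, windows) / (n_t * n_d)
    cs = _pair_bin_counts(source_tracts, windows) / (n_t * n_s)
    bins = pd.DataFrame({
        "chrom": [w.chrom for w in windows],
        "start": [w.start for w in windows],
        "end": [w.end for w in windows],
        "nibd_donor": cd,
        "nibd_source": cs,
        "ribd": cd - cs,
    })
    return RIBDProfile(bins=bins, n_pairs_donor=n_t * n_d,
                       n_pairs_source=n_t * n_s)


# ---------------------------------------------------------------------------
# segment calling and per-sample proportions
# ---------------------------------------------------------------------------

def call_segments(profile: RIBDProfile, threshold: float = 0.7,
                  donor_tracts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge maximal runs of overlapping bins with rIBD > *threshold* into
    introgression segments.

    The default 0.7 is a strict rule suited to near-fixed introgressed
    blocks; for diffuse (low-frequency) introgression the attainable rIBD is
    bounded by the introgressed-haplotype frequency and a recalibrated
    threshold (e.g. 0, any positive donor excess) is appropriate.  When
    *donor_tracts* are given, carrier samples (target samples with a donor
    tract overlapping the segment) are annotated.
    """
    b = profile.bins
    sel = b[b["ribd"] > threshold]
    segments = []
    for c, chunk in sel.groupby("chrom", sort=False):
        chunk = chunk.sort_values("start")
        cur = None
        for t in chunk.itertuples():
            if cur is not None and t.start <= cur[1]:
                cur[1] = max(cur[1], t.end)
                cur[2] = max(cur[2], t.ribd)
            else:
                if cur is not None:
                    segments.append((c, *cur))
                cur = [t.start, t.end, t.ribd]
        if cur is not None:
            segments.append((c, *cur))
    out = pd.DataFrame(segments, columns=["chrom", "start", "end", "peak_ribd"])
    if donor_tracts is not None:
        carriers = []
        for s in out.itertuples():
            t = donor_tracts
            hit = t[(t["chrom"] == s.chrom) & (t["start"] < s.end)
                    & (t["end"] > s.start)]
            carriers.append(sorted(set(hit["sample_a"])))
        out["carriers"] = carriers
    return out


def introgressed_proportion(donor_tracts: pd.DataFrame, panel: SamplePanel,
                            target_group: str, contigs: Mapping[str, int]
                            ) -> pd.Series:
    """Per-target-sample introgressed fraction: union of donor-IBD tract bp
    over both haplotypes, divided by 2 x genome length.

    ``donor_tracts`` are target x donor tracts with the target sample in
    ``sample_a``.  Samples without tracts get 0 (with a warning).
    """
    samples = panel.samples_in_group(target_group)
    genome = 2 * sum(contigs.values())
    out = pd.Series(0.0, index=sorted(samples), name="introgressed_fraction")
    t = donor_tracts
    for s in samples:
        mine = t[t["sample_a"] == s]
        total = 0
        for (h, c), chunk in mine.groupby(["hap_a", "chrom"], sort=False):
            total += _union_bp(chunk["start"].to_numpy(), chunk["end"].to_numpy())
        out[s] = total / genome
    missing = [s for s in samples if not (t["sample_a"] == s).any()]
    if missing:
        logger.warning("introgressed_proportion: %d target samples have no "
                       "donor tracts (proportion 0)", len(missing))
    return out


def _union_bp(starts: np.ndarray, ends: np.ndarray) -> int:
    order = np.argsort(starts)
    total, cur_s, cur_e = 0, None, None
    for s, e in zip(starts[order], ends[order]):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return int(total)


# ---------------------------------------------------------------------------
# sweep-window selection
# ---------------------------------------------------------------------------

def top_quantile_windows(scores: pd.DataFrame, quantile: float = 0.05,
                         score_col: str = "score") -> pd.DataFrame:
    """Windows whose score strictly exceeds the (1 - quantile) empirical
    quantile (lower-interpolation), merged when adjacent or overlapping.

    With all-equal scores the strict-exceedance rule selects nothing;
    ``quantile >= 1`` selects every window.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must lie in (0, 1]")
    req = {"chrom", "start", "end", score_col}
    if not req.issubset(scores.columns):
        raise ValueError(f"score table needs columns {sorted(req)}")
    vals = scores[score_col].to_numpy(dtype=np.float64)
    if quantile >= 1.0:
        sel = scores
    else:
        thr = np.quantile(vals, 1.0 - quantile, method="lower")
        sel = scores[vals > thr]
    merged = []
    for c, chunk in sel.groupby("chrom", sort=False):
        chunk = chunk.sort_values("start")
        cur = None
        for t in chunk.itertuples():
            if cur is not None and t.start <= cur[1]:
                cur[1] = max(cur[1], t.end)
            else:
                if cur is not None:
                    merged.append((c, cur[0], cur[1]))
                cur = [t.start, t.end]
        if cur is not None:
            merged.append((c, cur[0], cur[1]))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])
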
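"""ABBA-BABA D, f_d, IBD detection, rIBD scanning and sweep-window
selection against constructed cases and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introscan.introgression import (RIBDProfile, block_jackknife,
                                     call_segments, detect_ibd, fd_windows,
                                     group_hap_pairs, introgressed_proportion,
                                     patterson_d, ribd_scan,
                                     top_quantile_windows)
from introscan.variants import MISSING, SamplePanel

from conftest import matrix_from_haplotypes

RNG = np.random.default_rng(7)


def _four_taxon_matrix(h1, h2, h3, hO, pos=None, contigs=None):
    """One diploid (homozygous) sample per role from haploid allele vectors."""
    H = np.vstack([np.repeat(np.atleast_2d(h1), 2, axis=0),
                   np.repeat(np.atleast_2d(h2), 2, axis=0),
                   np.repeat(np.atleast_2d(h3), 2, axis=0),
                   np.repeat(np.atleast_2d(hO), 2, axis=0)])
    m = matrix_from_haplotypes(H, pos=pos, samples=["P1", "P2", "P3", "O"],
                               contigs=contigs)
    panel = SamplePanel({"P1": "P1", "P2": "P2", "P3": "P3", "O": "O"})
    return m, panel


def pattern_d_oracle(h1, h2, h3, hO):
    """D from exhaustive haploid site-pattern counting (outgroup = ancestral)."""
    abba = baba = 0
    for a, b, c, o in zip(h1, h2, h3, hO):
        derived = 1 - o
        if (a, b, c) == (o, derived, derived):
            abba += 1
        elif (a, b, c) == (derived, o, derived):
            baba += 1
    if abba + baba == 0:
        return None
    return (abba - baba) / (abba + baba)


# ---------------------------------------------------------------------------
# Patterson's D
# ---------------------------------------------------------------------------

def test_d_from_pattern_counts():
    """ABBA=3, BABA=1 with haploid-like roles gives D = 0.5."""
    h1 = [0, 0, 0, 1, 0]
    h2 = [1, 1, 1, 0, 0]
    h3 = [1, 1, 1, 1, 0]
    hO = [0, 0, 0, 0, 0]
    m, panel = _four_taxon_matrix(h1, h2, h3, hO)
    st_ = patterson_d(m, panel, "P1", "P2", "P3", "O")
    assert st_.d == pytest.approx(0.5, abs=1e-12)


def test_d_zero_when_p1_equals_p2():
    """Heterozygous P1 and P2 with identical frequencies: ABBA == BABA."""
    S = 30
    het = np.tile([0, 1], (S, 1)).T  # one het diploid: freq 0.5 everywhere
    h3 = np.repeat(np.atleast_2d(RNG.integers(0, 2, size=S)), 2, axis=0)
    hO = np.zeros((2, S), dtype=int)
    H = np.vstack([het, het.copy(), h3, hO]).astype(np.int8)
    m = matrix_from_haplotypes(H, samples=["P1", "P2", "P3", "O"])
    panel = SamplePanel({"P1": "P1", "P2": "P2", "P3": "P3", "O": "O"})
    st_ = patterson_d(m, panel, "P1", "P2", "P3", "O")
    assert st_.d == pytest.approx(0.0, abs=1e-12)


def test_d_antisymmetric_under_p1_p2_swap():
    for _ in range(10):
        h1, h2, h3 = (RNG.integers(0, 2, size=50) for _ in range(3))
        hO = np.zeros(50, dtype=int)
        m, panel = _four_taxon_matrix(h1, h2, h3, hO)
        try:
            d12 = patterson_d(m, panel, "P1", "P2", "P3", "O").d
            d21 = patterson_d(m, panel, "P2", "P1", "P3", "O").d
        except ValueError:
            continue
        assert d12 == pytest.approx(-d21, abs=1e-12)


def test_d_matches_pattern_oracle_on_random_haploids():
    """Frequency-based D equals exhaustive site-pattern counting when each
    role is a single (homozygous) individual."""
    checked = 0
    for _ in range(60):
        S = int(RNG.integers(5, 200))
        h1, h2, h3 = (RNG.integers(0, 2, size=S) for _ in range(3))
        hO = RNG.integers(0, 2, size=S)
        expected = pattern_d_oracle(h1, h2, h3, hO)
        m, panel = _four_taxon_matrix(h1, h2, h3, hO)
        if expected is None:
            with pytest.raises(ValueError):
                patterson_d(m, panel, "P1", "P2", "P3", "O")
            continue
        got = patterson_d(m, panel, "P1", "P2", "P3", "O").d
        assert got == pytest.approx(expected, abs=1e-10)
        checked += 1
    assert checked >= 30


# ---------------------------------------------------------------------------
# block jackknife
# ---------------------------------------------------------------------------

def test_jackknife_identical_blocks_degenerate():
    num = np.tile([1.0, 2.0], 50)
    den = np.tile([2.0, 4.0], 50)
    se, z, nb, degenerate = block_jackknife(num, den, block_size=10)
    assert se == 0.0 and degenerate and np.isnan(z)


def test_jackknife_matches_manual_computation():
    rng = np.random.default_rng(5)
    num = rng.normal(size=200)
    den = np.abs(rng.normal(size=200)) + 1.0
    B = 20
    se, z, nb, _ = block_jackknife(num, den, block_size=10)
    assert nb == B
    loo = []
    for b in range(B):
        keep = np.ones(200, dtype=bool)
        keep[b * 10:(b + 1) * 10] = False
        loo.append(num[keep].sum() / den[keep].sum())
    loo = np.array(loo)
    man_se = np.sqrt((B - 1) / B * ((loo - loo.mean()) ** 2).sum())
    assert se == pytest.approx(man_se, abs=1e-12)
    assert z == pytest.approx((num.sum() / den.sum()) / man_se, abs=1e-9)


def test_jackknife_z_detects_admixture_pulse():
    """An alpha=0.15 donor pulse yields Z > 3 in most replicates of a
    recombination-rich four-taxon scenario (desk-scale power; between-
    replicate coalescent variance of D limits this below the asymptotic
    ideal)."""
    from introscan.popsim import NoiseConfig, simulate_panel
    from introscan.popsim.presets import (calibration_demography,
                                          calibration_genome)
    from introscan.variants import FilterSpec, filter_variants
    n_sig = 0
    for seed in range(1, 7):
        m, panel, _ = simulate_panel(calibration_demography(0.15),
                                     calibration_genome(), NoiseConfig(),
                                     seed=seed)
        fm, _ = filter_variants(m, FilterSpec())
        st = patterson_d(fm, panel, "P1", "P2", "P3", "OUT")
        if st.z > 3:
            n_sig += 1
    assert n_sig >= 4


# ---------------------------------------------------------------------------
# f_d
# ---------------------------------------------------------------------------

def test_fd_is_one_when_p2_equals_p3():
    h23 = RNG.integers(0, 2, size=250)
    h1 = RNG.integers(0, 2, size=250)
    m, panel = _four_taxon_matrix(h1, h23, h23, np.zeros(250, dtype=int),
                                  contigs={"chr1": 1000})
    out = fd_windows(m, panel, "P1", "P2", "P3", "O", window_snps=50)
    informative = out.dropna(subset=["fd"])
    assert len(informative)
    assert np.allclose(informative.fd, 1.0, atol=1e-12)


def test_fd_zero_without_excess_sharing():
    h1 = RNG.integers(0, 2, size=250)
    h3 = RNG.integers(0, 2, size=250)
    m, panel = _four_taxon_matrix(h1, h1, h3, np.zeros(250, dtype=int),
                                  contigs={"chr1": 1000})
    out = fd_windows(m, panel, "P1", "P2", "P3", "O", window_snps=50)
    assert np.allclose(out.dropna(subset=["fd"]).fd, 0.0, atol=1e-12)


def test_fd_trailing_partial_window_dropped():
    h = RNG.integers(0, 2, size=130)
    m, panel = _four_taxon_matrix(h, h, h, np.zeros(130, dtype=int),
                                  contigs={"chr1": 1000})
    out = fd_windows(m, panel, "P1", "P2", "P3", "O", window_snps=100)
    assert len(out) <= 1  # 130 usable sites -> at most one full window


# ---------------------------------------------------------------------------
# IBD detection
# ---------------------------------------------------------------------------

def _pair_matrix(hap_a, hap_b, pos, contigs=None):
    H = np.vstack([hap_a, hap_a, hap_b, hap_b]).astype(np.int8)
    return matrix_from_haplotypes(H, pos=pos, samples=["x", "y"],
                                  contigs=contigs)


def bruteforce_runs_oracle(a, b, pos, min_snps, min_bp):
    """Maximal exact-identity runs (max_mismatch = 0) by direct scanning."""
    runs = []
    start = None
    for i in range(len(a)):
        same = a[i] == b[i]
        if same and start is None:
            start = i
        if (not same or i == len(a) - 1) and start is not None:
            end = i if same else i - 1
            n = end - start + 1
            span = pos[end] - pos[start] + 1
            if n >= min_snps and span >= min_bp:
                runs.append((int(pos[start] - 1), int(pos[end]), n))
            start = None
    return runs


def test_identical_haplotypes_single_tract():
    S = 500
    pos = np.sort(RNG.choice(np.arange(1, 1_000_000), size=S, replace=False))
    hap = RNG.integers(0, 2, size=S)
    m = _pair_matrix(hap, hap, pos, contigs={"chr1": 1_000_000})
    tr = detect_ibd(m, [("x", 0, "y", 0)], min_snps=50, min_bp=1000,
                    max_mismatch=0)
    assert len(tr) == 1
    assert tr.start[0] == pos[0] - 1 and tr.end[0] == pos[-1]
    assert tr.n_snps[0] == S


def test_opposite_haplotypes_no_tract():
    S = 300
    hap = RNG.integers(0, 2, size=S)
    m = _pair_matrix(hap, 1 - hap, np.arange(1, S + 1) * 100,
                     contigs={"chr1": 100_000})
    tr = detect_ibd(m, [("x", 0, "y", 0)], min_snps=10, min_bp=100,
                    max_mismatch=0)
    assert len(tr) == 0


def test_constructed_shared_block():
    """Sharing exactly sites 100..299 yields one tract with those bounds."""
    S = 500
    pos = np.arange(1, S + 1) * 1000
    a = np.zeros(S, dtype=np.int8)
    b = np.ones(S, dtype=np.int8)
    b[100:300] = 0  # identical on sites 100..299 only
    m = _pair_matrix(a, b, pos, contigs={"chr1": 600_000})
    tr = detect_ibd(m, [("x", 0, "y", 0)], min_snps=100, min_bp=1000,
                    max_mismatch=0)
    assert len(tr) == 1
    assert tr.n_snps[0] == 200
    assert tr.start[0] == pos[100] - 1 and tr.end[0] == pos[299]


def test_ibd_matches_bruteforce_on_random_pairs():
    for _ in range(30):
        S = int(RNG.integers(50, 300))
        pos = np.sort(RNG.choice(np.arange(1, 100_000), size=S, replace=False))
        a = RNG.integers(0, 2, size=S)
        flip = RNG.random(S) < 0.05
        b = np.where(flip, 1 - a, a)
        m = _pair_matrix(a, b, pos, contigs={"chr1": 100_000})
        got = detect_ibd(m, [("x", 0, "y", 0)], min_snps=10, min_bp=500,
                         max_mismatch=0)
        expected = bruteforce_runs_oracle(a, b, pos, 10, 500)
        assert len(got) == len(expected)
        for row, (s, e, n) in zip(got.itertuples(), expected):
            assert (row.start, row.end, row.n_snps) == (s, e, n)


def test_ibd_tracts_nonoverlapping_and_respect_budget():
    for _ in range(20):
        S = 400
        pos = np.arange(1, S + 1) * 250
        a = RNG.integers(0, 2, size=S)
        b = np.where(RNG.random(S) < 0.03, 1 - a, a)
        m = _pair_matrix(a, b, pos, contigs={"chr1": 110_000})
        tr = detect_ibd(m, [("x", 0, "y", 0)], min_snps=20, min_bp=2_000,
                        max_mismatch=1)
        assert (tr.n_mismatches <= 1).all()
        intervals = sorted(zip(tr.start, tr.end))
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2


def test_unphased_input_rejected():
    from conftest import matrix_from_genotypes
    m = matrix_from_genotypes(np.zeros((4, 10)))
    with pytest.raises(ValueError, match="phased"):
        detect_ibd(m, [("s0", 0, "s1", 0)])


# ---------------------------------------------------------------------------
# rIBD scan
# ---------------------------------------------------------------------------

def _toy_groups():
    panel = SamplePanel({"t1": "T", "t2": "T", "d1": "D", "s1": "S"})
    contigs = {"chr1": 30_000}
    return panel, contigs


def _tract(sa, ha, sb, hb, start, end, chrom="chr1"):
    return dict(sample_a=sa, hap_a=ha, sample_b=sb, hap_b=hb, chrom=chrom,
                start=start, end=end, n_snps=10, n_mismatches=0)


def test_ribd_direct_counting():
    """4 of 8 target x donor and 2 of 8 target x source pairs overlap the
    first bin: (0.5, 0.25, 0.25)."""
    panel, contigs = _toy_groups()
    donor = pd.DataFrame([
        _tract("t1", 0, "d1", 0, 0, 6_000),
        _tract("t1", 1, "d1", 0, 0, 6_000),
        _tract("t2", 0, "d1", 1, 2_000, 9_000),
        _tract("t2", 1, "d1", 1, 0, 5_000),
    ])
    source = pd.DataFrame([
        _tract("t1", 0, "s1", 0, 0, 4_000),
        _tract("t2", 1, "s1", 1, 1_000, 3_000),
    ])
    prof = ribd_scan(donor, source, panel, "T", "D", "S", contigs)
    first = prof.bins.iloc[0]
    assert first.nibd_donor == pytest.approx(0.5)
    assert first.nibd_source == pytest.approx(0.25)
    assert first.ribd == pytest.approx(0.25)


def test_ribd_all_and_none():
    panel, contigs = _toy_groups()
    full_donor = pd.DataFrame([
        _tract(t, h, "d1", hd, 0, 30_000)
        for t in ("t1", "t2") for h in (0, 1) for hd in (0, 1)])
    empty = pd.DataFrame(columns=full_donor.columns)
    prof = ribd_scan(full_donor, empty, panel, "T", "D", "S", contigs)
    assert np.allclose(prof.bins.nibd_donor, 1.0)
    assert np.allclose(prof.bins.nibd_source, 0.0)
    assert np.allclose(prof.bins.ribd, 1.0)
    prof0 = ribd_scan(empty, empty, panel, "T", "D", "S", contigs)
    assert np.allclose(prof0.bins.ribd, 0.0)


@given(st.lists(st.tuples(st.sampled_from(["t1", "t2"]), st.integers(0, 1),
                          st.integers(0, 1), st.integers(0, 28),
                          st.integers(1, 29)),
                max_size=20))
@settings(max_examples=40, deadline=None)
def test_ribd_bounds_fuzz(specs):
    """nIBD stays in [0, 1] and rIBD in [-1, 1] for arbitrary tract sets."""
    panel, contigs = _toy_groups()
    rows = []
    for s, h, hd, a, b in specs:
        lo, hi = sorted((a * 1000, b * 1000))
        if lo == hi:
            hi += 500
        rows.append(_tract(s, h, "d1", hd, lo, hi))
    donor = pd.DataFrame(rows, columns=list(_tract("t1", 0, "d1", 0, 0, 1).keys()))
    prof = ribd_scan(donor, donor.iloc[:0], panel, "T", "D", "S", contigs)
    assert (prof.bins.nibd_donor >= 0).all() and (prof.bins.nibd_donor <= 1).all()
    assert (prof.bins.ribd >= -1).all() and (prof.bins.ribd <= 1).all()


# ---------------------------------------------------------------------------
# segment calling / proportions / sweep windows
# ---------------------------------------------------------------------------

def _profile(bins):
    return RIBDProfile(bins=pd.DataFrame(bins, columns=["chrom", "start",
                                                        "end", "nibd_donor",
                                                        "nibd_source", "ribd"]),
                       n_pairs_donor=8, n_pairs_source=8)


def test_call_segments_merges_overlapping_bins():
    prof = _profile([("chr1", 0, 10_000, .9, 0, .9),
                     ("chr1", 5_000, 15_000, .8, 0, .8),
                     ("chr1", 10_000, 20_000, .1, 0, .1)])
    segs = call_segments(prof, 0.7)
    assert len(segs) == 1
    assert (segs.start[0], segs.end[0]) == (0, 15_000)
    assert segs.peak_ribd[0] == pytest.approx(0.9)


def test_call_segments_flat_zero_profile():
    prof = _profile([("chr1", i * 5_000, i * 5_000 + 10_000, 0, 0, 0.0)
                     for i in range(10)])
    assert len(call_segments(prof, 0.7)) == 0
    assert len(call_segments(prof, 1.0 + 1e-9)) == 0


def test_introgressed_proportion_examples():
    panel = SamplePanel({"t1": "T", "t2": "T"})
    contigs = {"chr1": 1000, "chr2": 1000}
    tracts = pd.DataFrame([
        _tract("t1", 0, "d1", 0, 0, 1000, chrom="chr1"),
        _tract("t1", 1, "d1", 1, 0, 1000, chrom="chr1"),
        # overlapping donors on the same haplotype count once
        _tract("t1", 0, "d2", 0, 0, 600, chrom="chr1"),
    ])
    prop = introgressed_proportion(tracts, panel, "T", contigs)
    assert prop["t1"] == pytest.approx(0.5)
    assert prop["t2"] == 0.0


def test_top_quantile_selection_and_ties():
    scores = pd.DataFrame({
        "chrom": [f"c{i}" for i in range(100)],  # distinct contigs: no merge
        "start": [0] * 100, "end": [10] * 100,
        "score": np.arange(1, 101)})
    top = top_quantile_windows(scores, 0.05)
    assert len(top) == 5
    assert set(top.chrom) == {f"c{i}" for i in range(95, 100)}
    assert len(top_quantile_windows(scores, 1.0)) == 100
    flat = scores.assign(score=7.0)
    assert len(top_quantile_windows(flat, 0.05)) == 0


def test_top_quantile_merges_adjacent_windows():
    scores = pd.DataFrame({
        "chrom": ["c1"] * 10, "start": np.arange(10) * 100,
        "end": np.arange(1, 11) * 100,
        "score": [1, 1, 9, 9, 1, 1, 1, 1, 1, 8]})
    top = top_quantile_windows(scores, 0.3)
    assert [(r.start, r.end) for r in top.itertuples()] == [(200, 400), (900, 1000)]
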
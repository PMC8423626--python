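"""Genotype-matrix container, VCF/panel I/O, the study's variant filters, and
windowing primitives shared by every scan.

Internal coordinates are 0-based half-open; VCF I/O converts to/from the
1-based convention.  Only biallelic SNPs are represented: multi-allelic and
indel records are dropped (with a count) on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel for missing allele / DP / GQ


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SamplePanel:
    """Sample -> group label (and optional analysis role) assignments.

    Roles are free-form but the scans recognize ``P1``, ``P2``, ``P3``,
    ``outgroup``, ``target``, ``donor`` and ``source``.
    """

    group: dict[str, str]
    role: dict[str, str] = field(default_factory=dict)

    def samples_in_group(self, label: str) -> list[str]:
        hits = [s for s, g in self.group.items() if g == label]
        if not hits:
            raise KeyError(f"no samples with group label {label!r} in panel")
        return hits

    def samples_with_role(self, role: str) -> list[str]:
        hits = [s for s, r in self.role.items() if r == role]
        if not hits:
            raise KeyError(f"no samples with role {role!r} in panel")
        return hits

    @classmethod
    def read(cls, path: str | Path) -> "SamplePanel":
        group: dict[str, str] = {}
        role: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"panel line needs >=2 columns: {line!r}")
                group[parts[0]] = parts[1]
                if len(parts) > 2 and parts[2]:
                    role[parts[0]] = parts[2]
        return cls(group=group, role=role)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, g in self.group.items():
                r = self.role.get(s, "")
                fh.write(f"{s}\t{g}\t{r}\n" if r else f"{s}\t{g}\n")


class VariantMatrix:
    """Biallelic-SNP genotype matrix (samples x sites) with per-call depth and
    quality and, optionally, phased haplotypes.

    Attributes
    ----------
    samples : list of sample ids (length n)
    chrom : (S,) array of contig names
    pos : (S,) int array, 1-based positions, strictly sorted by (chrom, pos)
    ref, alt : (S,) arrays of single bases
    haplotypes : (2n, S) int8 array in {0, 1, -1}; rows 2i, 2i+1 belong to
        sample i.  Present iff ``phased``.
    genotypes : (n, S) int8 dosage array in {0, 1, 2, -1}
    dp, gq : (n, S) int16 arrays, -1 where missing
    contigs : mapping contig name -> length in bp
    """

    def __init__(self, samples, chrom, pos, ref, alt, genotypes,
                 dp=None, gq=None, haplotypes=None, contigs=None,
                 phased: bool | None = None):
        self.samples = list(samples)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        n, S = self.genotypes.shape
        if len(self.samples) != n or len(self.pos) != S:
            raise ValueError("genotype matrix shape inconsistent with samples/sites")
        self.dp = None if dp is None else np.asarray(dp, dtype=np.int16)
        self.gq = None if gq is None else np.asarray(gq, dtype=np.int16)
        self.haplotypes = None if haplotypes is None else np.asarray(haplotypes, dtype=np.int8)
        self.phased = (self.haplotypes is not None) if phased is None else phased
        self.contigs = dict(contigs) if contigs else self._infer_contigs()
        self._check_sorted()
        if self.haplotypes is not None:
            gt = np.where((self.haplotypes[0::2] == MISSING) | (self.haplotypes[1::2] == MISSING),
                          MISSING,
                          self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)
            if not np.array_equal(gt, self.genotypes):
                raise ValueError("phased haplotypes inconsistent with genotype dosages")

    # -- basic properties ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def _infer_contigs(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in pd.unique(self.chrom):
            out[str(c)] = int(self.pos[self.chrom == c].max()) if self.n_sites else 0
        return out

    def _check_sorted(self) -> None:
        seen: list = []
        for c in self.chrom:
            if not seen or seen[-1] != c:
                if c in seen:
                    raise ValueError(f"sites not grouped by contig near {c}")
                seen.append(c)
        for c in seen:
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly sorted on {c}")

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in samples], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None

    def hap_indices(self, samples: Sequence[str]) -> np.ndarray:
        """Haplotype-row indices (2 per sample) for *samples*; phased only."""
        if self.haplotypes is None:
            raise ValueError("matrix has no phased haplotypes; provide a phased VCF")
        si = self.sample_indices(samples)
        return np.column_stack([2 * si, 2 * si + 1]).ravel()

    # -- subsetting ---------------------------------------------------------
    def take_sites(self, mask_or_index) -> "VariantMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantMatrix(
            self.samples, self.chrom[idx], self.pos[idx], self.ref[idx],
            self.alt[idx], self.genotypes[:, idx],
            None if self.dp is None else self.dp[:, idx],
            None if self.gq is None else self.gq[:, idx],
            None if self.haplotypes is None else self.haplotypes[:, idx],
            contigs=self.contigs, phased=self.phased)

    # -- per-site summaries -------------------------------------------------
    def alt_counts(self, sample_idx=None):
        """(alt allele count, called allele count) per site over given samples."""
        G = self.genotypes if sample_idx is None else self.genotypes[sample_idx]
        called = G != MISSING
        alt = np.where(called, G, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def maf(self) -> np.ndarray:
        alt, n = self.alt_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def het_fraction(self) -> np.ndarray:
        """Heterozygous calls / called genotypes per site (0 where no calls)."""
        called = (self.genotypes != MISSING).sum(axis=0)
        het = (self.genotypes == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, het / np.maximum(called, 1), 0.0)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int  # 0-based, inclusive
    end: int    # exclusive
    n_sites: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"degenerate window {self.chrom}:{self.start}-{self.end}")


def make_windows(contigs: Mapping[str, int], size: int, step: int | None = None
                 ) -> list[GenomicWindow]:
    """Sliding windows of *size* bp advanced by *step* bp over each contig.

    A contig no longer than *size* yields a single window covering it; otherwise
    window starts run 0, step, 2*step, ... while start < contig length, with the
    final window truncated at the contig end.
    """
    step = size if step is None else step
    if size <= 0:
        raise ValueError("window size must be positive")
    if step <= 0 or step > size:
        raise ValueError("need 0 < step <= size")
    out: list[GenomicWindow] = []
    for name, length in contigs.items():
        if length <= 0:
            continue
        if length <= size:
            out.append(GenomicWindow(name, 0, int(length)))
            continue
        for start in range(0, length, step):
            out.append(GenomicWindow(name, start, min(start + size, length)))
    return out


def assign_sites(m: VariantMatrix, windows: Sequence[GenomicWindow]) -> list[np.ndarray]:
    """Site indices of *m* contained in each window (0-based window bounds vs
    1-based site positions: site at pos p lies in [start, end) iff start < p <= end)."""
    by_chrom: dict[str, np.ndarray] = {}
    for c in m.contigs:
        by_chrom[c] = np.flatnonzero(m.chrom == c)
    out = []
    for w in windows:
        idx = by_chrom.get(w.chrom, np.array([], dtype=np.intp))
        if idx.size:
            p = m.pos[idx]
            lo = np.searchsorted(p, w.start + 1, side="left")
            hi = np.searchsorted(p, w.end, side="right")
            out.append(idx[lo:hi])
        else:
            out.append(idx)
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """The study's genotype- and site-level thresholds.

    Individual calls failing ``min_depth``/``min_gq`` are masked to missing
    first; the site-level minor-allele-frequency (>=), missing-fraction (<=)
    and heterozygous-rate (<, strict) filters are then applied to the masked
    matrix.
    """

    min_depth: int = 4
    min_gq: int = 5
    min_maf: float = 0.05
    max_missing: float = 0.1
    max_het: float = 0.1

    def __post_init__(self):
        if self.min_depth < 0 or self.min_gq < 0 or self.min_maf < 0:
            raise ValueError("thresholds must be >= 0")
        for frac in (self.min_maf, self.max_missing, self.max_het):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractional thresholds must lie in [0, 1]")


@dataclass
class FilterReport:
    n_in: int
    n_out: int
    calls_masked_dp: int = 0
    calls_masked_gq: int = 0
    sites_removed_maf: int = 0
    sites_removed_missing: int = 0
    sites_removed_het: int = 0
    sites_removed_monomorphic: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def filter_variants(m: VariantMatrix, spec: FilterSpec = FilterSpec()
                    ) -> tuple[VariantMatrix, FilterReport]:
    """Apply genotype masking then site filters; returns the surviving matrix
    and a per-criterion removal report.  A site failing several criteria is
    counted once per criterion it fails."""
    rep = FilterReport(n_in=m.n_sites, n_out=0)
    G = m.genotypes.copy()
    H = None if m.haplotypes is None else m.haplotypes.copy()
    dp, gq = m.dp, m.gq

    mask = np.zeros_like(G, dtype=bool)
    if spec.min_depth > 0 and dp is not None:
        bad = (dp != MISSING) & (dp < spec.min_depth) & (G != MISSING)
        rep.calls_masked_dp = int(bad.sum())
        mask |= bad
    if spec.min_gq > 0 and gq is not None:
        bad = (gq != MISSING) & (gq < spec.min_gq) & (G != MISSING)
        rep.calls_masked_gq = int(bad.sum())
        mask |= bad
    if mask.any():
        G[mask] = MISSING
        if H is not None:
            H[np.repeat(mask, 2, axis=0)] = MISSING

    masked = VariantMatrix(m.samples, m.chrom, m.pos, m.ref, m.alt, G,
                           dp, gq, H, contigs=m.contigs, phased=m.phased)

    maf = masked.maf()
    miss = masked.missing_fraction()
    het = masked.het_fraction()

    with np.errstate(invalid="ignore"):
        ok_maf = maf >= spec.min_maf
    ok_maf &= ~np.isnan(maf)
    ok_miss = miss <= spec.max_missing
    ok_het = het < spec.max_het
    keep = ok_maf & ok_miss & ok_het
    rep.sites_removed_maf = int((~ok_maf).sum())
    rep.sites_removed_missing = int((~ok_miss).sum())
    rep.sites_removed_het = int((~ok_het).sum())
    out = masked.take_sites(keep)
    rep.n_out = out.n_sites
    if out.n_sites == 0:
        logger.warning("filter_variants: no sites survive the filters")
    logger.info("filter_variants: %d -> %d sites", rep.n_in, rep.n_out)
    return out, rep


# ---------------------------------------------------------------------------
# per-site allele statistics (shared kernel of pi, Fst, D, fd)
# ---------------------------------------------------------------------------

def site_allele_stats(m: VariantMatrix, samples: Sequence[str]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (alt count, called alleles, alt frequency) over *samples*.

    Missing calls are excluded from denominators; sites with no called alleles
    get frequency NaN and must be excluded downstream.
    """
    if not len(samples):
        raise ValueError("empty sample group")
    idx = m.sample_indices(samples)
    alt, n = m.alt_counts(idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return alt, n, freq


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, panel_path: str | Path | None = None
             ) -> tuple[VariantMatrix, SamplePanel | None]:
    """Read a VCF into a :class:`VariantMatrix` (biallelic SNPs only).

    Multi-allelic and non-SNP records are skipped with a logged count; phase
    is preserved when every genotype is phased.  Raises on unsorted input or
    records without GT.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    contigs: dict[str, int] = {}
    if vcf.seqnames and vcf.seqlens:
        contigs = {str(c): int(l) for c, l in zip(vcf.seqnames, vcf.seqlens)}

    chrom, pos, ref, alt = [], [], [], []
    hap_cols, dp_cols, gq_cols = [], [], []
    n_skipped = 0
    phased = True
    last: tuple[str, int] | None = None
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        key = (rec.CHROM, rec.POS)
        if last is not None and last[0] == key[0] and key[1] <= last[1]:
            raise ValueError(f"VCF not sorted at {rec.CHROM}:{rec.POS}")
        last = key
        gts = rec.genotype.array()  # (n, 3): allele0, allele1, phased flag
        if gts is None:
            raise ValueError("VCF record lacks GT field")
        a0 = gts[:, 0].astype(np.int8)
        a1 = gts[:, 1].astype(np.int8)
        a0[a0 < 0] = MISSING
        a1[a1 < 0] = MISSING
        called = (a0 != MISSING) & (a1 != MISSING)
        if called.any() and not np.all(gts[called, 2] > 0):
            phased = False
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        hap_cols.append(np.column_stack([a0, a1]).ravel())
        try:
            d = rec.format("DP")
        except KeyError:
            d = None
        dp_cols.append(None if d is None else d[:, 0])
        try:
            q = rec.format("GQ")
        except KeyError:
            q = None
        gq_cols.append(None if q is None else q[:, 0])
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)

    S = len(pos)
    logger.info("read_vcf: %d sites, %d samples", S, len(samples))
    n = len(samples)
    H = (np.stack(hap_cols, axis=1) if S else np.zeros((2 * n, 0), dtype=np.int8))

    def _stack(cols, fill=MISSING):
        if S == 0:
            return np.full((n, 0), fill, dtype=np.int16)
        if all(c is None for c in cols):
            return None
        out = np.full((n, S), fill, dtype=np.int16)
        for j, c in enumerate(cols):
            if c is not None:
                v = np.asarray(c, dtype=np.float64)
                v = np.where(np.isnan(v) | (v < 0), MISSING, v)
                out[:, j] = v.astype(np.int16)
        return out

    dp = _stack(dp_cols)
    gq = _stack(gq_cols)
    G = np.where((H[0::2] == MISSING) | (H[1::2] == MISSING), MISSING,
                 H[0::2] + H[1::2]).astype(np.int8)
    m = VariantMatrix(samples, chrom, pos, ref, alt, G, dp, gq,
                      haplotypes=H if phased else None,
                      contigs=contigs or None, phased=phased)
    panel = None
    if panel_path is not None:
        panel = SamplePanel.read(panel_path)
        missing = [s for s in samples if s not in panel.group]
        if missing:
            raise ValueError(f"panel missing samples: {missing[:5]} ...")
        extras = [s for s in panel.group if s not in samples]
        if extras:
            logger.warning("panel has %d samples absent from VCF", len(extras))
    return m, panel


def write_vcf(m: VariantMatrix, path: str | Path) -> None:
    """Write a VCF 4.2 with GT[:DP:GQ]; phased matrices use '|' separators.

    Output is a pure function of the matrix, so equal matrices give
    byte-identical files.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscan\n")
        for c, l in m.contigs.items():
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        has_dpgq = m.dp is not None and m.gq is not None
        if has_dpgq:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.samples) + "\n")
        sep = "|" if m.phased else "/"
        fmt = "GT:DP:GQ" if has_dpgq else "GT"
        for j in range(m.n_sites):
            fields = [str(m.chrom[j]), str(m.pos[j]), ".", str(m.ref[j]),
                      str(m.alt[j]), ".", "PASS", ".", fmt]
            for i in range(m.n_samples):
                if m.haplotypes is not None:
                    a0, a1 = m.haplotypes[2 * i, j], m.haplotypes[2 * i + 1, j]
                    gt = ("." if a0 == MISSING else str(a0)) + sep + \
                         ("." if a1 == MISSING else str(a1))
                else:
                    g = m.genotypes[i, j]
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(g), "./.")
                if has_dpgq:
                    d = m.dp[i, j]
                    q = m.gq[i, j]
                    gt += ":" + ("." if d == MISSING else str(d))
                    gt += ":" + ("." if q == MISSING else str(q))
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")
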
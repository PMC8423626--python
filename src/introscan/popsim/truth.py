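"""Local-ancestry ground truth emitted by the simulator."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class AncestryTruth:
    """Exact local-ancestry tracts for every sampled haplotype.

    ``tracts`` has columns (chrom, start, end, sample, hap, label) with
    0-based half-open coordinates; per haplotype and chromosome the tracts
    tile the chromosome exactly.  ``label`` is the group label of the deme in
    which the lineage resided at its most recent founding or migration event,
    so admixture-derived material carries the donor deme's label.
    """

    tracts: pd.DataFrame
    sample_group: dict[str, str]
    contigs: dict[str, int]

    @property
    def genome_bp(self) -> int:
        return int(sum(self.contigs.values()))

    def donor_bp(self, donor_label: str) -> pd.Series:
        """Donor-labeled bp per sample (summed over both haplotypes)."""
        t = self.tracts
        sel = t[t["label"] == donor_label]
        bp = (sel["end"] - sel["start"]).groupby(sel["sample"]).sum()
        return bp.reindex(sorted(self.sample_group), fill_value=0)

    def write(self, path: str | Path) -> None:
        """BED-like TSV: chrom, start (0-based half-open), end, sample, hap, label."""
        self.tracts.to_csv(path, sep="\t", index=False,
                           columns=["chrom", "start", "end", "sample", "hap", "label"])

    @classmethod
    def read(cls, path: str | Path, sample_group: dict[str, str],
             contigs: dict[str, int]) -> "AncestryTruth":
        return cls(pd.read_csv(path, sep="\t"), dict(sample_group), dict(contigs))


def windowed_donor_frequency(truth: AncestryTruth, group: str,
                             donor_label: str, windows) -> np.ndarray:
    """Mean frequency of *donor_label* ancestry among *group* haplotypes in
    each window (fraction of haplotype-bp that is donor-labeled).

    Useful for scoring group-level introgression scans: a windowed scan is
    designed to see ancestry segregating at appreciable frequency, not every
    single-haplotype tract.
    """
    samples = [s for s, g in truth.sample_group.items() if g == group]
    if not samples:
        raise KeyError(f"no samples in group {group!r}")
    n_hap = 2 * len(samples)
    t = truth.tracts
    sel = t[(t["label"] == donor_label) & t["sample"].isin(samples)]
    by_chrom = {c: g for c, g in sel.groupby("chrom")}
    out = np.zeros(len(windows))
    for i, w in enumerate(windows):
        g = by_chrom.get(w.chrom)
        if g is None:
            continue
        ov = (np.minimum(g["end"].to_numpy(), w.end)
              - np.maximum(g["start"].to_numpy(), w.start)).clip(min=0)
        out[i] = ov.sum() / (n_hap * (w.end - w.start))
    return out


def realized_admixture(truth: AncestryTruth, recipient_group: str,
                       donor_label: str) -> pd.Series:
    """Fraction of each recipient-group sample's diploid genome carrying
    *donor_label* ancestry: donor bp / (2 x genome bp), in [0, 1]."""
    samples = [s for s, g in truth.sample_group.items() if g == recipient_group]
    if not samples:
        raise KeyError(f"no samples in group {recipient_group!r}")
    denom = 2 * truth.genome_bp
    t = truth.tracts
    sel = t[(t["label"] == donor_label) & t["sample"].isin(samples)]
    bp = (sel["end"] - sel["start"]).groupby(sel["sample"]).sum()
    frac = (bp / denom).reindex(sorted(samples), fill_value=0.0)
    frac.name = "donor_fraction"
    return frac
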
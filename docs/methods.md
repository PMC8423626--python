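# Methods

`introscan` implements the population-genomic machinery used to dissect the
origin and gene-flow history of a selfing allotetraploid crop panel:
variant filtering, diversity/differentiation/LD scans, ABBA–BABA and f_d
gene-flow statistics, IBD-based rIBD introgression mapping, Ks/2μ dating,
and candidate-gene haplotype grouping — all exercised end-to-end against a
forward Wright–Fisher simulator with exact local-ancestry bookkeeping.

## Estimators

**Nucleotide diversity.** Per site, the unbiased pairwise estimator
π = 2·j·(n−j)/(n·(n−1)) for j derived alleles among n called alleles;
windowed π sums site values over the window's bp length (the semantics of
the common windowed-π tools). Missing calls are excluded from denominators.

**F_ST.** Weir & Cockerham's (1984) θ for two populations from the a, b, c
variance components with the observed-heterozygosity correction; windows and
the genome-wide value use ratio-of-sums ("weighted") aggregation. θ can be
slightly negative by construction when differentiation is absent.

**D_xy.** Mean between-group per-bp difference Σ p_a(1−p_b) + p_b(1−p_a)
over the window length. The pairwise genetic distance printed by common
population-genetics suites is not uniquely defined; D_xy is implemented and
labeled as such.

**LD decay.** Squared Pearson correlation of unphased allele dosages
(0/1/2) over pairwise-complete samples, aggregated into 50 equal-width
distance bins to 500 kb by default, with group-level MAF ≥ 0.05 and
missingness ≤ 0.1 re-applied first — matching the conventions of the
standard LD-decay tools run on genotype VCFs.

**PCA.** Dosages centered at 2p and standardized by √(p(1−p)) with
mean-imputed missing calls (the GCTA convention), then an SVD.

**ABBA–BABA D.** With taxa (((P1,P2),P3),O) and per-group allele
frequencies p̂, sites are polarized so the outgroup *major* allele is
ancestral; sites where the outgroup minor-allele frequency exceeds 0.1 are
excluded. D = Σ[(1−p̂₁)p̂₂p̂₃(1−p̂_O) − p̂₁(1−p̂₂)p̂₃(1−p̂_O)] /
Σ[(1−p̂₁)p̂₂p̂₃(1−p̂_O) + p̂₁(1−p̂₂)p̂₃(1−p̂_O)]; D > 0 means excess
P2–P3 sharing. Significance is a delete-one-block jackknife over contiguous
500-SNP blocks (configurable); Z = D/SE against a standard normal.

**f_d.** The dynamic-donor formulation: per 100-SNP window,
f_d = S(P1,P2,P3,O)/S(P1,P_D,P_D,O) where S is the D numerator and P_D is,
per site, whichever of P2/P3 has the higher derived frequency. Windows are
consecutive non-overlapping blocks of exactly 100 usable SNPs per
chromosome; a trailing partial window is dropped. Values outside (0,1) are
retained but flagged as non-gene-flow.

**IBD detection.** A deterministic identity-run scan on phased haplotypes
rather than a probabilistic HMM: for each haplotype pair and chromosome,
maximal runs over jointly-called sites containing at most `max_mismatch`
mismatches (default 1), spanning ≥ `min_bp` (default 100 kb) with ≥
`min_snps` sites (default 50), trimmed to matching end sites; a
non-overlapping subset is chosen greedily by bp length. Determinism makes
the downstream rIBD layer exactly testable; all parameters are exposed.

**rIBD.** Chromosomes are cut into 10-kb bins advanced by 5 kb. Per bin,
nIBD_X = (haplotype pairs between the target group and group X with a tract
overlapping the bin, ≥1 bp) / (all target×X haplotype pairs) ∈ [0,1], and
rIBD = nIBD_donor − nIBD_source ∈ [−1,1]. Segment calling merges runs of
overlapping bins with rIBD above a threshold; per-sample introgressed
proportions are the union of a sample's donor-IBD tract bp over both
haplotypes divided by 2× genome length.

**Calling threshold.** The strict default rule (rIBD > 0.7) targets introgressed
blocks that are nearly fixed in the recipient group. For a *diffuse* neutral
pulse the attainable rIBD is bounded by the introgressed-haplotype
frequency (≈ the pulse fraction), so 0.7 cannot fire by construction; the
recovery experiments therefore recalibrate to threshold 0 — any positive
donor excess — which is sound here because target×donor IBD at the
detector's tract scale is structurally impossible without recent gene flow
(the no-pulse calibration run shows essentially zero donor tracts and zero
segments at the strict threshold).

**Sweep-window selection.** Windows whose externally computed score
strictly exceeds the empirical (1−q) quantile (lower interpolation,
q = 0.05 default), merged when adjacent; all-equal scores select nothing.

**Dating and LAI.** T = Ks/(2μ) × generation time, bracketed by
μ ∈ [9×10⁻⁹, 1.5×10⁻⁸] per synonymous site per year; the larger μ gives the
younger bound. LAI = 100 × intact LTR-RT length / total LTR-RT length.
Ks itself is an input (computed by external Ka/Ks tools).

**Haplotype groups.** Allele strings over a region's sites among
fully-called samples (phased: both haplotypes; unphased: homozygous samples
only, heterozygous ones set aside), ranked by frequency and retained at
frequency strictly > 0.01; compared across phenotypes by two-sided Welch
t-tests per environment, without pooling.

## The simulator

A discrete-generation Wright–Fisher forward simulator. Haplotypes carry a
sorted array of derived-mutation positions (infinite sites on integer bp;
collisions re-drawn) plus an exact ancestry track. Meiosis draws
Poisson(r·L) crossovers per chromosome without interference and assorts
chromosomes independently; selfing is the probability of drawing the same
parent twice. Splits found a deme from parent-deme individuals (ancestry
relabeled to the new deme); an admixture pulse redirects each parent choice
to the source deme with probability α, so donor-labeled tracts enter the
recipient and are inherited exactly thereafter. DP ~ Poisson(depth_mean),
GQ ~ uniform integers, and missingness masks GT/DP/GQ jointly. Identical
(configuration, seed) runs are bit-identical. Mutations fixed in every live
haplotype are pruned periodically; they could never be polymorphic among
the sampled panel, and pruning keeps meiosis cost bounded.

### Study conditions (defaults)

The bundled scenario emulates, at desk scale, the structure of the crop
panel: a leaf-mustard-like source group (G5, 150 diploids, the ancestral
root), an outgroup split 1,200 generations ago, a small yellow-seeded donor
group (G2, 20 diploids) split 400 generations ago, and a recipient group
(G4, 250 diploids) founded 150 generations ago that receives a donor pulse
of α = 0.15 fifty generations before sampling. Genome 10 × 1 Mb; per-bp
rates μ = 3×10⁻⁷ and r = 2×10⁻⁸ per generation; selfing rate 0.9
(inbred accessions: keeps per-site heterozygosity under the 0.1 filter
ceiling, as in the real panel); 20 diploids sampled per group; depth mean
15×, 5% missingness, GQ ∈ [20,99]. These numbers were chosen once so that
the scaled-down panel reproduces the *qualitative* regime of the study
system — thousands of filtered SNPs, incomplete lineage sorting deep enough
that ABBA–BABA is informative, IBD tracts detectable against the mismatch
budget, pulse ancestry surviving drift at roughly the documented
per-accession proportions (the real panel's range is 0.07–0.26) — with
runtimes of tens of seconds per replicate.

### What the scaling preserves and what it does not

Deme sizes are scaled down to tens–hundreds with per-bp rates raised;
θ = 4Nμ and the qualitative split structure are preserved, absolute π is
~10× below the real panel's 10⁻³. Two desk-scale limitations matter:

* **Drift at the pulse.** With scaled Ne, the 50 generations between pulse
  and sampling drift the realized admixture fraction substantially (whole
  replicates can lose or double the nominal 0.15); recovery experiments
  therefore compare against the *realized* ancestry-truth mean, and the
  documented-seed experiment uses a replicate with typical retention.
* **Pedigree correlation of D.** In the rIBD scenario every chromosome of
  the 20-diploid donor deme flows through the same few pedigree ancestors,
  so ABBA–BABA genealogies are correlated *across* chromosomes; no
  jackknife block size can then scale Z correctly, and null |Z| can exceed
  3 with appreciable probability. The D-statistic calibration and power
  experiments therefore use a second bundled scenario
  (`calibration_demography`/`calibration_genome`: four equal 80-diploid
  demes, splits 600/200/100 generations, 10 × 1 Mb, μ = 2.5×10⁻⁷,
  r = 2×10⁻⁷, selfing 0.5) in which each chromosome carries many
  independent genealogies (ρ per chromosome ≈ 100) and the null Z is well
  scaled. Even there, the between-replicate coalescent variance of D keeps
  the power of |Z| > 3 against an α = 0.15 pulse below the asymptotic
  ideal (the power test asserts the attainable level). Real panels with
  large Ne do not share these limits; conversely, IBD-tract detection at
  desk-scale SNP densities requires near-zero within-tract recombination,
  so one configuration cannot be simultaneously ideal for both statistics
  — hence the two scenarios.

### Recovery-truth definitions

The bp-union of *all* donor tracts degenerates as a truth set: under drift,
single-haplotype tracts can touch the entire genome, making union-based
precision trivially 1 and recall unachievable for any group-level scan.
Segment recovery is therefore scored window-wise: precision counts a called
bin as correct if it overlaps *any* genuine donor tract (an IBD hit on a
real tract is not a false positive), while recall is demanded only of
regions where donor ancestry segregates at ≥ 10% haplotype frequency in
the target group — the regime a normalized pair-counting scan is designed
to see. The same ≥ 10% rule labels "truly introgressed" f_d windows.

## Numerical and edge-case choices

Internal coordinates are 0-based half-open; VCF I/O converts to 1-based.
Sites with MAF exactly at the threshold are kept (≥); heterozygosity uses a
strict <. Genotype-level DP/GQ masking happens before site-level filters,
so masking can push a site over the missingness or under the MAF threshold.
A contig shorter than the window size yields a single truncated window.
Zero-variance site pairs give undefined r² and are skipped; zero jackknife
SE is flagged degenerate (Z undefined); an empty ABBA+BABA denominator
raises rather than returning 0/0. Window/tract intersection requires ≥ 1 bp
of overlap. PCA is deterministic up to the sign of each component.

## Scope limits

No selection, structural variants, multi-allelic sites or gene conversion
in the simulator; subgenomes of the allotetraploid are emulated simply as
distinct chromosome sets. Phasing, variant calling, Ks computation,
XP-CLR score computation, TreeMix/f-branch graph statistics and
demographic-curve inference are out of scope; the sweep module only
performs top-quantile window selection on externally supplied scores.
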
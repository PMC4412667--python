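# Methods

`setrcall` calls genome-wide copy-number variants (CNV), loss of
heterozygosity (LOH) and uniparental isodisomy (UPD) from sparse
targeted-sequencing panels — short (~150 bp) capture probes laid out
roughly every 10 kb across the genome — using the median across a
collection of unmatched samples in place of a matched control.  This
note records the model, the choices that were genuinely open, and what
the synthetic benchmark does and does not demonstrate.

## Depth model and normalization

For each target region *i*, the mean depth is `TD_i = bases_i / len_i`.
The observed depth of a probe is modeled as

    TD_i  ≈  D · e_i · (CN_i / 2) · ε,

where `D` is the sample's average depth, `e_i` a probe-specific capture
efficiency (a property of the probe chemistry, shared by all samples
sequenced with the same panel), `CN_i` the local copy number and `ε`
counting noise.  Two corrections isolate `CN_i/2`:

1. **Smoothing** — `TD_mi` is the mean of `TD` over target *i* and the
   `n = 10` following targets on the same chromosome (11 values; the
   window truncates at the chromosome end, with the divisor equal to
   the actual window size, and never crosses chromosomes).
2. **Ratio + panel baseline** — `R_i = TD_mi / mean(TD_m over
   autosomes)` removes library size; `R_mi = R_i / median_panel(R_i)`
   removes `e_i`, because the per-target median of `R_i` across ≥ 8
   samples is a robust estimate of the shared efficiency profile.

The diagnostic `preR_i = TD_i / mean(TD)` is kept alongside: it carries
no smoothing, so its probe-to-probe values are statistically
independent — which the caller exploits below.  The autosomal-only
divisor keeps a male sample's halved chrX from deflating the scale; X/Y
targets still receive ratios and feed sex inference (chrX mean ratio
≈ 1 → XX, ≈ 0.5 with chrY coverage → XY, ambiguous band [0.65, 0.85]
flagged).

The 8-sample panel minimum is enforced because a median over fewer
random samples is no longer reliably anchored by copy-neutral carriers
at any one locus.  When the test sample is itself a panel member, its
baseline is the leave-one-out median of the others, so a large event
cannot suppress itself.  Targets with zero depth in more than half the
panel are masked genome-wide.

## CNV calling

Per probe, the test ratio is compared with the panel:

    t = (R_mi,test − mean(R_mi,panel)) / sqrt(S²_panel · (1 + 1/n)),

with `n − 1` degrees of freedom and a two-sided p.  Sliding windows of
4 consecutive same-chromosome probes whose t-scores share one sign,
with ≥ 3 p-values < 0.05 and any remaining p ≤ 0.2, mark all four
probes with a '+'/'−' pseudo-signal; same-sign marked runs separated by
≤ 5 unmarked probes merge (gap probes included).  Each merged candidate
is re-tested with a one-sample t on `Z_i = R_mi,test − mean(R_mi,panel)`
over the interval (df = m − 1).

**Error control (this package's own addition).**  The smoothing window
makes neighbouring `R_m` values share 10 of 11 depth draws, so a single
lucky window masquerades as a sustained multi-probe run; under pure
Poisson noise the chain above admits roughly one spurious candidate per
sample per 12,000 probes, at any depth.  Each candidate is therefore
confirmed by a second one-sample t computed on the *unsmoothed* ratio
(`preR` normalized by the panel's `preR` median), whose probe-to-probe
independence makes the reference distribution honest, at a
Bonferroni-corrected threshold `p / n_targets` (the candidate is the
most extreme of a genome-wide scan).  Real events clear this by many
orders of magnitude (a 45-probe deletion at 8X has p ≈ 1e-16 against a
4e-6 threshold); noise excursions (p ≈ 1e-2) cannot.  A candidate whose
median smoothed ratio still rounds to copy number 2 is discarded as a
copy-neutral fluctuation.

**Boundaries and CN.**  Downstream smoothing drags a call's start
upstream of the true edge by up to ~10 probes, so each edge is re-fit
on the unsmoothed ratio by a least-squares changepoint within ± 12
probes (cost: distance to 1 outside, distance to the event level
inside).  The integer copy number is `CN = round_half_up(mean ratio /
0.5)` with the mean taken over the refined interval on the unsmoothed
track (the smoothed mean is biased toward 1 near edges).  Reported
calls must satisfy the region p threshold, a minimum probe count
(default 45) and a minimum size (default 1 Mb); a chromosome with
≥ 90% of its probes inside same-direction calls is reported as an
aneuploidy, which feeds the ISCN-style karyotype string
(e.g. `46,XY,del(5)(p14)`, `48,XXX,+18`).

## LOH and UPD

At known polymorphic sites with population allele frequency in
[0.1, 0.9], the B-allele frequency folds into the heterozygosity
coefficient `R_Het = min(BAF/(1−BAF), (1−BAF)/BAF)` — 1 at perfect
heterozygosity, 0 at homozygosity, symmetric in BAF ↔ 1−BAF.  Sites
need ≥ 10 reads for a usable BAF.  The per-site median `R_Het` across
the panel (leave-one-out for panel members; masked when usable in < 8
samples) is the baseline.

A window of `W = 25` consecutive usable sites slides one site at a
time, never crossing chromosomes.  The test window's sample variance is
compared with the baseline window's via

    F_upper = S²_max / S²_min,  F_under = S²_min / S²_max,
    p = P(F > F_upper) + (1 − P(F > F_under)),   df = (W−1, W−1),

clipped to 1; equal variances give p = 1, and a zero minimum variance
(total collapse of dispersion) floors p at the smallest representable
value with a degeneracy flag.  As printed, this two-sided construction
is anti-conservative under the median baseline: an individual's
genotype-driven `R_Het` (bimodal near 0/1) systematically out-disperses
the panel median, producing a ~28% null hit rate at p < 0.01.  A
directional gate therefore restricts *seeding*: an anchor may start an
interval only if the test window has both lower mean and lower variance
than the baseline window — the two signatures of true LOH — which
brings the null seedable-anchor rate to ~0.02%.

Intervals initiate at 3 consecutive significant anchors (p < 0.01),
then extend greedily in both directions over ungated p-values: anchors
with p < 0.01 are always absorbed; a single anchor with p ≥ 0.01 may be
absorbed if the interval's running mean p stays < 0.1; two consecutive
failures stop the extension, and an interval never ends on a tolerated
excursion.  Scan and extension run in *window* space — sites with no
window (low depth, masked baseline) are skipped, not treated as run
breaks — and extended intervals separated by ≤ 5 anchors are bridged,
mirroring the CNV merge heuristic; without this, local baseline
dropouts fragment real events below the reporting floor.

Classification intersects LOH with CNV: the copy number with majority
overlap decides — CN 2 (including no overlapping CNV call) → UPD
(isodisomy); any other CN → LOH_nonUPD.  Intervals below 5 Mb are not
reported.  As a QC cross-check, every reportable CN = 1 call must
overlap an LOH call (one haplotype cannot be heterozygous); violations
are surfaced as warnings and recorded in the run manifest.  A
balanced-allele three-copy region pulls `R_Het` toward 0.5 (BAF 1/3 or
2/3), a useful visual corroboration of gains on the exported tracks.

## Probe design

The four-stage selection emulates how such a panel is built: (1) keep
SNPs with population AF in the closed interval [0.10, 0.90] and drop
any site within 100 bp of a previously kept one; (2) keep sites whose
101-base flank (50 each side) occurs exactly once in the genome and has
no second locus above 95% identity — implemented with an exact 101-mer
index plus an edit-distance screen over loci sharing 20-mer seeds,
which is deterministic and reproducible where an external aligner's
scoring is not; (3) keep at most one SNP per 10 kb bin, preferring the
site nearest the bin center (tie → lower coordinate); (4) insert
`max(1, floor(gap/spacing) − 1)` evenly spaced filler anchors into any
gap wider than the spacing, sliding each by up to spacing/2 to the
nearest 150 bp window with GC in [0.3, 0.7] and no homopolymer run of
10+ (numbers chosen as conventional probe-design limits; skipped gaps
are logged).  Each anchor becomes a 150 bp probe centered on it,
clipped at contig edges; on overlap the SNP-sourced probe wins.

## Synthetic data

The simulator generates exactly what the callers consume, at count
level: a regular probe grid (default 10 kb spacing, 150 bp probes, one
SNP per probe with AF uniform on [0.1, 0.9]); per-probe efficiencies
`e_i ~ lognormal(0, 0.4)` drawn once and shared across samples;
per-probe depth `~ Poisson(D · e_i · CN/2)`; genotypes Hardy–Weinberg
at the site AF, collapsed to homozygous inside LOH/UPD/hemizygous-
deletion truth and moved to BAF 1/3 or 2/3 for heterozygotes inside
three-copy truth; alt counts `~ Binomial(depth_site, BAF_target)` with
a 0.002 sequencing-error floor so homozygous sites are never exactly
0/1.  Everything is deterministic under a seed, and truth tables are
structurally validated on write.

The benchmark preset mirrors the method's validation design: 8 samples,
two 60 Mb chromosomes, ~30X, 9 CNV events (CN 1 or 3, 450 kb–3 Mb)
across 3 carrier samples with 5 normals.  Implants are placed at
distinct loci across samples — the method's stated premise is that
aberrations do not co-localize across a random collection — separated
by ≥ 50 probes and ≥ 20 probes from chromosome ends so each implant is
an independent test case.  The LOH preset implants one ≥ 5 Mb UPD and
one ≥ 5 Mb hemizygous deletion on a 30 Mb chromosome of an 8-sample
panel; the null preset implants nothing.

What the simulator deliberately omits: GC-dependent coverage curves,
alignment and mappability artifacts, PCR duplication structure,
over-dispersion beyond Poisson, linkage between neighbouring sites, and
mosaic (fractional) copy states.  Passing the synthetic benchmark shows
the statistical machinery is correct under the stated noise model; it
does not certify performance on real capture data, where the panel
median must absorb additional systematic structure.

## Problem sizes and validation studies

The packaged studies use desk-scale sizes chosen to exercise every code
path: the CNV benchmark as above (12,000 probes × 8 samples, repeated
at 30X and 8X); the null study tests 50 samples leave-one-out (5
independent 10-sample panels, one 20 Mb chromosome) and counts reported
calls — the ≥ 5 Mb LOH floor and the CNV filters are part of the
method's error control, so sub-floor scan fragments (present in ~6% of
null samples) are tracked separately via the seedable-anchor rate; the
LOH/UPD study runs 100 replicates of the LOH preset.  Statistical
primitives (probe t, region t, window F) are checked against
independent textbook implementations to 1e-10 on 1,000 random fixtures
each.

## Known limitations

- **Co-localized events across samples.** A carrier in the panel
  inflates the per-probe variance even when the median stays clean; a
  test event fully contained in another sample's event loses most of
  its probe-level power.  The t-statistic as defined offers no
  robustness here; a trimmed or rank-based scale estimate would, at the
  cost of departing from the printed statistic.
- **Breakpoints** cannot be resolved beyond neighbouring probes
  (~10 kb), and never within a probe.
- **Heterodisomy** is undetectable without parental genotypes; only
  isodisomy (copy-neutral homozygous runs) is called.
- **Mixed-sex panels** bias X/Y baselines; X/Y medians are taken within
  inferred sex groups where possible, otherwise a warning is emitted.
- The two-sided F-window p is kept exactly in the additive form defined
  above (clipped to 1); its null distribution is not uniform under the
  median baseline, which is why thresholds act jointly with the
  directional gate rather than as calibrated error rates.
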
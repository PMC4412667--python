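# setrcall

Genome-wide calling of copy-number variants (CNV), loss of
heterozygosity (LOH) and uniparental isodisomy (UPD) from **sparse
targeted sequencing**: short (~150 bp) capture probes spaced roughly
every 10 kb across the genome ("selected target regions"), sequenced to
moderate depth.  Instead of a matched control, every sample is compared
against the **median across the sample collection** — a panel-of-normals
baseline that cancels probe-specific capture efficiency.

Who this is for: anyone screening many genomes for large (≳ 0.5 Mb)
structural aberrations — karyotype-scale deletions, duplications,
aneuploidies, copy-neutral LOH — at a fraction of whole-genome
sequencing cost, without parental or tumor/normal pairing.

## The method in brief

**Depth → ratio.**  Per target *i*: `TD_i = bases_i/len_i`; smoothing
`TD_mi = mean(TD_i..TD_{i+10})` within the chromosome;
`R_i = TD_mi / mean(TD_m, autosomes)`; and the final
`R_mi = R_i / median_panel(R_i)` against the per-target median of ≥ 8
samples (leave-one-out for panel members).  `R_mi ≈ CN/2`.

**CNV.**  Per probe, a one-vs-panel t-test
`t = (R_mi,test − mean_panel)/sqrt(S²(1+1/n))`, df `n−1`.  Four-probe
windows with a common t-sign, ≥ 3 p < 0.05 and the rest ≤ 0.2 mark
'+'/'−' pseudo-signals; same-sign runs ≤ 5 probes apart merge; merged
candidates are re-tested (one-sample t on `Z_i = R_mi,test −
mean_panel`, df `m−1`), confirmed on the unsmoothed ratio at a
genome-wide threshold, boundary-refined by a changepoint fit, and
assigned `CN = round(mean ratio / 0.5)`.  Whole-chromosome calls become
aneuploidies and feed ISCN-style strings such as `46,XY,del(5)(p14)`.

**LOH/UPD.**  Per polymorphic site, the heterozygosity coefficient
`R_Het = min(BAF/(1−BAF), (1−BAF)/BAF)` (1 = heterozygous,
0 = homozygous).  A 25-site window's variance is compared against the
panel-median baseline by a two-sided F construction
(`p = P(F>F_upper) + 1 − P(F>F_under)`, df (24, 24)); three consecutive
significant anchors (p < 0.01) seed an interval, which extends while
the running mean p stays < 0.1.  Intervals ≥ 5 Mb are reported;
CN 2 context → **UPD** (isodisomy), otherwise **LOH_nonUPD**, and every
CN = 1 call is cross-checked for LOH support.

See `docs/methods.md` for the full model, error control, and known
limitations.

## Worked example

Simulate an 8-sample panel on a 30 Mb chromosome in which sample `s1`
carries a 6 Mb copy-neutral UPD and a 6 Mb hemizygous deletion, then
run the full pipeline:

```sh
setrcall simulate --preset loh --seed 11 --out demo
setrcall loh --targets demo/targets.bed --depths demo/depth.tsv \
         --allele-counts demo/allele_counts.tsv --out demo_run
```

which prints

```
wrote 3000 probes, 8 samples, 2 truth events to demo
1 CNV calls, 2 LOH/UPD calls; 0 QC warnings
```

`demo_run/cnv_calls.tsv`:

```
sample  chrom  start     end       size_bp  n_probes  mean_ratio  t_or_F_stat  p_value       CN  class
s1      chr1   16120000  22100150  5980150  599       0.571661    -190.362     2.22507e-308  1   loss
```

`demo_run/loh_calls.tsv`:

```
sample  chrom  start     end       size_bp  n_probes  mean_ratio  t_or_F_stat  p_value      CN  class
s1      chr1   9480031   15530032  6050001  606                                4.61431e-07  2   UPD
s1      chr1   16080123  22130008  6049885  606                                7.40572e-06  1   LOH_nonUPD
```

Reading this: the deletion (implanted at chr1:16.12–22.12 Mb) is
recovered with mean ratio ≈ 0.57 → integer CN 1 and, because its LOH
interval overlaps a CN 1 call, classified `LOH_nonUPD`; the implanted
UPD (chr1:9.52–15.52 Mb) shows LOH with no copy-number change → `UPD`.
Boundaries land within a probe spacing of the implanted edges.  The
`p_value` column holds the region t-test p for CNV rows and the mean
window p for LOH rows; `manifest.json` records configuration, input
checksums, per-stage counts and QC warnings.

Other entry points: `setrcall simulate --preset benchmark|null`, `setrcall
cnv` (depth-only panels), `setrcall design --genome ref.fa --snps
snps.tsv --out probes.bed` (four-stage probe selection), `setrcall
depth` (per-target depth from a sorted SAM/BAM), and `setrcall run`
(YAML config).  Everything is equally usable as a library
(`import setrcall`).

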
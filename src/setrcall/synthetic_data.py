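"""Count-level simulator with implanted CNV/LOH/UPD truth.

Emulates captured targeted sequencing at the level the callers consume:
a regular 10 kb probe grid, per-probe multiplicative capture efficiencies
shared across samples (log-normal), Poisson depth noise scaled by CN/2,
and binomial allele counts around genotype-determined BAF targets.
Read-level details (inserts, alignment artifacts, GC curves) are
deliberately out of scope: every statistic the pipeline consumes is a
function of per-probe depths and per-site allele counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (DepthProfile, SiteAlleleTable, SnpSite, TargetRegion,
                         TargetSet, write_allele_counts, write_depth_table,
                         write_snp_sites, write_targets_bed)

ERROR_FLOOR = 0.002  # sequencing-error BAF floor at homozygous sites


@dataclass(frozen=True)
class TruthEvent:
    """One implanted aberration; UPD implies CN 2 with homozygous genotypes."""

    sample_id: str
    chrom: str
    start: int
    end: int
    kind: str  # {cnv, loh, upd}
    cn: int = 2
    zygosity_effect: str = "none"  # {none, homozygous}

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("event end must exceed start")
        if self.kind == "upd" and (self.cn != 2 or self.zygosity_effect != "homozygous"):
            raise ValueError("UPD events are CN 2 with homozygous genotypes")


@dataclass
class SimConfig:
    n_chroms: int = 2
    chrom_length_bp: int = 60_000_000
    probe_spacing: int = 10_000
    probe_len: int = 150
    n_samples: int = 8
    mean_depth: float = 30.0
    capture_efficiency_sd: float = 0.4  # log-normal sigma
    sites_per_probe: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chroms", "chrom_length_bp", "probe_spacing", "probe_len",
                     "n_samples", "sites_per_probe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass
class SimDataset:
    config: SimConfig
    targets: TargetSet
    sites: list[SnpSite]
    efficiencies: np.ndarray
    depths: dict[str, DepthProfile] = field(default_factory=dict)
    alleles: dict[str, SiteAlleleTable] = field(default_factory=dict)
    truth: list[TruthEvent] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return [f"s{i + 1}" for i in range(self.config.n_samples)]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_targets_bed(self.targets, out / "targets.bed")
        write_snp_sites(self.sites, out / "sites.tsv")
        write_depth_table(self.depths, self.targets, out / "depth.tsv")
        write_allele_counts(self.alleles, self.sites, out / "allele_counts.tsv")
        truth_df = pd.DataFrame(
            [(e.sample_id, e.chrom, e.start, e.end, e.kind, e.cn) for e in self.truth],
            columns=["sample", "chrom", "start", "end", "kind", "cn"])
        self._validate_truth()
        truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)

    def _validate_truth(self) -> None:
        by_sample: dict[str, list[TruthEvent]] = {}
        for e in self.truth:
            by_sample.setdefault(e.sample_id, []).append(e)
        for sample, evs in by_sample.items():
            evs = sorted(evs, key=lambda e: (e.chrom, e.start))
            for a, b in zip(evs, evs[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ValueError(f"overlapping truth events in {sample}")


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

def make_grid(config: SimConfig) -> tuple[TargetSet, list[SnpSite]]:
    """Probes every `probe_spacing` bp; `sites_per_probe` SNPs per probe.

    Population AFs are drawn uniform on [0.1, 0.9] (the AF window the
    caller keeps), site offsets uniform inside the probe window.
    """
    rng = np.random.default_rng(config.seed)
    regions: list[TargetRegion] = []
    sites: list[SnpSite] = []
    idx = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n_probes = config.chrom_length_bp // config.probe_spacing
        for k in range(int(n_probes)):
            start = k * config.probe_spacing
            end = start + config.probe_len
            rid = f"{chrom}_{idx:06d}"
            regions.append(TargetRegion(chrom, start, end, rid, idx))
            offsets = np.sort(rng.choice(config.probe_len,
                                         size=config.sites_per_probe,
                                         replace=False))
            afs = rng.uniform(0.1, 0.9, size=config.sites_per_probe)
            for off, af in zip(offsets, afs):
                pos = start + int(off)
                sites.append(SnpSite(chrom, pos, "A", "G", float(af),
                                     f"{chrom}:{pos}"))
            idx += 1
    return TargetSet(regions), sites


def _cn_vector(targets: TargetSet, truth: list[TruthEvent],
               sample_id: str) -> np.ndarray:
    """Per-probe copy number for one sample (2 outside truth events).

    A probe belongs to an event when its start falls inside the event
    interval, so event sizes are expressible as whole probes.
    """
    cn = np.full(len(targets), 2, dtype=int)
    for e in truth:
        if e.sample_id != sample_id or e.kind == "loh":
            continue
        for r in targets:
            if r.chrom == e.chrom and e.start <= r.start < e.end:
                cn[r.index] = e.cn
    return cn


def simulate_depths(targets: TargetSet, truth: list[TruthEvent],
                    config: SimConfig,
                    efficiencies: np.ndarray | None = None,
                    rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, DepthProfile], np.ndarray]:
    """Per-probe depth ~ Poisson(mean_depth * e_i * CN/2).

    Capture efficiencies e_i ~ log-normal(0, sigma) are drawn once and
    shared across samples — they model probe chemistry, not libraries.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if efficiencies is None:
        efficiencies = rng.lognormal(0.0, config.capture_efficiency_sd,
                                     size=len(targets))
    out: dict[str, DepthProfile] = {}
    for j in range(config.n_samples):
        sample = f"s{j + 1}"
        cn = _cn_vector(targets, truth, sample)
        lam = config.mean_depth * efficiencies * cn / 2.0
        td = rng.poisson(lam).astype(float)
        out[sample] = DepthProfile(sample, td)
    return out, efficiencies


def simulate_allele_counts(targets: TargetSet, sites: list[SnpSite],
                           truth: list[TruthEvent], config: SimConfig,
                           efficiencies: np.ndarray,
                           rng: np.random.Generator | None = None
                           ) -> dict[str, SiteAlleleTable]:
    """Binomial allele counts around genotype-determined BAF targets.

    Genotypes follow Hardy-Weinberg at the site's population AF; inside
    loh/upd (or CN=1) truth the genotype collapses to homozygous; inside
    CN=3 truth a heterozygote's BAF target moves to 1/3 or 2/3 depending
    on which haplotype gained the copy.  A small sequencing-error floor
    keeps homozygous BAF targets off exactly 0/1.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    site_probe = np.array([0] * len(sites))
    probe_of = {}
    for r in targets:
        probe_of[(r.chrom, r.start)] = r.index
    for k, s in enumerate(sites):
        site_probe[k] = probe_of[(s.chrom, (s.pos // config.probe_spacing)
                                  * config.probe_spacing)]
    e_site = efficiencies[site_probe]
    pop_af = np.array([s.pop_af for s in sites])
    out: dict[str, SiteAlleleTable] = {}
    for j in range(config.n_samples):
        sample = f"s{j + 1}"
        u = rng.uniform(size=len(sites))
        hom_ref = u < (1 - pop_af) ** 2
        hom_alt = u > 1 - pop_af ** 2
        het = ~hom_ref & ~hom_alt
        baf_target = np.where(het, 0.5, np.where(hom_alt, 1.0, 0.0))
        for e in truth:
            if e.sample_id != sample:
                continue
            in_event = np.array([s.chrom == e.chrom and e.start <= s.pos < e.end
                                 for s in sites])
            if e.kind in ("loh", "upd") or (e.kind == "cnv" and e.cn <= 1):
                # one haplotype remains/duplicated: heterozygotes collapse
                pick_alt = rng.uniform(size=len(sites)) < pop_af
                baf_target = np.where(in_event & het,
                                      np.where(pick_alt, 1.0, 0.0), baf_target)
            elif e.kind == "cnv" and e.cn == 3:
                dup_alt = rng.uniform(size=len(sites)) < 0.5
                baf_target = np.where(in_event & het,
                                      np.where(dup_alt, 2.0 / 3.0, 1.0 / 3.0),
                                      baf_target)
        baf_target = np.clip(baf_target, ERROR_FLOOR, 1.0 - ERROR_FLOOR)
        depth = rng.poisson(config.mean_depth * e_site)
        alt = rng.binomial(depth, baf_target)
        ref = depth - alt
        out[sample] = SiteAlleleTable(sample, ref, alt)
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig, truth: list[TruthEvent]) -> SimDataset:
    targets, sites = make_grid(config)
    rng = np.random.default_rng(config.seed + 1)
    depths, eff = simulate_depths(targets, truth, config, rng=rng)
    alleles = simulate_allele_counts(targets, sites, truth, config, eff,
                                     rng=np.random.default_rng(config.seed + 2))
    return SimDataset(config, targets, sites, eff, depths, alleles, truth)


def benchmark_scenario(seed: int, mean_depth: float = 30.0) -> SimDataset:
    """The benchmark panel: 8 samples, two 60 Mb chromosomes, 9 CNV events.

    Three samples carry three events each (CN 1 or 3 uniformly, sizes
    drawn uniformly from 450 kb to 3 Mb, snapped to whole probes); the
    other five are normal and anchor the median baseline.  Events are
    placed at distinct loci across ALL samples (each implant probes an
    independent region, matching the method's premise that aberrations
    do not co-localize across a random collection), separated by at
    least 50 probes and kept 20 probes from chromosome ends so distinct
    implants yield distinct merged calls.
    """
    config = SimConfig(n_chroms=2, chrom_length_bp=60_000_000, n_samples=8,
                       mean_depth=mean_depth, seed=seed)
    rng = np.random.default_rng(seed + 10)
    spacing = config.probe_spacing
    n_probes = config.chrom_length_bp // spacing
    truth: list[TruthEvent] = []
    carriers = ["s1", "s2", "s3"]
    events_per = [3, 3, 3]
    placed: list[tuple[str, int, int]] = []  # global: implants never co-localize
    for sample, k in zip(carriers, events_per):
        n_before = len(placed)
        attempts = 0
        while len(placed) - n_before < k and attempts < 1000:
            attempts += 1
            chrom = f"chr{rng.integers(1, config.n_chroms + 1)}"
            size_bp = rng.uniform(450_000, 3_000_000)
            size_probes = max(45, int(round(size_bp / spacing)))
            start_probe = int(rng.integers(20, n_probes - size_probes - 20))
            start = start_probe * spacing
            end = (start_probe + size_probes) * spacing
            clash = any(c == chrom and not (end + 50 * spacing <= s
                                            or start >= e + 50 * spacing)
                        for c, s, e in placed)
            if clash:
                continue
            placed.append((chrom, start, end))
            cn = int(rng.choice([1, 3]))
            truth.append(TruthEvent(sample, chrom, start, end, "cnv", cn))
    assert len(truth) == 9
    return simulate_dataset(config, truth)


def null_scenario(seed: int, n_samples: int = 10, n_chroms: int = 1,
                  chrom_length_bp: int = 20_000_000,
                  mean_depth: float = 30.0,
                  capture_efficiency_sd: float = 0.4) -> SimDataset:
    """A panel with no implanted events, for false-positive studies."""
    config = SimConfig(n_chroms=n_chroms, chrom_length_bp=chrom_length_bp,
                       n_samples=n_samples, mean_depth=mean_depth,
                       capture_efficiency_sd=capture_efficiency_sd, seed=seed)
    return simulate_dataset(config, [])


def loh_scenario(seed: int, n_samples: int = 8,
                 chrom_length_bp: int = 30_000_000,
                 upd_size_bp: int = 6_000_000,
                 del_size_bp: int = 6_000_000,
                 mean_depth: float = 30.0) -> SimDataset:
    """One chromosome; the test sample s1 carries a UPD and a CN=1 deletion.

    Both events exceed the 5 Mb reporting floor; the deletion collapses
    heterozygosity (hemizygous) so both callers should fire on it.
    """
    config = SimConfig(n_chroms=1, chrom_length_bp=chrom_length_bp,
                       n_samples=n_samples, mean_depth=mean_depth, seed=seed)
    spacing = config.probe_spacing
    rng = np.random.default_rng(seed + 20)
    n_probes = chrom_length_bp // spacing
    upd_probes = upd_size_bp // spacing
    del_probes = del_size_bp // spacing
    gap = 60  # probes between the two events
    free = n_probes - upd_probes - del_probes - gap - 40
    off = int(rng.integers(0, max(free, 1)))
    upd_start = (20 + off) * spacing
    upd_end = upd_start + upd_probes * spacing
    del_start = upd_end + gap * spacing
    del_end = del_start + del_probes * spacing
    truth = [
        TruthEvent("s1", "chr1", upd_start, upd_end, "upd", 2, "homozygous"),
        TruthEvent("s1", "chr1", del_start, del_end, "cnv", 1, "homozygous"),
    ]
    return simulate_dataset(config, truth)


# ---------------------------------------------------------------------------
# Truth-aware evaluation
# ---------------------------------------------------------------------------

def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return min(a_end, b_end) - max(a_start, b_start) > 0


def cnv_benchmark(truth: list[TruthEvent], calls) -> dict:
    """Event-level sensitivity and specificity against implanted truth.

    An event counts as recovered when a same-sample call overlaps it with
    the implanted integer copy number; a call counts as true when it
    overlaps any same-sample truth event.  Percentages follow the usual
    benchmark convention (specificity = precision of emitted calls; 100
    when no calls are emitted on an all-recovered run).
    """
    events = [e for e in truth if e.kind == "cnv"]
    recovered = [
        e for e in events
        if any(c.sample_id == e.sample_id and c.chrom == e.chrom
               and _overlaps(c.start, c.end, e.start, e.end) and c.cn == e.cn
               for c in calls)
    ]
    true_calls = [
        c for c in calls
        if any(e.sample_id == c.sample_id and e.chrom == c.chrom
               and _overlaps(c.start, c.end, e.start, e.end) for e in truth)
    ]
    n_events, n_calls = len(events), len(calls)
    sens = 100.0 * len(recovered) / n_events if n_events else 100.0
    spec = 100.0 * len(true_calls) / n_calls if n_calls else 100.0
    return {
        "n_events": n_events,
        "n_recovered": len(recovered),
        "n_calls": n_calls,
        "n_true_calls": len(true_calls),
        "sensitivity_pct": sens,
        "specificity_pct": spec,
    }


# ---------------------------------------------------------------------------
# Probe-design fixture
# ---------------------------------------------------------------------------

def make_design_fixture(seed: int, length: int = 1_000_000,
                        n_snps: int = 400) -> tuple[dict[str, str], pd.DataFrame]:
    """A small random genome plus SNP table exercising the design filters.

    Plants: (a) a verbatim duplicate segment (non-unique flanks), (b) a
    ~99%-identical decoy of one locus (near-duplicate screen), (c) a
    ~90%-identical decoy of another (should survive the screen), (d) a
    poly-A stretch and (e) a GC-extreme window, plus a uniform SNP
    scatter with AF labels spanning [0, 1].
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length)

    # planted features at fixed fractions of the genome length
    L = length
    dup_a, dup_b = int(0.20 * L), int(0.40 * L)
    near_a, near_b = int(0.25 * L), int(0.50 * L)
    far_a, far_b = int(0.30 * L), int(0.60 * L)
    seq[dup_b:dup_b + 1000] = seq[dup_a:dup_a + 1000]  # verbatim duplicate

    decoy99 = seq[near_a:near_a + 101].copy()
    decoy99[50] = "T" if decoy99[50] != "T" else "C"  # 1 mismatch (~99%)
    seq[near_b:near_b + 101] = decoy99

    decoy90 = seq[far_a:far_a + 101].copy()
    flips = rng.choice(101, size=10, replace=False)
    for f in flips:
        decoy90[f] = bases[(np.flatnonzero(bases == decoy90[f])[0] + 1) % 4]
    seq[far_b:far_b + 101] = decoy90  # ~90% identical

    seq[int(0.70 * L):int(0.70 * L) + 300] = "A"  # homopolymer stretch
    seq[int(0.80 * L):int(0.80 * L) + 400] = rng.choice(["G", "C"], 400)

    genome = {"chr1": "".join(seq)}
    pos = np.sort(rng.choice(np.arange(200, length - 200), size=n_snps,
                             replace=False))
    # guarantee SNPs at the planted loci so the filters are exercised
    special = [dup_a + 50, dup_b + 50, near_a + 50, far_a + 50]
    pos = np.unique(np.concatenate([pos, special]))
    af = rng.uniform(0.2, 0.8, size=len(pos))
    refs = [genome["chr1"][p] for p in pos]
    alts = [("A" if r != "A" else "G") for r in refs]
    snps = pd.DataFrame({"chrom": "chr1", "pos": pos, "ref": refs,
                         "alt": alts, "af": af})
    return genome, snps
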
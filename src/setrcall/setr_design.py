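"""Four-stage selection of evenly spaced capture probe locations.

Stage 1 keeps SNPs with population AF in [0.10, 0.90] and removes
clustered sites (within 100 bp of a previously kept one).  Stage 2 keeps
only SNPs whose 101-base flank (50 up + site + 50 down) is unique in the
genome: exactly one perfect occurrence, and no second locus above 95%
identity (an exact k-mer index plus an edit-distance screen stands in
for an external aligner).  Stage 3 thins to at most one SNP per 10 kb
bin.  Stage 4 inserts evenly spaced filler anchors into larger gaps,
sliding each filler away from homopolymer runs and GC extremes.  Every
anchor finally becomes a 150 bp probe window centered on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SnpSite, TargetRegion, TargetSet, _chrom_key

logger = logging.getLogger("setrcall")

FLANK = 50          # bases either side of the SNP
KMER = 2 * FLANK + 1  # 101-base uniqueness window
SEED_K = 20         # seed k-mer for the near-duplicate screen


@dataclass(frozen=True)
class CandidateSnp:
    site: SnpSite
    flank_sequence: str
    uniqueness_pass: bool = False


@dataclass(frozen=True)
class ProbeLocation:
    chrom: str
    anchor_pos: int
    source: str  # {snp, filler}


# ---------------------------------------------------------------------------
# Stage 1: AF window and declustering
# ---------------------------------------------------------------------------

def filter_by_af(snps: Sequence[SnpSite], af_min: float = 0.10,
                 af_max: float = 0.90) -> list[SnpSite]:
    """Keep sites with af_min <= pop_af <= af_max (closed interval)."""
    return [s for s in snps if af_min <= s.pop_af <= af_max]


def remove_clustered(snps: Sequence[SnpSite], radius: int = 100) -> list[SnpSite]:
    """Scanning in genome order, drop any site within `radius` bp of the
    previously kept site on the same chromosome."""
    ordered = sorted(snps, key=lambda s: (_chrom_key(s.chrom), s.pos))
    kept: list[SnpSite] = []
    for s in ordered:
        if kept and kept[-1].chrom == s.chrom and s.pos - kept[-1].pos <= radius:
            continue
        kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# Stage 2: uniqueness
# ---------------------------------------------------------------------------

def extract_flank(genome: Mapping[str, str], site: SnpSite) -> str | None:
    """101-base window around the site; None when truncated by a contig edge."""
    seq = genome.get(site.chrom)
    if seq is None:
        return None
    lo, hi = site.pos - FLANK, site.pos + FLANK + 1
    if lo < 0 or hi > len(seq):
        return None
    return seq[lo:hi].upper()


class GenomeIndex:
    """Exact 101-mer occurrence counts plus a seed index for identity checks."""

    def __init__(self, genome: Mapping[str, str]):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.kmer_counts: dict[str, int] = {}
        self.seed_hits: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(0, len(seq) - KMER + 1):
                km = seq[i:i + KMER]
                self.kmer_counts[km] = self.kmer_counts.get(km, 0) + 1
            for i in range(0, len(seq) - SEED_K + 1):
                sd = seq[i:i + SEED_K]
                self.seed_hits.setdefault(sd, []).append((chrom, i))

    def occurrences(self, flank: str) -> int:
        return self.kmer_counts.get(flank, 0)

    def second_best_identity(self, flank: str, chrom: str, pos0: int) -> float:
        """Highest identity of any other locus sharing a seed with `flank`.

        pos0 is the flank's own start; loci overlapping it are skipped.
        """
        import edlib

        best = 0.0
        seen: set[tuple[str, int]] = set()
        for off in range(0, KMER - SEED_K + 1, SEED_K // 2):
            sd = flank[off:off + SEED_K]
            for hit_chrom, hit_pos in self.seed_hits.get(sd, []):
                anchor = hit_pos - off
                key = (hit_chrom, anchor)
                if key in seen:
                    continue
                seen.add(key)
                if hit_chrom == chrom and abs(anchor - pos0) < KMER:
                    continue
                seq = self.genome[hit_chrom]
                lo = max(0, anchor - 5)
                hi = min(len(seq), anchor + KMER + 5)
                window = seq[lo:hi]
                res = edlib.align(flank, window, mode="HW", task="distance")
                ident = 1.0 - res["editDistance"] / KMER
                best = max(best, ident)
        return best


def uniqueness_filter(snps: Sequence[SnpSite], genome: Mapping[str, str],
                      max_second_identity: float = 0.95,
                      index: GenomeIndex | None = None) -> list[SnpSite]:
    """Keep SNPs whose flank is unique and has no near-identical second locus.

    A site passes when its 101-mer flank occurs exactly once verbatim in
    the genome and the best-matching other locus is <= max_second_identity
    identical.  Edge-truncated flanks are dropped and logged.
    """
    if index is None:
        index = GenomeIndex(genome)
    kept: list[SnpSite] = []
    n_edge = n_dup = n_near = 0
    for s in snps:
        flank = extract_flank(genome, s)
        if flank is None:
            n_edge += 1
            continue
        if index.occurrences(flank) != 1:
            n_dup += 1
            continue
        if index.second_best_identity(flank, s.chrom, s.pos - FLANK) > max_second_identity:
            n_near += 1
            continue
        kept.append(s)
    if n_edge or n_dup or n_near:
        logger.info("uniqueness filter: dropped %d edge-truncated, %d non-unique, "
                    "%d near-duplicate sites", n_edge, n_dup, n_near)
    return kept


# ---------------------------------------------------------------------------
# Stage 3: thinning to the grid
# ---------------------------------------------------------------------------

def thin_to_grid(snps: Sequence[SnpSite], spacing: int = 10_000) -> list[ProbeLocation]:
    """Per chromosome, keep at most one SNP per spacing-sized bin.

    The kept site is the one closest to the bin center (tie -> lower
    position).
    """
    by_bin: dict[tuple[str, int], SnpSite] = {}
    for s in sorted(snps, key=lambda s: (_chrom_key(s.chrom), s.pos)):
        b = s.pos // spacing
        center = b * spacing + spacing // 2
        key = (s.chrom, b)
        cur = by_bin.get(key)
        if cur is None or abs(s.pos - center) < abs(cur.pos - center):
            by_bin[key] = s
    out = [ProbeLocation(s.chrom, s.pos, "snp") for s in by_bin.values()]
    return sorted(out, key=lambda p: (_chrom_key(p.chrom), p.anchor_pos))


# ---------------------------------------------------------------------------
# Stage 4: gap filling
# ---------------------------------------------------------------------------

def _window_compliant(seq: str, center: int, probe_len: int,
                      gc_min: float, gc_max: float,
                      max_homopolymer: int = 9) -> bool:
    lo = max(0, center - probe_len // 2)
    hi = min(len(seq), lo + probe_len)
    w = seq[lo:hi]
    if len(w) < probe_len // 2:
        return False
    gc = (w.count("G") + w.count("C")) / len(w)
    if not (gc_min <= gc <= gc_max):
        return False
    run, prev = 1, ""
    for ch in w:
        if ch == prev:
            run += 1
            if run > max_homopolymer:
                return False
        else:
            run, prev = 1, ch
    return True


def fill_gaps(locations: Sequence[ProbeLocation], genome: Mapping[str, str],
              spacing: int = 10_000, probe_len: int = 150,
              gc_min: float = 0.3, gc_max: float = 0.7) -> list[ProbeLocation]:
    """Insert evenly spaced filler anchors into every inter-anchor gap > spacing.

    A gap of G bp receives max(1, floor(G / spacing) - 1) fillers at the
    even division points.  Each filler slides up to spacing/2 to the
    nearest window passing the GC and homopolymer screens, else it is
    skipped with a logged gap.  Chromosome ends are treated as anchors at
    0 and contig length so leading/trailing gaps are filled too.
    """
    by_chrom: dict[str, list[ProbeLocation]] = {}
    for p in locations:
        by_chrom.setdefault(p.chrom, []).append(p)
    out = list(locations)
    for chrom, seq in genome.items():
        anchors = sorted(p.anchor_pos for p in by_chrom.get(chrom, []))
        bounds = [0] + anchors + [len(seq)]
        for a, b in zip(bounds, bounds[1:]):
            gap = b - a
            if gap <= spacing:
                continue
            n_fill = max(1, gap // spacing - 1)
            for k in range(1, n_fill + 1):
                target = a + round(gap * k / (n_fill + 1))
                placed = None
                for delta in range(0, spacing // 2 + 1, 10):
                    for cand in ((target + delta, target - delta)
                                 if delta else (target,)):
                        if not (0 <= cand < len(seq)):
                            continue
                        if _window_compliant(seq, cand, probe_len, gc_min, gc_max):
                            placed = cand
                            break
                    if placed is not None:
                        break
                if placed is None:
                    logger.warning("no compliant filler window near %s:%d; gap kept",
                                   chrom, target)
                    continue
                out.append(ProbeLocation(chrom, int(placed), "filler"))
    return sorted(out, key=lambda p: (_chrom_key(p.chrom), p.anchor_pos))


# ---------------------------------------------------------------------------
# Probe emission and reporting
# ---------------------------------------------------------------------------

def emit_probes(locations: Sequence[ProbeLocation],
                contig_lengths: Mapping[str, int],
                probe_len: int = 150) -> TargetSet:
    """Each anchor becomes a probe_len window centered on it, clipped at
    contig edges; on overlap the SNP-sourced probe wins over a filler."""
    ordered = sorted(locations, key=lambda p: (_chrom_key(p.chrom), p.anchor_pos))
    chosen: list[tuple[str, int, int, str]] = []
    for p in ordered:
        clen = contig_lengths[p.chrom]
        start = max(0, p.anchor_pos - probe_len // 2)
        end = min(clen, start + probe_len)
        start = max(0, end - probe_len)
        if chosen and chosen[-1][0] == p.chrom and start < chosen[-1][2]:
            prev = chosen[-1]
            if prev[3] == "filler" and p.source == "snp":
                chosen[-1] = (p.chrom, start, end, p.source)
            continue  # keep earlier probe; drop the filler (or later dup)
        chosen.append((p.chrom, start, end, p.source))
    regions = [TargetRegion(c, s, e, f"{c}_{s}", i)
               for i, (c, s, e, _) in enumerate(chosen)]
    return TargetSet(regions)


def design_report(targets: TargetSet) -> pd.DataFrame:
    """Per-chromosome and total probe counts, bp, and inter-probe spacing."""
    rows = []
    all_gaps: list[int] = []
    for chrom in targets.chroms:
        sl = targets.chrom_slice(chrom)
        regs = targets.regions[sl]
        mids = [r.midpoint for r in regs]
        gaps = list(np.diff(mids)) if len(mids) > 1 else []
        all_gaps.extend(int(g) for g in gaps)
        rows.append({
            "chrom": chrom, "n_probes": len(regs),
            "total_bp": sum(r.length for r in regs),
            "median_gap": float(np.median(gaps)) if gaps else np.nan,
            "mean_gap": float(np.mean(gaps)) if gaps else np.nan,
        })
    rows.append({
        "chrom": "ALL", "n_probes": len(targets),
        "total_bp": sum(r.length for r in targets),
        "median_gap": float(np.median(all_gaps)) if all_gaps else np.nan,
        "mean_gap": float(np.mean(all_gaps)) if all_gaps else np.nan,
    })
    return pd.DataFrame(rows)


def design_probes(genome: Mapping[str, str], snps: Sequence[SnpSite],
                  spacing: int = 10_000, probe_len: int = 150,
                  af_min: float = 0.10, af_max: float = 0.90,
                  cluster_radius: int = 100,
                  max_second_identity: float = 0.95) -> TargetSet:
    """Run all four stages end-to-end; deterministic given its inputs."""
    s1 = remove_clustered(filter_by_af(snps, af_min, af_max), cluster_radius)
    s2 = uniqueness_filter(s1, genome, max_second_identity)
    s3 = thin_to_grid(s2, spacing)
    s4 = fill_gaps(s3, genome, spacing, probe_len)
    return emit_probes(s4, {c: len(s) for c, s in genome.items()}, probe_len)
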
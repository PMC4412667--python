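"""Readers and writers for every on-disk artifact the pipeline touches.

All interval arithmetic is 0-based half-open internally (standard BED
semantics); karyotype-style strings and report tables render 1-based
inclusive at the edge.  Depth tables come in two dialects: ``mean-depth``
(values are already reads-per-base) and ``base-count`` (values are total
aligned bases, divided by region length on read).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("setrcall")

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetRegion:
    """One capture probe region on the genome grid (0-based half-open)."""

    chrom: str
    start: int
    end: int
    region_id: str
    index: int

    def __post_init__(self):
        if self.end <= self.start:
            raise FormatError(
                f"region {self.region_id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class TargetSet:
    """The ordered genome-wide probe grid all per-probe vectors align to.

    Regions are sorted by (chrom, start), non-overlapping within a
    chromosome, and indexed 0..N-1 with no gaps.
    """

    def __init__(self, regions: Sequence[TargetRegion]):
        self.regions = list(regions)
        self._by_id = {r.region_id: r for r in self.regions}
        if len(self._by_id) != len(self.regions):
            raise FormatError("duplicate region_id in target set")
        self._validate()
        self.chroms: list[str] = []
        for r in self.regions:
            if not self.chroms or self.chroms[-1] != r.chrom:
                self.chroms.append(r.chrom)

    def _validate(self) -> None:
        for i, r in enumerate(self.regions):
            if r.index != i:
                raise FormatError(f"region {r.region_id}: index {r.index} != position {i}")
        for a, b in zip(self.regions, self.regions[1:]):
            if a.chrom == b.chrom:
                if b.start < a.start:
                    raise FormatError("targets not sorted by (chrom, start)")
                if b.start < a.end:
                    raise FormatError(
                        f"overlapping targets {a.region_id} and {b.region_id}"
                    )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i: int) -> TargetRegion:
        return self.regions[i]

    def by_id(self, region_id: str) -> TargetRegion:
        return self._by_id[region_id]

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def chrom_slice(self, chrom: str) -> slice:
        """Index slice covering all targets on `chrom` (contiguous by sort)."""
        idx = [r.index for r in self.regions if r.chrom == chrom]
        if not idx:
            return slice(0, 0)
        return slice(idx[0], idx[-1] + 1)

    def chrom_of(self) -> np.ndarray:
        return np.array([r.chrom for r in self.regions], dtype=object)

    def autosomal_mask(self) -> np.ndarray:
        return np.array([r.chrom not in SEX_CHROMS for r in self.regions], dtype=bool)

    def lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.regions], dtype=float)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]],
                       id_prefix: str = "t") -> "TargetSet":
        """Build a TargetSet from (chrom, start, end) triples, sorting them."""
        rows = sorted(intervals, key=lambda x: (_chrom_key(x[0]), x[1]))
        regions = [
            TargetRegion(c, s, e, f"{id_prefix}_{c}_{s}", i)
            for i, (c, s, e) in enumerate(rows)
        ]
        return cls(regions)


@dataclass(frozen=True)
class SnpSite:
    """A known polymorphic position with its population allele frequency."""

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    pop_af: float
    site_id: str

    def __post_init__(self):
        if not (0.0 <= self.pop_af <= 1.0):
            raise FormatError(f"site {self.site_id}: pop_af {self.pop_af} outside [0, 1]")


@dataclass
class DepthProfile:
    """One sample's raw mean depth per target (reads-per-base units)."""

    sample_id: str
    td: np.ndarray  # aligned to TargetSet indices

    def __post_init__(self):
        self.td = np.asarray(self.td, dtype=float)
        if np.any(self.td < 0):
            raise FormatError(f"sample {self.sample_id}: negative depth")


@dataclass
class SiteAlleleTable:
    """Per-site ref/alt read counts and derived BAF for one sample.

    Arrays are aligned to the SnpSite list; `usable` marks sites whose
    total depth meets the minimum for a trustworthy BAF.
    """

    sample_id: str
    ref_count: np.ndarray
    alt_count: np.ndarray
    usable: np.ndarray = field(default=None)  # type: ignore[assignment]
    min_depth: int = 10

    def __post_init__(self):
        self.ref_count = np.asarray(self.ref_count)
        self.alt_count = np.asarray(self.alt_count)
        if self.ref_count.shape != self.alt_count.shape:
            raise FormatError("ref/alt count arrays differ in length")
        if np.any(self.ref_count < 0) or np.any(self.alt_count < 0):
            raise FormatError("negative allele counts")
        if self.usable is None:
            self.usable = self.depth >= self.min_depth

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    @property
    def baf(self) -> np.ndarray:
        d = self.depth.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(d > 0, self.alt_count / d, np.nan)
        return b


class CytobandTable:
    """Cytogenetic band table in UCSC cytoBand column order."""

    COLS = ["chrom", "start", "end", "band", "stain"]

    def __init__(self, df: pd.DataFrame):
        self.df = df.sort_values(["chrom", "start"]).reset_index(drop=True)

    @classmethod
    def read(cls, path) -> "CytobandTable":
        df = pd.read_csv(path, sep="\t", header=None, names=cls.COLS,
                         dtype={"chrom": str, "band": str, "stain": str})
        return cls(df)

    def bands_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        sub = self.df[(self.df.chrom == chrom)
                      & (self.df.end > start) & (self.df.start < end)]
        return list(sub.band)

    def band_at(self, chrom: str, pos: int) -> str | None:
        sub = self.df[(self.df.chrom == chrom)
                      & (self.df.start <= pos) & (self.df.end > pos)]
        if len(sub) == 0:
            return None
        return sub.band.iloc[0]


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _chrom_key(chrom: str):
    """Natural chromosome ordering: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    c = chrom[3:] if chrom.startswith("chr") else chrom
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_targets(path) -> TargetSet:
    """Parse a 3+ column BED file (0-based half-open) into a TargetSet.

    Rows are sorted into genome order before indexing; duplicate and
    overlapping intervals are rejected.
    """
    rows: list[tuple[str, int, int, str | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            name = parts[3] if len(parts) >= 4 else None
            rows.append((chrom, start, end, name))
    if not rows:
        logger.warning("%s: empty target BED", path)
        return TargetSet([])
    if len({(c, s, e) for c, s, e, _ in rows}) != len(rows):
        raise FormatError(f"{path}: duplicate intervals in target BED")
    rows.sort(key=lambda x: (_chrom_key(x[0]), x[1]))
    regions = [
        TargetRegion(c, s, e, name if name else f"{c}_{s}", i)
        for i, (c, s, e, name) in enumerate(rows)
    ]
    return TargetSet(regions)


def read_snp_sites(path) -> list[SnpSite]:
    """Read a SNP TSV (chrom, pos, ref, alt, af) with 0-based positions."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "af"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values(["chrom", "pos"],
                        key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s)
    sites = [
        SnpSite(r.chrom, int(r.pos), r.ref, r.alt, float(r.af),
                f"{r.chrom}:{int(r.pos)}")
        for r in df.itertuples()
    ]
    return sites


def read_depth_table(path, targets: TargetSet,
                     dialect: str = "mean-depth") -> dict[str, DepthProfile]:
    """Read the per-target depth matrix (region_id + one column per sample).

    dialect "base-count" divides each value by the region length so the
    stored per-target value is mean depth in reads-per-base.
    """
    if dialect not in ("mean-depth", "base-count"):
        raise ValueError(f"unknown depth dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    if "region_id" not in df.columns:
        raise FormatError(f"{path}: missing 'region_id' column")
    known = set(targets.region_ids)
    unknown = set(df.region_id) - known
    if unknown:
        raise FormatError(
            f"{path}: regions not in target set: {sorted(unknown)[:5]}")
    missing = known - set(df.region_id)
    if missing:
        raise FormatError(f"{path}: regions missing from table: {sorted(missing)[:5]}")
    df = df.set_index("region_id").loc[targets.region_ids]
    lengths = targets.lengths()
    out: dict[str, DepthProfile] = {}
    for sample in df.columns:
        vals = df[sample].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise FormatError(f"{path}: negative depth for sample {sample}")
        if dialect == "base-count":
            vals = vals / lengths
        out[sample] = DepthProfile(sample, vals)
    return out


def _attach_sites_to_probes(sites: Sequence[SnpSite], targets: TargetSet) -> np.ndarray:
    """Assign each site to its containing or nearest probe on the same chromosome.

    Ties go to the lower probe index so probe- and site-indexed logic agree.
    Sites on chromosomes without probes get index -1.
    """
    assign = np.full(len(sites), -1, dtype=int)
    by_chrom: dict[str, list[TargetRegion]] = {}
    for r in targets:
        by_chrom.setdefault(r.chrom, []).append(r)
    for k, s in enumerate(sites):
        regs = by_chrom.get(s.chrom)
        if not regs:
            continue
        mids = np.array([r.midpoint for r in regs])
        starts = np.array([r.start for r in regs])
        ends = np.array([r.end for r in regs])
        inside = (starts <= s.pos) & (s.pos < ends)
        if inside.any():
            assign[k] = regs[int(np.argmax(inside))].index
        else:
            d = np.abs(mids - s.pos)
            assign[k] = regs[int(np.argmin(d))].index
    return assign


def read_allele_counts(path, sites: Sequence[SnpSite],
                       af_min: float = 0.1, af_max: float = 0.9,
                       min_depth: int = 10,
                       dialect: str = "tsv") -> dict[str, SiteAlleleTable]:
    """Read per-sample ref/alt counts aligned to the SNP site list.

    Sites whose population AF falls outside [af_min, af_max] are dropped
    (with a logged count) before alignment; downstream arrays align to the
    retained sites, obtainable via :func:`filter_sites_by_af`.
    """
    kept_sites, kept_idx = filter_sites_by_af(sites, af_min, af_max)
    id_to_row = {s.site_id: i for i, s in enumerate(kept_sites)}
    if dialect == "vcf":
        return _read_allele_counts_vcf(path, kept_sites, id_to_row, min_depth)
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    for col in ("site_id", "sample", "ref_count", "alt_count"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    for col in ("ref_count", "alt_count"):
        vals = df[col]
        if not np.array_equal(vals, vals.astype(int)):
            raise FormatError(f"{path}: non-integer {col}")
    all_ids = {s.site_id for s in sites}
    unknown = set(df.site_id) - all_ids
    if unknown:
        raise FormatError(f"{path}: sites not in site list: {sorted(unknown)[:5]}")
    n_dropped = len(set(df.site_id) - set(id_to_row))
    if n_dropped:
        logger.info("%s: dropped %d sites outside AF window [%g, %g]",
                    path, n_dropped, af_min, af_max)
    out: dict[str, SiteAlleleTable] = {}
    for sample, sub in df.groupby("sample"):
        ref = np.zeros(len(kept_sites), dtype=int)
        alt = np.zeros(len(kept_sites), dtype=int)
        seen = np.zeros(len(kept_sites), dtype=bool)
        for r in sub.itertuples():
            row = id_to_row.get(r.site_id)
            if row is None:
                continue
            ref[row] = int(r.ref_count)
            alt[row] = int(r.alt_count)
            seen[row] = True
        tbl = SiteAlleleTable(str(sample), ref, alt, min_depth=min_depth)
        tbl.usable &= seen
        out[str(sample)] = tbl
    return out


def _read_allele_counts_vcf(path, kept_sites, id_to_row, min_depth):
    """VCF dialect: allelic depths from the per-sample AD field."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    n = len(kept_sites)
    ref = {s: np.zeros(n, dtype=int) for s in samples}
    alt = {s: np.zeros(n, dtype=int) for s in samples}
    seen = {s: np.zeros(n, dtype=bool) for s in samples}
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            warnings.warn(f"skipping multi-allelic record at {rec.chrom}:{rec.pos}")
            continue
        row = id_to_row.get(f"{rec.chrom}:{rec.pos - 1}")
        if row is None:
            continue
        for s in samples:
            ad = rec.samples[s].get("AD")
            if ad is None or ad[0] is None:
                continue
            ref[s][row] = int(ad[0])
            alt[s][row] = int(ad[1])
            seen[s][row] = True
    out = {}
    for s in samples:
        tbl = SiteAlleleTable(s, ref[s], alt[s], min_depth=min_depth)
        tbl.usable &= seen[s]
        out[s] = tbl
    return out


def filter_sites_by_af(sites: Sequence[SnpSite], af_min: float = 0.1,
                       af_max: float = 0.9) -> tuple[list[SnpSite], np.ndarray]:
    """Retain sites with af_min <= pop_af <= af_max (closed interval)."""
    kept, idx = [], []
    for i, s in enumerate(sites):
        if af_min <= s.pop_af <= af_max:
            kept.append(s)
            idx.append(i)
    return kept, np.array(idx, dtype=int)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

CALL_COLUMNS = ["sample", "chrom", "start", "end", "size_bp", "n_probes",
                "mean_ratio", "t_or_F_stat", "p_value", "CN", "class"]


def write_calls(calls: Iterable, path) -> None:
    """Write calls to a TSV and a mirroring BED (`path` + '.bed').

    Accepts any objects exposing the CALL_COLUMNS fields via `as_row()`.
    Output is sorted and formatted deterministically.
    """
    path = Path(path)
    rows = [c.as_row() for c in calls]
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    df = df.sort_values(["sample", "chrom", "start"],
                        key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    with open(str(path) + ".bed", "w") as fh:
        for _, r in df.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                     f"{r['sample']}:{r['class']}:CN{r['CN']}\n")


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})


def export_tracks(targets: TargetSet, out_dir, *, r_m: np.ndarray | None = None,
                  rhet_sites: Sequence[SnpSite] | None = None,
                  rhet: np.ndarray | None = None,
                  pvalues: np.ndarray | None = None,
                  sample_id: str = "sample") -> list[Path]:
    """Export per-chromosome bedGraph-style tracks of the normalized depth
    ratio, the per-site heterozygosity coefficient, and window p-values for
    external plotting."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name, rows_by_chrom):
        for chrom, rows in rows_by_chrom.items():
            p = out_dir / f"{sample_id}.{name}.{chrom}.bedgraph"
            with open(p, "w") as fh:
                for s, e, v in rows:
                    if np.isfinite(v):
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
            written.append(p)

    if r_m is not None:
        by_chrom: dict[str, list] = {}
        for reg, v in zip(targets, r_m):
            by_chrom.setdefault(reg.chrom, []).append((reg.start, reg.end, v))
        _write("Rm", by_chrom)
    if rhet_sites is not None and rhet is not None:
        by_chrom = {}
        for s, v in zip(rhet_sites, rhet):
            by_chrom.setdefault(s.chrom, []).append((s.pos, s.pos + 1, v))
        _write("Rhet", by_chrom)
    if rhet_sites is not None and pvalues is not None:
        by_chrom = {}
        for s, v in zip(rhet_sites, pvalues):
            by_chrom.setdefault(s.chrom, []).append((s.pos, s.pos + 1, v))
        _write("loh_p", by_chrom)
    return written


def write_depth_table(profiles: Mapping[str, DepthProfile], targets: TargetSet,
                      path) -> None:
    df = pd.DataFrame({"region_id": targets.region_ids})
    for sample, prof in profiles.items():
        df[sample] = prof.td
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_allele_counts(tables: Mapping[str, SiteAlleleTable],
                        sites: Sequence[SnpSite], path) -> None:
    recs = []
    for sample, tbl in tables.items():
        for s, r, a in zip(sites, tbl.ref_count, tbl.alt_count):
            recs.append((s.site_id, sample, int(r), int(a)))
    pd.DataFrame(recs, columns=["site_id", "sample", "ref_count", "alt_count"]) \
        .to_csv(path, sep="\t", index=False)


def write_snp_sites(sites: Sequence[SnpSite], path) -> None:
    pd.DataFrame(
        [(s.chrom, s.pos, s.ref_allele, s.alt_allele, s.pop_af) for s in sites],
        columns=["chrom", "pos", "ref", "alt", "af"],
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_targets_bed(targets: TargetSet, path) -> None:
    with open(path, "w") as fh:
        for r in targets:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")
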
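"""LOH and UPD detection from B-allele-frequency dispersion.

Each polymorphic site's BAF is folded into the heterozygosity coefficient

    R_Het = min(BAF / (1 - BAF), (1 - BAF) / BAF)  in [0, 1]

which is 1 at perfect heterozygosity and 0 at homozygosity.  Over a
sliding window of usable sites, the variance of the test sample's R_Het
values is compared against the variance of the panel's per-site median
R_Het with a two-sided F construction:

    F_upper = S2_max / S2_min,  F_under = S2_min / S2_max
    p = P(F > F_upper) + (1 - P(F > F_under))        (clipped to 1)

with (n-1, n-1) degrees of freedom.  Runs of 3+ significant anchors seed
LOH intervals, which extend greedily while tolerating a single
above-threshold anchor as long as the running mean p stays small.
Intersecting LOH with copy number classifies copy-neutral LOH (CN = 2)
as uniparental isodisomy (UPD) and the rest as LOH_nonUPD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cnv_caller import CnvCall
from .io_formats import SiteAlleleTable, SnpSite

logger = logging.getLogger("setrcall")


@dataclass
class RHetBaseline:
    """Per-site median R_Het across the panel; masked where too few samples."""

    median_rhet: np.ndarray
    n_samples: int
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.mask is None:
            self.mask = ~np.isfinite(self.median_rhet)


@dataclass
class LohWindow:
    anchor: int
    span: tuple[int, int]  # half-open site-index span
    s2_test: float
    s2_mul: float
    f_upper: float
    f_under: float
    p_value: float
    degenerate: bool = False


@dataclass
class LohCall:
    sample_id: str
    chrom: str
    start: int
    end: int
    n_sites: int
    mean_p: float
    loh_class: str = "LOH"  # {LOH, LOH_nonUPD, UPD}
    cn_context: int | None = None
    site_span: tuple[int, int] = field(default=(0, 0))

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    def as_row(self):
        return {
            "sample": self.sample_id, "chrom": self.chrom,
            "start": self.start, "end": self.end, "size_bp": self.size_bp,
            "n_probes": self.n_sites, "mean_ratio": np.nan,
            "t_or_F_stat": np.nan, "p_value": self.mean_p,
            "CN": self.cn_context if self.cn_context is not None else "",
            "class": self.loh_class,
        }


@dataclass
class LohParams:
    p_loh: float = 0.01          # per-window significance threshold
    init_run: int = 3            # consecutive significant anchors to seed
    mean_p_cap: float = 0.1      # running-mean cap during extension
    window: int = 25             # usable sites per variance window
    min_depth: int = 10          # reads for a usable BAF
    min_size_bp: int = 5_000_000  # reporting floor
    directional: bool = True     # require test window mean AND variance below baseline's
    merge_gap: int = 5           # anchors bridged when merging extended intervals


# ---------------------------------------------------------------------------
# R_Het
# ---------------------------------------------------------------------------

def compute_rhet(baf):
    """R_Het = min(BAF/(1-BAF), (1-BAF)/BAF); 0 at the homozygous boundaries.

    Accepts scalars or arrays; symmetric under BAF <-> 1 - BAF.
    """
    b = np.asarray(baf, dtype=float)
    if np.any((b < 0) | (b > 1) & np.isfinite(b)):
        raise ValueError("BAF outside [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        r = np.minimum(b / (1.0 - b), (1.0 - b) / b)
    r = np.where((b == 0) | (b == 1), 0.0, r)
    if np.isscalar(baf):
        return float(r)
    return r


def sample_rhet(table: SiteAlleleTable) -> np.ndarray:
    """Per-site R_Het for one sample; NaN where the site is unusable."""
    baf = table.baf
    out = np.full(len(baf), np.nan)
    ok = table.usable & np.isfinite(baf)
    out[ok] = compute_rhet(baf[ok])
    return out


def build_rhet_baseline(tables: list[SiteAlleleTable],
                        min_samples: int = 8) -> RHetBaseline:
    """Per-site median R_Het over samples with usable depth.

    Sites usable in fewer than `min_samples` samples are masked.
    """
    if len(tables) < min_samples:
        raise ValueError(
            f"R_Het baseline needs >= {min_samples} samples, got {len(tables)}")
    mat = np.vstack([sample_rhet(t) for t in tables])
    n_usable = np.sum(np.isfinite(mat), axis=0)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(mat, axis=0)
    mask = n_usable < min_samples
    med = np.where(mask, np.nan, med)
    if mask.any():
        logger.info("R_Het baseline: %d of %d sites masked",
                    int(mask.sum()), mat.shape[1])
    return RHetBaseline(med, len(tables), mask=mask)


def leave_one_out_rhet_baseline(tables: list[SiteAlleleTable], test_index: int,
                                min_samples: int = 8) -> RHetBaseline:
    rest = [t for i, t in enumerate(tables) if i != test_index]
    return build_rhet_baseline(
        rest, min_samples=min_samples - 1 if min_samples > 3 else min_samples)


# ---------------------------------------------------------------------------
# F test
# ---------------------------------------------------------------------------

def f_test_p(s2_test: float, s2_mul: float, n: int) -> tuple[float, float, float, bool]:
    """Two-sided F construction: returns (f_upper, f_under, p, degenerate).

    p = P(F > F_upper) + (1 - P(F > F_under)) at (n-1, n-1) df, clipped
    to 1.  A zero minimum variance (total loss of dispersion) floors p at
    the smallest representable value and sets the degenerate flag.
    """
    s2_max = max(s2_test, s2_mul)
    s2_min = min(s2_test, s2_mul)
    if s2_min <= 0:
        if s2_max <= 0:
            return 1.0, 1.0, 1.0, True
        return np.inf, 0.0, np.finfo(float).tiny, True
    f_upper = s2_max / s2_min
    f_under = s2_min / s2_max
    df = n - 1
    p_upper = stats.f.sf(f_upper, df, df)
    p_under = stats.f.sf(f_under, df, df)
    p = p_upper + (1.0 - p_under)
    return f_upper, f_under, float(min(p, 1.0)), False


def window_f_test(test_window: np.ndarray, baseline_window: np.ndarray,
                  anchor: int = -1, span: tuple[int, int] = (0, 0)) -> LohWindow:
    """Compare test-sample R_Het dispersion against the panel median's."""
    t = np.asarray(test_window, dtype=float)
    m = np.asarray(baseline_window, dtype=float)
    if t.shape != m.shape:
        raise ValueError("test and baseline windows differ in length")
    n = len(t)
    s2_test = float(np.var(t, ddof=1))
    s2_mul = float(np.var(m, ddof=1))
    f_upper, f_under, p, degen = f_test_p(s2_test, s2_mul, n)
    return LohWindow(anchor, span, s2_test, s2_mul, f_upper, f_under, p, degen)


def _sliding_var(x: np.ndarray, w: int) -> np.ndarray:
    """Sample variance (ddof=1) of every length-w window, via cumsums."""
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    var = (s2 - s1 * s1 / w) / (w - 1)
    return np.maximum(var, 0.0)


def windowed_f_tests(test_rhet: np.ndarray, baseline_rhet: np.ndarray,
                     usable: np.ndarray, chrom_ids: np.ndarray,
                     params: LohParams) -> dict[str, np.ndarray]:
    """Sliding-window F tests over usable sites, per chromosome.

    Windows slide by one usable site and never cross chromosomes; the
    anchor is the window's first site.  Returns site-aligned arrays
    (NaN at non-anchor positions): p, f_upper, mean difference gate.
    """
    n = len(test_rhet)
    p = np.full(n, np.nan)
    f_up = np.full(n, np.nan)
    gate = np.zeros(n, dtype=bool)
    span_end = np.full(n, -1, dtype=int)
    w = params.window
    df = w - 1
    ok = usable & np.isfinite(test_rhet) & np.isfinite(baseline_rhet)
    for chrom in np.unique(chrom_ids):
        idx = np.flatnonzero((chrom_ids == chrom) & ok)
        if len(idx) < w:
            continue
        t = test_rhet[idx]
        m = baseline_rhet[idx]
        v_t = _sliding_var(t, w)
        v_m = _sliding_var(m, w)
        s_max = np.maximum(v_t, v_m)
        s_min = np.minimum(v_t, v_m)
        with np.errstate(divide="ignore", invalid="ignore"):
            fu = np.where(s_min > 0, s_max / s_min, np.inf)
            fl = np.where(s_max > 0, s_min / s_max, 1.0)
        pv = np.where(
            s_min > 0,
            np.minimum(stats.f.sf(fu, df, df) + 1.0 - stats.f.sf(fl, df, df), 1.0),
            np.where(s_max > 0, np.finfo(float).tiny, 1.0),
        )
        c_t = np.concatenate([[0.0], np.cumsum(t)])
        c_m = np.concatenate([[0.0], np.cumsum(m)])
        mean_t = (c_t[w:] - c_t[:-w]) / w
        mean_m = (c_m[w:] - c_m[:-w]) / w
        anchors = idx[: len(pv)]
        p[anchors] = pv
        f_up[anchors] = fu
        # LOH collapses both the level and the dispersion of R_Het in the
        # test sample; without the variance condition the test's genotype-
        # driven variance (bimodal 0/1) systematically exceeds the panel
        # median's and the two-sided F fires on the wrong tail.
        gate[anchors] = (mean_t < mean_m) & (v_t < v_m)
        span_end[anchors] = idx[np.arange(len(pv)) + w - 1]
    return {"p": p, "f_upper": f_up, "gate": gate, "span_end": span_end}


# ---------------------------------------------------------------------------
# Scan / extend
# ---------------------------------------------------------------------------

def scan_loh(p_values: np.ndarray, p_loh: float = 0.01,
             init_run: int = 3) -> list[tuple[int, int]]:
    """Find maximal runs of >= init_run consecutive anchors with p < p_loh.

    Anchors with NaN p (no window) break runs.  Returns half-open
    anchor-index intervals.
    """
    sig = np.isfinite(p_values) & (p_values < p_loh)
    intervals: list[tuple[int, int]] = []
    i, n = 0, len(sig)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j < n and sig[j]:
            j += 1
        if j - i >= init_run:
            intervals.append((i, j))
        i = j
    return intervals


def extend_loh(interval: tuple[int, int], p_values: np.ndarray,
               p_loh: float = 0.01, mean_p_cap: float = 0.1) -> tuple[int, int]:
    """Greedy extension of a seeded interval in both directions.

    Adjacent anchors with p < p_loh are always absorbed; at most one
    consecutive anchor with p >= p_loh may be absorbed provided the
    running mean p of the extended interval stays below `mean_p_cap`.
    Two consecutive above-threshold anchors stop the extension.
    """
    lo, hi = interval
    n = len(p_values)

    def mean_p(a, b):
        vals = p_values[a:b]
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals)) if len(vals) else np.inf

    # extend right
    excursion = False
    j = hi
    while j < n and np.isfinite(p_values[j]):
        if p_values[j] < p_loh:
            hi = j + 1
            excursion = False
        elif not excursion and mean_p(lo, j + 1) < mean_p_cap:
            hi = j + 1
            excursion = True
        else:
            break
        j += 1
    if excursion and p_values[hi - 1] >= p_loh:
        hi -= 1  # never end on a tolerated excursion
    # extend left
    excursion = False
    j = lo - 1
    while j >= 0 and np.isfinite(p_values[j]):
        if p_values[j] < p_loh:
            lo = j
            excursion = False
        elif not excursion and mean_p(j, hi) < mean_p_cap:
            lo = j
            excursion = True
        else:
            break
        j -= 1
    if excursion and p_values[lo] >= p_loh:
        lo += 1
    return lo, hi


# ---------------------------------------------------------------------------
# Full chain and UPD classification
# ---------------------------------------------------------------------------

def call_loh(table: SiteAlleleTable, baseline: RHetBaseline,
             sites: list[SnpSite], params: LohParams | None = None,
             return_tracks: bool = False):
    """Windowed F tests -> seed -> extend -> genomic intervals.

    Returns raw LohCall candidates (no size filter, class 'LOH'); pass
    them through :func:`classify_upd` for the reportable set.
    """
    if params is None:
        params = LohParams()
    chrom_ids = np.array([s.chrom for s in sites], dtype=object)
    test = sample_rhet(table)
    res = windowed_f_tests(test, baseline.median_rhet,
                           table.usable & ~baseline.mask, chrom_ids, params)
    # Scan and extension run over consecutive WINDOWS (anchor space):
    # sites without a window — unusable depth or masked baseline — are
    # skipped, not treated as run breaks.  The directional gate decides
    # where intervals may START (a true LOH window has both lower mean
    # and lower variance than the baseline); extension and continuity
    # follow the plain p-value rule so a single gate dropout inside an
    # event does not fragment it.
    anchor_idx = np.flatnonzero(np.isfinite(res["p"]))
    p_ext = res["p"][anchor_idx]
    p_seed = p_ext.copy()
    if params.directional:
        p_seed[~res["gate"][anchor_idx]] = np.nan
    anchor_chrom = chrom_ids[anchor_idx]
    calls: list[LohCall] = []
    raw = scan_loh(p_seed, p_loh=params.p_loh, init_run=params.init_run)
    merged: list[tuple[int, int]] = []
    for iv in raw:
        lo, hi = extend_loh(iv, p_ext, p_loh=params.p_loh,
                            mean_p_cap=params.mean_p_cap)
        # clip the extension to the seed's chromosome
        while lo < iv[0] and anchor_chrom[lo] != anchor_chrom[iv[0]]:
            lo += 1
        while hi > iv[1] and anchor_chrom[hi - 1] != anchor_chrom[iv[0]]:
            hi -= 1
        # extended intervals separated by a handful of anchors describe
        # one event fragmented by local dropouts: bridge them
        # (same-chromosome only), mirroring the CNV merge heuristic
        if merged and lo - merged[-1][1] <= params.merge_gap \
                and anchor_chrom[lo] == anchor_chrom[merged[-1][0]]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    for lo, hi in merged:
        first_site = int(anchor_idx[lo])
        last_anchor = int(anchor_idx[hi - 1])
        end_site = int(res["span_end"][last_anchor])
        if end_site < 0:
            end_site = last_anchor
        chrom = sites[first_site].chrom
        start = sites[first_site].pos
        end = sites[end_site].pos + 1
        vals = p_ext[lo:hi]
        vals = vals[np.isfinite(vals)]
        calls.append(LohCall(table.sample_id, chrom, start, end,
                             n_sites=end_site - first_site + 1,
                             mean_p=float(np.mean(vals)) if len(vals) else np.nan,
                             site_span=(first_site, end_site + 1)))
    if return_tracks:
        return calls, res
    return calls


def classify_upd(candidates: list[LohCall], cnv_calls: list[CnvCall],
                 min_size_bp: int = 5_000_000,
                 keep_small: bool = False) -> list[LohCall]:
    """Intersect LOH candidates with CNV calls to separate UPD from LOH.

    The copy number with majority overlap decides: CN 2 (including no
    overlapping CNV call at all) -> UPD; any other CN -> LOH_nonUPD.
    Candidates below `min_size_bp` are dropped unless `keep_small`.
    """
    out: list[LohCall] = []
    for c in candidates:
        best_cn, best_ov = 2, 0
        for cv in cnv_calls:
            if cv.sample_id != c.sample_id or cv.chrom != c.chrom:
                continue
            ov = min(c.end, cv.end) - max(c.start, cv.start)
            if ov > best_ov:
                best_ov, best_cn = ov, cv.cn
        if best_ov <= (c.end - c.start) / 2:
            best_cn = 2  # majority of the LOH interval is copy-neutral
        c.cn_context = best_cn
        c.loh_class = "UPD" if best_cn == 2 else "LOH_nonUPD"
        if c.size_bp >= min_size_bp or keep_small:
            out.append(c)
    return out


def check_consistency(loh_calls: list[LohCall], cnv_calls: list[CnvCall],
                      min_size_bp: int = 5_000_000) -> list[str]:
    """QC: every reportable CN=1 CNV call must overlap an LOH call.

    A hemizygous deletion leaves one haplotype, so heterozygosity is
    necessarily lost there; a CN=1 call without LOH support is suspect.
    """
    warnings_out: list[str] = []
    for cv in cnv_calls:
        if cv.cn != 1 or cv.size_bp < min_size_bp:
            continue
        hit = any(l.sample_id == cv.sample_id and l.chrom == cv.chrom
                  and min(l.end, cv.end) - max(l.start, cv.start) > 0
                  for l in loh_calls)
        if not hit:
            msg = (f"{cv.sample_id}: CN=1 call {cv.chrom}:{cv.start}-{cv.end} "
                   f"has no overlapping LOH call")
            logger.warning(msg)
            warnings_out.append(msg)
    return warnings_out
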
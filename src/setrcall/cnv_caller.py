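"""CNV calling from baseline-normalized depth ratios.

Per probe, the test sample's ratio is compared against the panel with a
one-vs-panel t test; runs of four consecutive same-direction probes with
three p-values under the primary threshold (and the fourth under four
times it) are marked with a '+'/'-' pseudo-signal; same-sign marked runs
separated by at most `max_gap` unmarked probes merge; each merged
candidate is re-tested at region level (one-sample t on the per-probe
deviations Z_i), its boundaries refined on the unsmoothed ratio, and its
integer copy number assigned as round(mean ratio / 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .depth_normalization import BaselinePanel, RatioProfile
from .io_formats import SEX_CHROMS, CytobandTable, TargetSet

logger = logging.getLogger("setrcall")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ProbeTestResult:
    """Per-probe one-vs-panel t test outcome."""

    index: int
    z: float
    t_score: float
    p_value: float
    pseudo_signal: str = "none"  # {+, -, none}


@dataclass
class CnvCall:
    sample_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    mean_r_m: float
    region_t: float
    region_p: float
    cn: int
    direction: str  # {loss, gain}
    is_aneuploidy: bool = False
    probe_span: tuple[int, int] = field(default=(0, 0))  # target indices, half-open

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    def as_row(self):
        return {
            "sample": self.sample_id, "chrom": self.chrom,
            "start": self.start, "end": self.end, "size_bp": self.size_bp,
            "n_probes": self.n_probes, "mean_ratio": self.mean_r_m,
            "t_or_F_stat": self.region_t, "p_value": self.region_p,
            "CN": self.cn,
            "class": ("aneuploidy" if self.is_aneuploidy else self.direction),
        }


@dataclass
class SexAssignment:
    sample_id: str
    sex: str  # {XX, XY, other, unknown}
    chrx_mean_r: float
    chry_mean_r: float


@dataclass
class CnvParams:
    """Tunables for the calling chain (see docs/methods.md for rationale)."""

    p_probe: float = 0.05       # primary probe-level threshold
    p_seed2: float = 0.2        # relaxed threshold for the 4th probe in a seed
    seed_window: int = 4        # probes per seeding window
    seed_hits: int = 3          # probes under p_probe required per window
    max_gap: int = 5            # unmarked probes bridged when merging runs
    p_region: float = 0.05      # region-level significance
    min_probes: int = 45        # minimum probes per reported call
    min_size_bp: int = 1_000_000
    aneuploidy_fraction: float = 0.9
    refine_boundaries: bool = True
    confirm_on_raw: bool = True  # re-test candidates on the unsmoothed ratio
    p_confirm: float | None = None  # None -> p_region / n_targets (genome-wide)


# ---------------------------------------------------------------------------
# Probe-level statistics
# ---------------------------------------------------------------------------

def probe_level_ttest(r_m_test: float, panel_values: np.ndarray) -> ProbeTestResult:
    """One test value against a panel: t = (x - mean) / sqrt(S^2 (1 + 1/n)).

    df = n - 1 with n the panel size; p is two-sided.
    """
    panel_values = np.asarray(panel_values, dtype=float)
    n = len(panel_values)
    mean = float(np.mean(panel_values))
    s2 = float(np.var(panel_values, ddof=1))
    z = r_m_test - mean
    if s2 <= 0:
        return ProbeTestResult(-1, z, np.nan, np.nan, "none")
    t = z / np.sqrt(s2 * (1.0 + 1.0 / n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return ProbeTestResult(-1, z, t, max(p, np.finfo(float).tiny), "none")


def probe_tests(test_r_m: np.ndarray, panel_r_m: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized probe-level t tests across all targets.

    `panel_r_m` is (n_samples, n_targets).  Probes with zero panel
    variance or non-finite values are masked (NaN t and p).
    """
    panel_r_m = np.asarray(panel_r_m, dtype=float)
    n = panel_r_m.shape[0]
    mean = np.nanmean(panel_r_m, axis=0)
    s2 = np.nanvar(panel_r_m, axis=0, ddof=1)
    z = test_r_m - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        t = z / np.sqrt(s2 * (1.0 + 1.0 / n))
    bad = ~np.isfinite(test_r_m) | ~np.isfinite(s2) | (s2 <= 0)
    t = np.where(bad, np.nan, t)
    p = np.full_like(t, np.nan)
    ok = np.isfinite(t)
    p[ok] = np.maximum(2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1),
                       np.finfo(float).tiny)
    if np.any(bad & np.isfinite(test_r_m)):
        logger.debug("%d probes masked in probe-level test", int(np.sum(bad)))
    return {"z": z, "t": t, "p": p}


# ---------------------------------------------------------------------------
# Seeding and merging
# ---------------------------------------------------------------------------

def seed_pseudo_signals(t: np.ndarray, p: np.ndarray, chrom_ids: np.ndarray,
                        p1: float = 0.05, p2: float = 0.2,
                        window: int = 4, min_hits: int = 3) -> np.ndarray:
    """Mark probes with '+'/'-' pseudo-signals via the sliding 4-probe rule.

    A window of `window` consecutive same-chromosome probes qualifies when
    all t-scores share one sign, at least `min_hits` p-values are < p1, and
    every remaining p-value is <= p2.  All probes of a qualifying window are
    marked; overlapping windows accumulate marks.
    """
    n = len(t)
    marks = np.zeros(n, dtype="<U1")
    marks[:] = ""
    for i in range(n - window + 1):
        sl = slice(i, i + window)
        if len(set(chrom_ids[sl])) != 1:
            continue
        tw, pw = t[sl], p[sl]
        if np.any(~np.isfinite(tw)) or np.any(~np.isfinite(pw)):
            continue
        if np.all(tw < 0):
            sign = "-"
        elif np.all(tw > 0):
            sign = "+"
        else:
            continue
        hits = int(np.sum(pw < p1))
        if hits < min_hits:
            continue
        if np.any(pw[pw >= p1] > p2):
            continue
        cur = marks[sl]
        if np.any((cur != "") & (cur != sign)):
            continue  # never overwrite the opposite sign
        marks[sl] = sign
    return marks


def merge_marked_runs(marks: np.ndarray, chrom_ids: np.ndarray,
                      max_gap: int = 5) -> list[tuple[int, int, str]]:
    """Merge same-sign marked runs separated by <= max_gap unmarked probes.

    Returns half-open probe-index intervals (lo, hi, sign).  Merging
    includes the gap probes and iterates to a fixpoint (single left-to-
    right pass suffices since gaps only shrink leftward).
    """
    runs: list[tuple[int, int, str]] = []
    i = 0
    n = len(marks)
    while i < n:
        if marks[i] == "":
            i += 1
            continue
        sign = marks[i]
        j = i
        while j < n and marks[j] == sign and chrom_ids[j] == chrom_ids[i]:
            j += 1
        runs.append((i, j, sign))
        i = j
    merged: list[tuple[int, int, str]] = []
    for run in runs:
        if merged:
            lo, hi, sign = merged[-1]
            nlo, nhi, nsign = run
            gap = nlo - hi
            if (sign == nsign and gap <= max_gap
                    and chrom_ids[hi - 1] == chrom_ids[nlo]
                    and np.all(marks[hi:nlo] == "")):
                merged[-1] = (lo, nhi, sign)
                continue
        merged.append(run)
    return merged


# ---------------------------------------------------------------------------
# Region-level statistics, refinement, CN
# ---------------------------------------------------------------------------

def region_level_ttest(z_values: np.ndarray) -> tuple[float, float]:
    """One-sample t of the interval's Z_i against 0; df = m - 1, two-sided.

    Degenerate intervals (SD = 0) get the smallest representable p and a
    +/-inf statistic so they are never silently dropped.
    """
    z_values = np.asarray(z_values, dtype=float)
    z_values = z_values[np.isfinite(z_values)]
    m = len(z_values)
    if m < 2:
        return np.nan, np.nan
    sd = float(np.std(z_values, ddof=1))
    mean = float(np.mean(z_values))
    if sd == 0:
        logger.warning("region with zero Z dispersion; p floored")
        return np.inf * np.sign(mean) if mean else 0.0, np.finfo(float).tiny
    t = mean * np.sqrt(m) / sd
    p = 2.0 * stats.t.sf(abs(t), df=m - 1)
    return t, max(p, np.finfo(float).tiny)


def assign_copy_number(mean_r_m: float) -> int:
    """CN = round-half-up(mean ratio / 0.5), floored at zero.

    A diploid ratio of 1.0 gives CN 2; the half-up tie-break makes the
    mapping deterministic at ratio multiples of 0.25.
    """
    if not np.isfinite(mean_r_m):
        raise ValueError("cannot assign CN to non-finite ratio")
    cn = int(np.floor(mean_r_m / 0.5 + 0.5))
    return max(cn, 0)


def refine_boundaries(raw_ratio: np.ndarray, lo: int, hi: int,
                      chrom_lo: int, chrom_hi: int,
                      level: float, margin: int = 12) -> tuple[int, int]:
    """Least-squares changepoint fit of the call's edges on unsmoothed ratios.

    The downstream smoothing window drags a call's start upstream of the
    true edge, so each edge is re-fit within +/- `margin` probes by
    minimizing sum (x - 1)^2 outside + sum (x - level)^2 inside over the
    candidate breakpoints.  `level` is the event's unsmoothed ratio level.
    """
    x = raw_ratio

    def fit_edge(window_lo, window_hi, left_is_outside):
        seg = x[window_lo:window_hi]
        ok = np.isfinite(seg)
        segf = np.where(ok, seg, level if not left_is_outside else 1.0)
        out_cost = np.where(ok, (segf - 1.0) ** 2, 0.0)
        in_cost = np.where(ok, (segf - level) ** 2, 0.0)
        c_out = np.concatenate([[0.0], np.cumsum(out_cost)])
        c_in = np.concatenate([[0.0], np.cumsum(in_cost)])
        m = len(seg)
        ks = np.arange(m + 1)
        if left_is_outside:  # outside on [0,k), inside on [k,m)
            cost = c_out[ks] + (c_in[m] - c_in[ks])
        else:                # inside on [0,k), outside on [k,m)
            cost = c_in[ks] + (c_out[m] - c_out[ks])
        return window_lo + int(np.argmin(cost))

    start_lo = max(chrom_lo, lo - margin)
    start_hi = min(hi, lo + margin)
    end_lo = max(lo, hi - margin)
    end_hi = min(chrom_hi, hi + margin)
    new_lo = fit_edge(start_lo, start_hi, left_is_outside=True)
    new_hi = fit_edge(end_lo, end_hi, left_is_outside=False)
    if new_hi <= new_lo:
        return lo, hi
    return new_lo, new_hi


# ---------------------------------------------------------------------------
# Sex inference & karyotype rendering
# ---------------------------------------------------------------------------

def infer_sex(profile: RatioProfile, targets: TargetSet,
              xx_band: tuple[float, float] = (0.65, 0.85)) -> SexAssignment:
    """Classify XX/XY from mean chrX ratio (vs autosomes) and chrY coverage.

    chrX mean R near 1 with no chrY signal reads XX; near 0.5 with chrY
    coverage reads XY; the band [0.65, 0.85] around the 0.75 threshold is
    flagged 'other' for manual review.
    """
    chroms = targets.chrom_of()
    x_mask = np.isin(chroms, ["chrX", "X"])
    y_mask = np.isin(chroms, ["chrY", "Y"])
    x_mean = float(np.nanmean(profile.r[x_mask])) if x_mask.any() else np.nan
    y_mean = float(np.nanmean(profile.r[y_mask])) if y_mask.any() else np.nan
    if not np.isfinite(x_mean):
        return SexAssignment(profile.sample_id, "unknown", x_mean, y_mean)
    lo, hi = xx_band
    if lo <= x_mean <= hi:
        logger.warning("%s: ambiguous chrX ratio %.3f", profile.sample_id, x_mean)
        return SexAssignment(profile.sample_id, "other", x_mean, y_mean)
    if x_mean > hi:
        return SexAssignment(profile.sample_id, "XX", x_mean, y_mean)
    return SexAssignment(profile.sample_id, "XY", x_mean, y_mean)


def format_karyotype(sex: SexAssignment, calls: list[CnvCall],
                     cytobands: CytobandTable | None = None) -> str:
    """Render an ISCN-like string, e.g. '46,XY,del(5)(p14)' or '48,XXX,+18'.

    Whole-chromosome gains/losses adjust the modal number and appear as
    +N/-N tokens; segmental calls become del/dup tokens with band names
    from the cytoband table (coordinates if no table is given).
    """
    modal = 46
    sex_token = sex.sex if sex.sex in ("XX", "XY") else "??"
    tokens: list[str] = []
    aneu = [c for c in calls if c.is_aneuploidy]
    segmental = [c for c in calls if not c.is_aneuploidy]
    extra_x = 0
    for c in sorted(aneu, key=lambda c: c.chrom):
        c_name = c.chrom[3:] if c.chrom.startswith("chr") else c.chrom
        delta = c.cn - 2
        if c_name in ("X", "Y"):
            if c_name == "X" and delta > 0:
                extra_x += delta
                modal += delta
                continue
            modal += delta
            tokens.append(("+" if delta > 0 else "-") + c_name)
            continue
        modal += delta
        sign = "+" if delta > 0 else "-"
        tokens.extend([f"{sign}{c_name}"] * abs(delta))
    if extra_x:
        sex_token = sex_token + "X" * extra_x if sex_token != "??" else "??"
    for c in sorted(segmental, key=lambda c: (c.chrom, c.start)):
        c_name = c.chrom[3:] if c.chrom.startswith("chr") else c.chrom
        kind = "del" if c.cn < 2 else "dup"
        if cytobands is not None:
            b1 = cytobands.band_at(c.chrom, c.start)
            b2 = cytobands.band_at(c.chrom, max(c.start, c.end - 1))
            if b1 is None or b2 is None:
                span = f"{c.start + 1}-{c.end}"
            else:
                span = b1 if b1 == b2 else f"{b1}{b2}"
        else:
            span = f"{c.start + 1}-{c.end}"
        tokens.append(f"{kind}({c_name})({span})")
    return ",".join([str(modal), sex_token] + tokens)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def call_cnvs(profile: RatioProfile, panel_r_m: np.ndarray, targets: TargetSet,
              params: CnvParams | None = None,
              panel_raw: np.ndarray | None = None) -> list[CnvCall]:
    """Probe test -> seed -> merge -> region test -> filters -> CN.

    `panel_r_m` holds the panel samples' R_m values, shape
    (n_panel, n_targets), normalized against the same baseline as the
    test profile (leave-one-out when the test sample is a panel member).
    Whole-chromosome aberrations are reported as aneuploidies when at
    least `aneuploidy_fraction` of a chromosome's probes fall in
    same-direction calls.
    """
    if params is None:
        params = CnvParams()
    chroms = targets.chrom_of()
    res = probe_tests(profile.r_m, panel_r_m)
    raw = profile.pre_r_m if profile.pre_r_m is not None else profile.r_m
    raw_panel_mean = (np.nanmean(panel_raw, axis=0)
                      if panel_raw is not None else None)
    marks = seed_pseudo_signals(res["t"], res["p"], chroms,
                                p1=params.p_probe, p2=params.p_seed2,
                                window=params.seed_window,
                                min_hits=params.seed_hits)
    candidates = merge_marked_runs(marks, chroms, max_gap=params.max_gap)
    calls: list[CnvCall] = []
    for lo, hi, sign in candidates:
        if hi - lo < params.seed_window:
            continue
        t_stat, p_val = region_level_ttest(res["z"][lo:hi])
        if not np.isfinite(p_val) or p_val >= params.p_region:
            continue
        # Confirmation on the UNsmoothed ratio: downstream smoothing makes
        # neighbouring R_m values share depth draws, so a single lucky
        # window can masquerade as a sustained run.  The raw per-probe
        # ratios are independent, making this t's reference distribution
        # honest at df m-1.  The threshold is Bonferroni-corrected for the
        # genome-wide scan (candidates are the most extreme of ~n_targets
        # window positions); real events sit far beyond it.
        if params.confirm_on_raw:
            p_confirm = (params.p_confirm if params.p_confirm is not None
                         else params.p_region / max(len(targets), 1))
            base = raw_panel_mean[lo:hi] if raw_panel_mean is not None else 1.0
            _, p_raw = region_level_ttest(raw[lo:hi] - base)
            if not np.isfinite(p_raw) or p_raw >= p_confirm:
                continue
        chrom = targets[lo].chrom
        sl = targets.chrom_slice(chrom)
        # The candidate's level on the smoothed track is a low-variance
        # estimate of the segment ratio; a level that rounds to CN 2 is a
        # copy-neutral fluctuation, not a CNV.
        smooth_level = float(np.nanmedian(profile.r_m[lo:hi]))
        if np.isfinite(smooth_level) and assign_copy_number(smooth_level) == 2:
            continue
        level = float(np.nanmedian(raw[lo:hi]))
        if params.refine_boundaries and np.isfinite(level):
            lo, hi = refine_boundaries(raw, lo, hi, sl.start, sl.stop, level)
        mean_ratio = float(np.nanmean(raw[lo:hi]))
        if not np.isfinite(mean_ratio):
            mean_ratio = float(np.nanmean(profile.r_m[lo:hi]))
        n_probes = hi - lo
        start = targets[lo].start
        end = targets[hi - 1].end
        if n_probes < params.min_probes:
            continue
        if end - start < params.min_size_bp:
            continue
        cn = assign_copy_number(mean_ratio)
        if cn == 2:
            continue  # copy-neutral after refinement: not a CNV
        direction = "loss" if cn < 2 else "gain"
        calls.append(CnvCall(profile.sample_id, chrom, start, end, n_probes,
                             mean_ratio, t_stat, p_val, cn, direction,
                             probe_span=(lo, hi)))
    _flag_aneuploidies(calls, targets, params)
    return calls


def _flag_aneuploidies(calls: list[CnvCall], targets: TargetSet,
                       params: CnvParams) -> None:
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, chrom_calls in by_chrom.items():
        sl = targets.chrom_slice(chrom)
        n_chrom = sl.stop - sl.start
        for direction in ("loss", "gain"):
            dcalls = [c for c in chrom_calls if c.direction == direction]
            covered = sum(c.n_probes for c in dcalls)
            if n_chrom and covered / n_chrom >= params.aneuploidy_fraction:
                for c in dcalls:
                    c.is_aneuploidy = True
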
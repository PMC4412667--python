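"""Depth-of-coverage normalization against a multi-sample median baseline.

The chain per sample is

    TD_i   = bases_i / length_i              (mean depth per target)
    TD_mi  = mean(TD_i .. TD_{i+n})          (downstream smoothing, n = 10)
    R_i    = TD_mi / mean(TD_m over autosomes)
    R_mi   = R_i / median_panel(R_i)         (panel-of-normals baseline)

plus the diagnostic preR_i = TD_i / mean(TD).  The per-target median of
R_i across >= 8 samples stands in for a matched control: capture
efficiency is a probe property shared by all samples, so dividing by the
panel median cancels it and leaves copy-number signal plus counting noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import DepthProfile, TargetSet

logger = logging.getLogger("setrcall")

#: smoothing window: target i plus SMOOTH_N downstream targets
SMOOTH_N = 10
#: minimum number of samples for a trustworthy median baseline
MIN_BASELINE_SAMPLES = 8


class BaselineError(ValueError):
    pass


@dataclass
class RatioProfile:
    """Per-target depth ratios for one sample.

    `r_m` is NaN where the baseline is masked; `pre_r_m` is the analogous
    ratio built from the unsmoothed preR_i, used for boundary refinement
    and copy-number estimation where smoothing bias matters.
    """

    sample_id: str
    pre_r: np.ndarray
    td_m: np.ndarray
    r: np.ndarray
    r_m: np.ndarray = field(default=None)  # type: ignore[assignment]
    pre_r_m: np.ndarray = field(default=None)  # type: ignore[assignment]
    autosomal_mean: float = float("nan")


@dataclass
class BaselinePanel:
    """Per-target median of R_i (and of preR_i) across the sample panel."""

    median_r: np.ndarray
    median_pre_r: np.ndarray
    n_samples: int
    sample_ids: list[str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.mask is None:
            self.mask = ~((self.median_r > 0) & np.isfinite(self.median_r))


def compute_region_depth(base_counts: np.ndarray, targets: TargetSet,
                         sample_id: str = "sample",
                         dialect: str = "base-count") -> DepthProfile:
    """TD_i = aligned bases over region i divided by its length.

    With dialect "mean-depth" the input is already per-base depth and
    passes through unchanged.
    """
    base_counts = np.asarray(base_counts, dtype=float)
    if len(base_counts) != len(targets):
        raise ValueError("base-count vector length does not match target set")
    lengths = targets.lengths()
    if np.any(lengths <= 0):
        raise ValueError("zero-length region in target set")
    if dialect == "mean-depth":
        td = base_counts.copy()
    else:
        td = base_counts / lengths
    n_zero = int(np.sum(td == 0))
    if n_zero:
        logger.debug("%s: %d targets with zero depth", sample_id, n_zero)
    return DepthProfile(sample_id, td)


def smooth_depth(profile: DepthProfile, targets: TargetSet,
                 n: int = SMOOTH_N) -> np.ndarray:
    """TD_mi: mean of TD over targets i..i+n on the same chromosome.

    Near a chromosome end the window truncates to the remaining targets
    (divisor = actual window size); windows never cross chromosomes.
    """
    td = profile.td
    out = np.empty_like(td)
    for chrom in targets.chroms:
        sl = targets.chrom_slice(chrom)
        x = td[sl]
        m = len(x)
        if m < 2:
            logger.warning("chromosome %s has %d target(s); TD_m = TD", chrom, m)
            out[sl] = x
            continue
        # cumulative sum gives every truncated trailing window in O(m)
        cs = np.concatenate([[0.0], np.cumsum(x)])
        idx = np.arange(m)
        hi = np.minimum(idx + n + 1, m)
        out[sl] = (cs[hi] - cs[idx]) / (hi - idx)
    return out


def compute_pre_ratio(profile: DepthProfile) -> np.ndarray:
    """preR_i = TD_i / mean(TD over all targets)."""
    mean_td = float(np.mean(profile.td))
    if mean_td == 0:
        raise ValueError(f"sample {profile.sample_id}: empty library (all-zero depth)")
    return profile.td / mean_td


def compute_ratio(td_m: np.ndarray, targets: TargetSet) -> tuple[np.ndarray, float]:
    """R_i = TD_mi / mean(TD_m over autosomal targets).

    The divisor excludes sex chromosomes so a male sample's halved chrX
    coverage does not deflate the genome-wide scale; R_i is still defined
    for every target including X/Y.
    """
    auto = targets.autosomal_mask()
    if not auto.any():
        raise ValueError("target set has no autosomal targets")
    denom = float(np.mean(td_m[auto]))
    if denom == 0:
        raise ValueError("zero autosomal mean depth")
    return td_m / denom, denom


def make_ratio_profile(profile: DepthProfile, targets: TargetSet,
                       n: int = SMOOTH_N) -> RatioProfile:
    """Run the per-sample chain TD -> preR, TD_m, R (baseline applied later)."""
    pre_r = compute_pre_ratio(profile)
    td_m = smooth_depth(profile, targets, n=n)
    r, denom = compute_ratio(td_m, targets)
    return RatioProfile(profile.sample_id, pre_r=pre_r, td_m=td_m, r=r,
                        autosomal_mean=denom)


def build_baseline(profiles: list[RatioProfile],
                   min_samples: int = MIN_BASELINE_SAMPLES,
                   max_zero_fraction: float = 0.5) -> BaselinePanel:
    """Per-target median of R_i (ordinary median) across the panel.

    Requires at least `min_samples` profiles — below roughly 8 random
    samples a median at any one probe is no longer robust to a variant
    carrier in the panel.  Targets with zero depth in more than
    `max_zero_fraction` of samples are masked genome-wide.
    """
    if len(profiles) < min_samples:
        raise BaselineError(
            f"baseline needs >= {min_samples} samples (8-sample minimum rule); "
            f"got {len(profiles)}")
    R = np.vstack([p.r for p in profiles])
    P = np.vstack([p.pre_r for p in profiles])
    median_r = np.median(R, axis=0)
    median_pre_r = np.median(P, axis=0)
    zero_frac = np.mean(P == 0, axis=0)
    mask = (median_r <= 0) | ~np.isfinite(median_r) | (zero_frac > max_zero_fraction)
    if mask.any():
        logger.info("baseline: %d of %d targets masked", int(mask.sum()), R.shape[1])
    return BaselinePanel(median_r, median_pre_r, len(profiles),
                         [p.sample_id for p in profiles], mask=mask)


def normalize_by_baseline(profile: RatioProfile, panel: BaselinePanel) -> RatioProfile:
    """R_mi = R_i / median_panel(R_i); masked targets propagate as NaN."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r_m = np.where(panel.mask, np.nan, profile.r / panel.median_r)
        pre_r_m = np.where(
            panel.mask | (panel.median_pre_r <= 0), np.nan,
            profile.pre_r / panel.median_pre_r)
    profile.r_m = r_m
    profile.pre_r_m = pre_r_m
    return profile


def leave_one_out_baseline(profiles: list[RatioProfile], test_index: int,
                           min_samples: int = MIN_BASELINE_SAMPLES,
                           **kwargs) -> BaselinePanel:
    """Baseline median over every panel sample except the test sample.

    Prevents a large event in the test sample from dragging its own
    baseline toward the aberration (self-suppression).
    """
    rest = [p for i, p in enumerate(profiles) if i != test_index]
    return build_baseline(rest, min_samples=min_samples - 1
                          if min_samples > 3 else min_samples, **kwargs)
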
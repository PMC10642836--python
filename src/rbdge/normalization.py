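"""nCounter count normalization and noise filtering.

Three stages, applied in a fixed order:

1. **Technical normalization** — each lane is rescaled by
   ``f_l = mean(g) / g_l`` where ``g_l`` is the geometric mean of that lane's
   positive-control counts and ``mean(g)`` the cohort arithmetic mean of the
   per-lane geometric means; then the lane's background threshold
   ``tau_l = mu_l + 2 sigma_l`` (mean + 2 SD of the scaled negative controls,
   SD with the n-1 denominator) is subtracted from every non-control probe,
   floored at zero.  Control probes ride through scaled but unsubtracted.
2. **Biological (reference) normalization** — each lane is rescaled by
   ``r_l = mean(h) / h_l`` with ``h_l`` the geometric mean of the lane's
   positive-count housekeeping probes.
3. **Noise filter** — per endogenous gene, a one-sided one-sample t-test of
   its normalized counts against the pooled threshold ``mu0`` (the mean over
   lanes of ``tau_l`` recomputed on the normalized scale); a gene with
   p > 0.05 is flagged below noise.  Flagged genes are retained, not deleted;
   downstream differential testing excludes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rcc import CountMatrix

NOISE_ALPHA = 0.05


class NormalizationError(ValueError):
    """Raised when a lane cannot be normalized (zero controls etc.)."""


@dataclass
class TechnicalFactors:
    sample_ids: list[str]
    geo_means: np.ndarray   # g_l
    factors: np.ndarray     # f_l = mean(g) / g_l
    basis: str = "all"      # which positive probes entered g_l


@dataclass
class BackgroundEstimate:
    sample_id: str
    mean: float
    sd: float

    @property
    def threshold(self) -> float:
        """tau = mu + 2 sigma."""
        return self.mean + 2.0 * self.sd


@dataclass
class ReferenceFactors:
    sample_ids: list[str]
    geo_means: np.ndarray   # h_l
    factors: np.ndarray     # r_l = mean(h) / h_l


@dataclass
class NoiseCall:
    gene: str
    t_statistic: float
    p_value: float

    @property
    def above_noise(self) -> bool:
        return self.p_value <= NOISE_ALPHA


def _geometric_mean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def positive_factors(raw: CountMatrix, basis: str = "all") -> TechnicalFactors:
    """Per-lane positive-control scale factors.

    ``basis='exclude_lowest'`` drops the 0.125 fM ladder probe, whose counts
    sit near background, from the geometric mean.
    """
    pos_rows = raw.rows_of_class("Positive")
    if pos_rows.size == 0:
        raise NormalizationError("no positive-control probes")
    if basis == "exclude_lowest" and pos_rows.size > 1:
        concs = np.array(
            [raw.codeset.probes[i].expected_concentration for i in pos_rows]
        )
        pos_rows = pos_rows[concs > concs.min()]
    elif basis not in ("all", "exclude_lowest"):
        raise NormalizationError(f"unknown factor basis {basis!r}")

    geo_means = np.empty(len(raw.sample_ids))
    for j, sid in enumerate(raw.sample_ids):
        lane = raw.values[pos_rows, j]
        if np.any(lane <= 0):
            raise NormalizationError(
                f"lane {sid!r}: zero positive-control count, geometric mean undefined"
            )
        geo_means[j] = _geometric_mean(lane)
    factors = geo_means.mean() / geo_means
    return TechnicalFactors(list(raw.sample_ids), geo_means, factors, basis)


def estimate_backgrounds(matrix: CountMatrix) -> list[BackgroundEstimate]:
    """Mean and SD (ddof=1) of each lane's negative-control counts."""
    neg_rows = matrix.rows_of_class("Negative")
    if neg_rows.size < 2:
        raise NormalizationError(
            f"need >=2 negative-control probes for an SD, got {neg_rows.size}"
        )
    out = []
    for j, sid in enumerate(matrix.sample_ids):
        lane = matrix.values[neg_rows, j]
        out.append(BackgroundEstimate(sid, float(lane.mean()), float(lane.std(ddof=1))))
    return out


def technical_normalize(
    raw: CountMatrix,
    basis: str = "all",
    order: str = "scale_then_subtract",
) -> tuple[CountMatrix, TechnicalFactors, list[BackgroundEstimate]]:
    """Positive-control lane scaling plus mean+2SD background subtraction.

    ``order`` controls whether the background threshold is computed on the
    scaled lane (default) or subtracted on the raw scale before scaling.
    """
    if order not in ("scale_then_subtract", "subtract_then_scale"):
        raise NormalizationError(f"unknown order {order!r}")
    factors = positive_factors(raw, basis=basis)

    noncontrol = np.concatenate(
        [raw.rows_of_class("Endogenous"), raw.rows_of_class("Housekeeping")]
    )

    if order == "scale_then_subtract":
        scaled = raw.values * factors.factors[None, :]
        work = raw.copy_with(scaled)
        backgrounds = estimate_backgrounds(work)
        values = work.values.copy()
        for j, bg in enumerate(backgrounds):
            values[noncontrol, j] = np.maximum(values[noncontrol, j] - bg.threshold, 0.0)
    else:
        backgrounds = estimate_backgrounds(raw)
        values = raw.values.copy()
        for j, bg in enumerate(backgrounds):
            values[noncontrol, j] = np.maximum(values[noncontrol, j] - bg.threshold, 0.0)
        values = values * factors.factors[None, :]

    return raw.copy_with(values), factors, backgrounds


def reference_normalize(matrix: CountMatrix) -> tuple[CountMatrix, ReferenceFactors]:
    """Housekeeping geometric-mean normalization (mean-anchored)."""
    hk_rows = matrix.rows_of_class("Housekeeping")
    if hk_rows.size == 0:
        raise NormalizationError("no housekeeping probes")
    geo_means = np.empty(len(matrix.sample_ids))
    for j, sid in enumerate(matrix.sample_ids):
        lane = matrix.values[hk_rows, j]
        lane = lane[lane > 0]
        if lane.size == 0:
            raise NormalizationError(f"lane {sid!r}: all housekeeping counts are zero")
        geo_means[j] = _geometric_mean(lane)
    factors = geo_means.mean() / geo_means
    values = matrix.values * factors[None, :]
    return matrix.copy_with(values), ReferenceFactors(list(matrix.sample_ids), geo_means, factors)


def noise_filter(
    matrix: CountMatrix,
    mu0: float | None = None,
    per_lane: bool = False,
) -> list[NoiseCall]:
    """One-sided t-test of each endogenous gene against the noise threshold.

    ``mu0`` defaults to the pooled threshold: the mean over lanes of
    ``tau_l`` recomputed from the negative-control rows of ``matrix`` (i.e.
    on the normalized scale).  With ``per_lane=True`` each count has its own
    lane's ``tau_l`` subtracted and the test runs against zero.

    Zero-variance genes get p = 0 if their mean exceeds the threshold and
    p = 1 otherwise, so degenerate genes receive a decision rather than an
    exception.
    """
    if len(matrix.sample_ids) < 2:
        raise NormalizationError("noise filter needs >=2 samples")
    backgrounds = estimate_backgrounds(matrix)
    thresholds = np.array([bg.threshold for bg in backgrounds])

    endo_rows = matrix.rows_of_class("Endogenous")
    calls = []
    for i in endo_rows:
        gene = matrix.codeset.probes[i].name
        x = matrix.values[i, :]
        if per_lane:
            x = x - thresholds
            target = 0.0
        else:
            target = float(np.mean(thresholds)) if mu0 is None else mu0
        n = x.size
        sd = x.std(ddof=1)
        if sd == 0.0:
            t = np.inf if x.mean() > target else (-np.inf if x.mean() < target else 0.0)
            p = 0.0 if x.mean() > target else (1.0 if x.mean() < target else 0.5)
        else:
            t = (x.mean() - target) / (sd / np.sqrt(n))
            p = float(stats.t.sf(t, df=n - 1))
            t = float(t)
        calls.append(NoiseCall(gene, t, p))
    return calls


def normalize_pipeline(
    raw: CountMatrix,
    basis: str = "all",
    order: str = "scale_then_subtract",
    per_lane_noise: bool = False,
) -> tuple[CountMatrix, TechnicalFactors, ReferenceFactors, list[NoiseCall], list[BackgroundEstimate]]:
    """Full normalization: technical -> biological -> noise filter.

    Returns every intermediate for audit; below-noise genes are flagged in
    the returned calls, never removed from the matrix.
    """
    raw.codeset.validate_for_analysis()
    tech, tfactors, backgrounds = technical_normalize(raw, basis=basis, order=order)
    normalized, rfactors = reference_normalize(tech)
    calls = noise_filter(normalized, per_lane=per_lane_noise)
    return normalized, tfactors, rfactors, calls, backgrounds
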
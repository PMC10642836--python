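"""ROC-based composite biomarker scoring.

Each candidate gene gets an empirical ROC curve (URB as the positive class),
an AUC in its Mann-Whitney form (ties count one half), a percentile bootstrap
confidence interval (default 1,000 resamples) for internal validation, and a
Youden-J cutoff that binarizes expression per sample ("1 equaling a better
chance of an event", i.e. the URB side of the cutoff).  Binarized markers sum
to a per-sample composite score, whose discrimination is summarized by a
threshold sweep of sensitivity/specificity and by a two-parameter logistic
curve P(URB | S) = 1/(1+exp(-(a+bS))) fitted by (weighted) nonlinear least
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

POSITIVE_CLASS = "URB"
SLOPE_CAP = 50.0


class ScoringError(ValueError):
    """Raised for degenerate marker or label configurations."""


def _split_classes(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == POSITIVE_CLASS]
    neg = values[labels != POSITIVE_CLASS]
    if pos.size == 0 or neg.size == 0:
        raise ScoringError("both classes must be present")
    return pos, neg


@dataclass
class ROCCurve:
    thresholds: np.ndarray       # ascending; +/- inf endpoints included
    sensitivity: np.ndarray      # P(value > t | URB)
    specificity: np.ndarray      # P(value <= t | not URB)
    values: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def roc_curve(values: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """Empirical ROC over midpoints of adjacent distinct values plus +/-inf."""
    pos, neg = _split_classes(values, labels)
    values = np.asarray(values, dtype=float)
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    return ROCCurve(thresholds, sens, spec, values, np.asarray(labels))


def auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (URB, non-URB) pairs ranked correctly."""
    pos, neg = _split_classes(values, labels)
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


@dataclass
class AUCEstimate:
    auc: float
    ci_low: float
    ci_high: float
    n_iterations: int
    seed: int
    n_redraws: int = 0


def bootstrap_auc(
    values: np.ndarray, labels: np.ndarray, B: int = 1000, seed: int = 0
) -> AUCEstimate:
    """Percentile bootstrap CI for the AUC over full-cohort resamples.

    Resamples missing a class are redrawn (attempts counted); the estimate
    is fully determined by the seed.
    """
    if B < 1:
        raise ScoringError("bootstrap needs B >= 1")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    point = auc(values, labels)
    rng = np.random.default_rng(seed)
    n = values.size
    boot = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if (lab == POSITIVE_CLASS).any() and (lab != POSITIVE_CLASS).any():
                break
            redraws += 1
        boot[b] = auc(values[idx], lab)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return AUCEstimate(point, float(lo), float(hi), B, seed, redraws)


@dataclass
class GeneMarker:
    gene: str
    cutoff: float
    direction: str               # "up-in-URB" or "down-in-URB"
    binarized: pd.Series         # sample_id -> 0/1
    auc: float
    youden_j: float


def youden_cutoff(roc: ROCCurve) -> tuple[float, float]:
    """Cutoff maximizing J = sens + spec - 1; ties resolve toward the pooled
    median.  Returns (cutoff, J)."""
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise ScoringError("degenerate ROC: no finite cutoff available")
    thresholds = roc.thresholds[finite]
    j = roc.sensitivity[finite] + roc.specificity[finite] - 1.0
    best = j.max()
    candidates = thresholds[j == best]
    median = float(np.median(roc.values))
    cutoff = candidates[np.argmin(np.abs(candidates - median))]
    return float(cutoff), float(best)


def make_marker(
    gene: str, values: np.ndarray, labels: np.ndarray, sample_ids: list[str]
) -> GeneMarker:
    """Build a binarized marker: direction flipped so its AUC >= 0.5."""
    values = np.asarray(values, dtype=float)
    a = auc(values, labels)
    if a >= 0.5:
        direction, oriented = "up-in-URB", values
    else:
        direction, oriented = "down-in-URB", -values
        a = 1.0 - a
    roc = roc_curve(oriented, labels)
    cutoff, j = youden_cutoff(roc)
    bits = (oriented > cutoff).astype(int)
    if direction == "down-in-URB":
        cutoff = -cutoff
    return GeneMarker(
        gene, cutoff, direction, pd.Series(bits, index=sample_ids), a, j
    )


@dataclass
class CompositeScore:
    scores: pd.Series            # sample_id -> integer in [0, n markers]
    genes: list[str]


def composite_score(markers: list[GeneMarker]) -> CompositeScore:
    """Per-sample sum of binarized marker indicators."""
    if not markers:
        raise ScoringError("empty marker panel")
    index = markers[0].binarized.index
    for m in markers[1:]:
        if not m.binarized.index.equals(index):
            raise ScoringError("markers do not share a sample set")
    total = sum(m.binarized for m in markers)
    return CompositeScore(total.astype(int), [m.gene for m in markers])


def score_performance(
    score: CompositeScore, labels: np.ndarray, threshold: int
) -> tuple[float, float, pd.DataFrame]:
    """Sensitivity/specificity of 'URB iff S >= threshold', plus the sweep
    over every threshold 0..G+1."""
    labels = np.asarray(labels)
    s = score.scores.to_numpy()
    pos = s[labels == POSITIVE_CLASS]
    neg = s[labels != POSITIVE_CLASS]
    if pos.size == 0 or neg.size == 0:
        raise ScoringError("both classes must be present")

    def at(t: int) -> tuple[float, float]:
        return float((pos >= t).mean()), float((neg < t).mean())

    sweep = pd.DataFrame(
        [(t, *at(t)) for t in range(0, len(score.genes) + 2)],
        columns=["threshold", "sensitivity", "specificity"],
    )
    sens, spec = at(threshold)
    return sens, spec, sweep


@dataclass
class ProbabilityModel:
    intercept: float
    slope: float
    converged: str               # "converged" or "boundary"
    n_iterations: int
    weights: np.ndarray = field(repr=False, default=None)


def fit_probability_model(
    scores: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
) -> ProbabilityModel:
    """Least-squares logistic curve through (score, URB-indicator) points.

    Damped Gauss-Newton (Levenberg-Marquardt family via trust-region
    reflective with bounds), init (0, 0), relative tolerance 1e-8, at most
    500 iterations; the slope is capped at +/-50 and hitting the cap marks
    the fit "boundary" (perfectly separated scores).
    """
    s = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = (labels == POSITIVE_CLASS).astype(float)
    if y.min() == y.max():
        raise ScoringError("both classes must be present")
    if np.unique(s).size < 2:
        raise ScoringError("need >=2 distinct score values")
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b = theta
        p = 1.0 / (1.0 + np.exp(-(a + b * s)))
        return sw * (y - p)

    res = least_squares(
        residuals,
        x0=np.zeros(2),
        bounds=([-1e3, -SLOPE_CAP], [1e3, SLOPE_CAP]),
        xtol=1e-8, ftol=1e-8, gtol=1e-8,
        max_nfev=500,
    )
    a, b = res.x
    # separable scores: the objective vanishes and the slope runs away (or
    # hits the cap) -- flag so callers know the curve is a step, not a fit
    separated = float(np.max(np.abs(res.fun))) < 1e-4
    at_cap = abs(abs(b) - SLOPE_CAP) < 1e-6
    flag = "boundary" if (at_cap or separated) else "converged"
    return ProbabilityModel(float(a), float(b), flag, int(res.nfev), w)


def predict_probability(model: ProbabilityModel, score) -> np.ndarray | float:
    """Evaluate P(URB | S) on the fitted logistic curve."""
    s = np.asarray(score, dtype=float)
    p = 1.0 / (1.0 + np.exp(-(model.intercept + model.slope * s)))
    return float(p) if p.ndim == 0 else p


def select_markers(
    de_results: pd.DataFrame,
    matrix,
    annotations,
    top_k: int = 5,
) -> list[GeneMarker]:
    """Panel selection: significant DE genes ranked by AUC, top K.

    Falls back to ranking all tested genes when fewer than K are significant
    (small synthetic cohorts), so the panel is always populated.
    """
    by_id = {a.sample_id: a for a in annotations}
    tumor_ids = [s for s in matrix.sample_ids if s in by_id and by_id[s].subtype in ("URB", "DRB")]
    labels = np.array([by_id[s].subtype for s in tumor_ids])
    cols = [matrix.sample_ids.index(s) for s in tumor_ids]
    name_to_row = {p.name: i for i, p in enumerate(matrix.codeset.probes)}

    candidates = de_results[de_results["significant"]]["gene"].tolist()
    if len(candidates) < top_k:
        candidates = de_results["gene"].tolist()

    scored = []
    for gene in candidates:
        vals = np.log2(matrix.values[name_to_row[gene], cols] + 1.0)
        a = auc(vals, labels)
        scored.append((max(a, 1.0 - a), gene, vals))
    scored.sort(key=lambda t: (-t[0], t[1]))

    markers = []
    for _, gene, vals in scored[:top_k]:
        if np.ptp(vals) == 0.0:
            continue
        markers.append(make_marker(gene, vals, labels, tumor_ids))
    if not markers:
        raise ScoringError("no usable marker genes")
    return markers
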
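"""Two-group differential expression with normality-gated test choice.

Per gene, expression is log2(x+1)-transformed and each group is screened
with the Shapiro-Wilk test; both groups normal (p > 0.05) sends the gene to
the pooled-variance two-sided Student's t-test, anything else to the
Wilcoxon-Mann-Whitney rank-sum test (exact enumeration for tie-free pooled
n <= 12, otherwise the normal approximation with tie and continuity
corrections).  Raw p-values over the tested set are Benjamini-Hochberg
adjusted; significance is declared at q <= 0.05.  Fold changes are
log2((mean_URB + 1) / (mean_DRB + 1)) on the normalized counts.

Also hosts the supporting QC and structure-discovery steps: mean-variance
outlier flagging, sample correlation, PCA, and hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .normalization import NoiseCall
from .rcc import CountMatrix, SampleAnnotation

SIGNIFICANCE_ALPHA = 0.05
SHAPIRO_ALPHA = 0.05
EXACT_WILCOXON_MAX_N = 12


class CohortError(ValueError):
    """Raised when the sample layout cannot support the analysis."""


# ---------------------------------------------------------------------------
# per-gene testing
# ---------------------------------------------------------------------------

def choose_test(values_a: np.ndarray, values_b: np.ndarray) -> tuple[str, float, float]:
    """Pick student_t vs wilcoxon from per-group Shapiro-Wilk screens.

    Returns ``(test, shapiro_p_a, shapiro_p_b)``; a group below n=3 or with
    zero variance cannot be screened and forces the rank test (its Shapiro p
    is reported as NaN).
    """
    ps = []
    for values in (values_a, values_b):
        values = np.asarray(values, dtype=float)
        if values.size < 3 or np.ptp(values) == 0.0:
            ps.append(np.nan)
        else:
            ps.append(float(stats.shapiro(values).pvalue))
    pa, pb = ps
    if np.isnan(pa) or np.isnan(pb) or pa <= SHAPIRO_ALPHA or pb <= SHAPIRO_ALPHA:
        return "wilcoxon", pa, pb
    return "student_t", pa, pb


def _wilcoxon(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return float(a.size * b.size / 2.0), 1.0
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and pooled.size <= EXACT_WILCOXON_MAX_N:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def de_test(
    values_a: np.ndarray, values_b: np.ndarray, choice: str
) -> tuple[str, float, float]:
    """Run the chosen two-group test; returns (test_used, statistic, p).

    A parametric request on pooled-zero-variance data reroutes to the rank
    test, which has a defined answer for degenerate input.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if choice == "student_t":
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            stat, p = _wilcoxon(a, b)
            return "wilcoxon", stat, p
        res = stats.ttest_ind(a, b, equal_var=True)
        return "student_t", float(res.statistic), float(res.pvalue)
    if choice == "wilcoxon":
        stat, p = _wilcoxon(a, b)
        return "wilcoxon", stat, p
    raise ValueError(f"unknown test choice {choice!r}")


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """log2((mean_a + 1)/(mean_b + 1)); positive = higher in group A (URB)."""
    ma = float(np.mean(values_a))
    mb = float(np.mean(values_b))
    return float(np.log2((ma + 1.0) / (mb + 1.0)))


def run_de(
    matrix: CountMatrix,
    annotations: list[SampleAnnotation],
    noise_calls: list[NoiseCall],
) -> pd.DataFrame:
    """Per-gene URB vs DRB testing over above-noise endogenous genes.

    Controls are excluded; BH runs over exactly the tested set; the result
    frame is sorted by q then |log2_fc| (descending).
    """
    by_id = {a.sample_id: a for a in annotations}
    urb = [s for s in matrix.sample_ids if s in by_id and by_id[s].subtype == "URB"]
    drb = [s for s in matrix.sample_ids if s in by_id and by_id[s].subtype == "DRB"]
    if len(urb) < 2 or len(drb) < 2:
        raise CohortError(
            f"need >=2 samples per subtype, got URB={len(urb)}, DRB={len(drb)}"
        )
    cols_a = [matrix.sample_ids.index(s) for s in urb]
    cols_b = [matrix.sample_ids.index(s) for s in drb]

    above = {c.gene for c in noise_calls if c.above_noise}
    rows = []
    for i in matrix.rows_of_class("Endogenous"):
        gene = matrix.codeset.probes[i].name
        if gene not in above:
            continue
        raw_a = matrix.values[i, cols_a]
        raw_b = matrix.values[i, cols_b]
        la, lb = np.log2(raw_a + 1.0), np.log2(raw_b + 1.0)
        choice, sh_a, sh_b = choose_test(la, lb)
        used, statistic, p = de_test(la, lb, choice)
        rows.append(
            {
                "gene": gene,
                "test_used": used,
                "shapiro_p_a": sh_a,
                "shapiro_p_b": sh_b,
                "statistic": statistic,
                "p_raw": p,
                "log2_fc": log2_fold_change(raw_a, raw_b),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "gene", "test_used", "shapiro_p_a", "shapiro_p_b",
            "statistic", "p_raw", "log2_fc",
        ],
    )
    if len(result):
        result["q_fdr"] = bh_adjust(result["p_raw"].to_numpy())
    else:
        result["q_fdr"] = pd.Series(dtype=float)
    result["significant"] = result["q_fdr"] <= SIGNIFICANCE_ALPHA
    result = result.sort_values(
        by=["q_fdr", "log2_fc"],
        key=lambda s: s.abs() if s.name == "log2_fc" else s,
        ascending=[True, False],
    ).reset_index(drop=True)
    return result


# ---------------------------------------------------------------------------
# QC and structure discovery
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    gene_stats: pd.DataFrame          # log2 mean / log2 variance / residual
    outlier_genes: list[str]
    outlier_samples: list[str]
    correlation: pd.DataFrame
    correlation_method: str


def mean_variance_qc(matrix: CountMatrix, method: str = "pearson") -> QCReport:
    """Flag genes off the log-mean/log-variance trend and outlying lanes.

    Genes: least-squares line through (log2 mean+1, log2 var+1); residuals
    beyond 3x their median absolute deviation flag the gene.  Samples: lane
    totals beyond 3x MAD from the median total.
    """
    if matrix.values.shape[0] < 3 or matrix.values.shape[1] < 3:
        raise CohortError("mean-variance QC needs >=3 genes and >=3 samples")
    endo = matrix.rows_of_class("Endogenous")
    genes = [matrix.codeset.probes[i].name for i in endo]
    x = matrix.values[endo, :]
    log_mean = np.log2(x.mean(axis=1) + 1.0)
    log_var = np.log2(x.var(axis=1, ddof=1) + 1.0)

    if np.ptp(log_mean) == 0.0:
        resid = np.zeros_like(log_mean)
    else:
        # quadratic trend: overdispersed counts have var = mu + phi*mu^2,
        # which is curved on the log-log scale
        deg = 2 if np.unique(log_mean).size > 2 else 1
        coeffs = np.polyfit(log_mean, log_var, deg=deg)
        resid = log_var - np.polyval(coeffs, log_mean)
    # MAD scaled to a consistent sigma estimate (x1.4826), threshold 3 sigma
    mad = float(stats.median_abs_deviation(resid, scale="normal"))
    if mad == 0.0:
        gene_mask = np.zeros(len(genes), dtype=bool)
    else:
        gene_mask = np.abs(resid - np.median(resid)) > 3.0 * mad

    totals = np.log2(matrix.values[endo, :].sum(axis=0) + 1.0)
    tot_mad = float(stats.median_abs_deviation(totals, scale="normal"))
    if tot_mad == 0.0:
        sample_mask = np.zeros(len(matrix.sample_ids), dtype=bool)
    else:
        sample_mask = np.abs(totals - np.median(totals)) > 3.0 * tot_mad

    logged = pd.DataFrame(
        np.log2(x + 1.0), index=genes, columns=matrix.sample_ids
    )
    corr = logged.corr(method=method)

    return QCReport(
        gene_stats=pd.DataFrame(
            {"log2_mean": log_mean, "log2_var": log_var, "residual": resid},
            index=pd.Index(genes, name="gene"),
        ),
        outlier_genes=[g for g, m in zip(genes, gene_mask) if m],
        outlier_samples=[s for s, m in zip(matrix.sample_ids, sample_mask) if m],
        correlation=corr,
        correlation_method=method,
    )


def correlation_analysis(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> tuple[float, float]:
    """Pearson r (t-based p, df n-2) or Spearman rho (same formula on ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass
class PCAResult:
    scores: pd.DataFrame              # samples x components
    variance_fractions: np.ndarray


def pca(matrix: CountMatrix, log_transform: bool = True) -> PCAResult:
    """Sample-space PCA of (optionally log2) gene-centred expression via SVD."""
    if len(matrix.sample_ids) < 2:
        raise CohortError("PCA needs >=2 samples")
    endo = matrix.rows_of_class("Endogenous")
    data = matrix.values[endo, :].T  # samples x genes
    if log_transform:
        data = np.log2(data + 1.0)
    centered = data - data.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    fractions = (s**2 / total) if total > 0 else np.zeros_like(s)
    scores = u * s
    cols = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        variance_fractions=fractions,
    )


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    mode: str


def cluster(
    matrix: CountMatrix,
    mode: str = "unsupervised",
    annotations: list[SampleAnnotation] | None = None,
    method: str = "complete",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative sample clustering on log2(x+1) endogenous expression.

    Supervised mode clusters within each subtype and concatenates the leaf
    orders, so subtypes never interleave.
    """
    if len(matrix.sample_ids) < 2:
        raise CohortError("clustering needs >=2 samples")
    if method not in ("single", "complete", "average", "ward"):
        raise ValueError(f"unknown linkage {method!r}")
    endo = matrix.rows_of_class("Endogenous")
    data = np.log2(matrix.values[endo, :].T + 1.0)

    if mode == "unsupervised":
        link = linkage(pdist(data, metric=metric), method=method)
        order = [matrix.sample_ids[i] for i in leaves_list(link)]
        return ClusterResult(link, order, mode)
    if mode == "supervised":
        if annotations is None:
            raise CohortError("supervised clustering requires annotations")
        by_id = {a.sample_id: a.subtype for a in annotations}
        order: list[str] = []
        link = None
        for subtype in dict.fromkeys(by_id[s] for s in matrix.sample_ids if s in by_id):
            members = [s for s in matrix.sample_ids if by_id.get(s) == subtype]
            if len(members) == 1:
                order.extend(members)
                continue
            idx = [matrix.sample_ids.index(s) for s in members]
            sub_link = linkage(pdist(data[idx, :], metric=metric), method=method)
            order.extend(members[i] for i in leaves_list(sub_link))
            link = sub_link if link is None else link
        return ClusterResult(
            link if link is not None else np.empty((0, 4)), order, mode
        )
    raise ValueError(f"unknown mode {mode!r}")
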
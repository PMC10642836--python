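"""Clinical-covariate testing by tumor subtype (the cohort characteristics table).

Dichotomous covariates cross-tabulated against subtype go to Pearson's
chi-squared *without* continuity correction (the convention that reproduces
the published laterality p-value; Yates' correction does not).  The 2x2
germline-mutation table goes to the two-sided Fisher exact test with the
point-probability rule (sum of all tables, at fixed margins, whose
probability does not exceed the observed one).  Ordinal stages are coded
0/1/2 and compared across subtypes with the tie-corrected Kruskal-Wallis
test; age in months uses the Wilcoxon-Mann-Whitney engine shared with the
expression module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .de import _wilcoxon
from .rcc import C_STAGES, N_STAGES, SampleAnnotation


class TableError(ValueError):
    """Raised for contingency tables the requested test cannot handle."""


@dataclass
class ClinicalTestResult:
    characteristic: str
    test: str
    statistic: float
    p_value: float


def chisq_test(table: np.ndarray, characteristic: str = "") -> ClinicalTestResult:
    """Pearson chi-squared, no continuity correction, df=(r-1)(c-1)."""
    table = np.asarray(table)
    if table.ndim != 2 or min(table.shape) < 2:
        raise TableError("chi-squared needs at least a 2x2 table")
    if not np.issubdtype(table.dtype, np.integer) and not np.allclose(
        table, np.round(table)
    ):
        raise TableError("cell counts must be integers")
    if np.any(table < 0):
        raise TableError("cell counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise TableError("zero margin: chi-squared statistic undefined")
    res = stats.chi2_contingency(table, correction=False)
    return ClinicalTestResult(
        characteristic, "chi-square", float(res.statistic), float(res.pvalue)
    )


def fisher_exact(table: np.ndarray, characteristic: str = "") -> ClinicalTestResult:
    """Two-sided Fisher exact test on a 2x2 table (point-probability rule)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise TableError("Fisher's exact test needs a 2x2 table")
    if not np.allclose(table, np.round(table)):
        raise TableError("cell counts must be integers")
    res = stats.fisher_exact(table.astype(int), alternative="two-sided")
    return ClinicalTestResult(
        characteristic, "fisher-exact", float(res.statistic), float(res.pvalue)
    )


def kruskal_wallis(
    values: np.ndarray, groups: np.ndarray, characteristic: str = ""
) -> ClinicalTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared (k-1 df) p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise TableError("Kruskal-Wallis needs >=2 groups")
    samples = [values[groups == g] for g in labels]
    if any(s.size == 0 for s in samples):
        raise TableError("Kruskal-Wallis: empty group")
    if values.size < 3:
        raise TableError("Kruskal-Wallis needs total n >= 3")
    if np.ptp(values) == 0.0:
        # all observations tied: H = 0 by convention (scipy's tie correction
        # would divide by zero)
        return ClinicalTestResult(characteristic, "kruskal-wallis", 0.0, 1.0)
    res = stats.kruskal(*samples)
    return ClinicalTestResult(
        characteristic, "kruskal-wallis", float(res.statistic), float(res.pvalue)
    )


def mann_whitney(
    values_a: np.ndarray, values_b: np.ndarray, characteristic: str = ""
) -> ClinicalTestResult:
    """Wilcoxon-Mann-Whitney via the shared rank-sum engine."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise TableError("Mann-Whitney needs >=1 observation per group")
    statistic, p = _wilcoxon(a, b)
    return ClinicalTestResult(characteristic, "mann-whitney", statistic, p)


# ---------------------------------------------------------------------------
# cohort characteristics table assembly
# ---------------------------------------------------------------------------

AGE_BINS = ("<18", "18-36", ">36")


def age_category(age_months: float) -> str:
    if age_months < 18:
        return "<18"
    if age_months <= 36:
        return "18-36"
    return ">36"


def crosstab(
    annotations: list[SampleAnnotation], row_of, row_labels, subtypes=("URB", "DRB")
) -> np.ndarray:
    table = np.zeros((len(row_labels), len(subtypes)), dtype=int)
    for ann in annotations:
        if ann.subtype not in subtypes:
            continue
        table[row_labels.index(row_of(ann)), subtypes.index(ann.subtype)] += 1
    return table


def build_table1(annotations: list[SampleAnnotation]) -> list[ClinicalTestResult]:
    """Run the whole covariate battery on a cohort's annotations.

    Rows mirror the published layout: sex and laterality by chi-squared, age
    in months by Mann-Whitney, the age category and N/C stages by
    Kruskal-Wallis on ordinal codes, germline RB1 status by Fisher's exact
    test.  Control samples are excluded; order of input records is
    irrelevant.
    """
    tumors = [a for a in annotations if a.subtype in ("URB", "DRB")]
    present = {a.subtype for a in tumors}
    if present != {"URB", "DRB"}:
        raise TableError(f"need both URB and DRB samples, found {sorted(present)}")

    subtype = np.array([a.subtype for a in tumors])
    results = [
        chisq_test(
            crosstab(tumors, lambda a: a.sex, ["female", "male"]), "sex"
        ),
        chisq_test(
            crosstab(tumors, lambda a: a.laterality, ["unilateral", "bilateral"]),
            "laterality",
        ),
        mann_whitney(
            np.array([a.age_months for a in tumors if a.subtype == "URB"]),
            np.array([a.age_months for a in tumors if a.subtype == "DRB"]),
            "age_months",
        ),
        kruskal_wallis(
            np.array([AGE_BINS.index(age_category(a.age_months)) for a in tumors]),
            subtype,
            "age_category",
        ),
        kruskal_wallis(
            np.array([N_STAGES.index(a.n_stage) for a in tumors]), subtype, "n_stage"
        ),
        kruskal_wallis(
            np.array([C_STAGES.index(a.c_stage) for a in tumors]), subtype, "c_stage"
        ),
        fisher_exact(
            crosstab(tumors, lambda a: a.rb1_germline, [True, False]), "rb1_germline"
        ),
    ]
    return results
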
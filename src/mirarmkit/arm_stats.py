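"""Arm expression statistics: relative (2^-ddCt) and absolute (standard
curve) quantification, risk factor/score calls, arm-pair trend
classification across paired cohorts, and Kaplan-Meier / log-rank survival
stratification.

Relative quantification follows the comparative-Ct convention:
dCt = Ct(target) - Ct(reference) within a condition, ddCt = dCt(case) -
dCt(calibrator), and the expression ratio is 2^-ddCt. A ratio below 1.0 is
called low expression in the case relative to the calibrator; everything
else (including exactly 1.0) is high by default. One risk factor is
counted for 5p upregulation (ratio > 1) and one for 3p downregulation
(ratio < 1); the risk score is a linear combination of cohort-standardized
log arm expression, increasing in 5p and decreasing in 3p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

AVOGADRO = 6.02e23
MEAN_BASE_MW = 308.95  # g/mol per nucleotide residue


class InputError(ValueError):
    """Raised on malformed analysis inputs."""


# ---------------------------------------------------------------------------
# Relative quantification
# ---------------------------------------------------------------------------

def _summarize_ct(ct: pd.DataFrame, gene: str, condition: str) -> pd.Series:
    sub = ct[(ct["gene"] == gene) & (ct["condition"] == condition)]
    if sub.empty:
        raise InputError(f"no Ct values for gene {gene!r} in condition {condition!r}")
    if ((sub["ct"] <= 0) | (sub["ct"] >= 50)).any():
        raise InputError("Ct values must lie in (0, 50)")
    # replicates are summarized by median (robust to outlier wells)
    return sub.groupby("sample")["ct"].median()


def ddct_relative_expression(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    case_condition: str = "tumor",
    calibrator_condition: str = "normal",
    low_threshold: float = 1.0,
) -> pd.DataFrame:
    """Comparative-Ct relative expression of ``target_gene``.

    ``ct`` is a long table with columns ``sample, gene, condition, ct``
    (replicate rows allowed; they are median-summarized per sample before
    differencing).

    Returns one row per sample with ``delta_ct_case, delta_ct_calibrator,
    delta_delta_ct, ratio, call`` where ratio = 2^-ddCt and call is
    ``low`` iff ratio < ``low_threshold`` (exactly the threshold is high).
    """
    required = {"sample", "gene", "condition", "ct"}
    if not required.issubset(ct.columns):
        raise InputError(f"Ct table must have columns {sorted(required)}")
    if reference_gene not in set(ct["gene"]):
        raise InputError(f"reference gene {reference_gene!r} not measured")

    t_case = _summarize_ct(ct, target_gene, case_condition)
    r_case = _summarize_ct(ct, reference_gene, case_condition)
    t_cal = _summarize_ct(ct, target_gene, calibrator_condition)
    r_cal = _summarize_ct(ct, reference_gene, calibrator_condition)

    samples = t_case.index.intersection(r_case.index).intersection(
        t_cal.index.intersection(r_cal.index)
    )
    if len(samples) == 0:
        raise InputError("no sample has all four Ct measurements")
    d_case = t_case[samples] - r_case[samples]
    d_cal = t_cal[samples] - r_cal[samples]
    ddct = d_case - d_cal
    ratio = np.power(2.0, -ddct)
    return pd.DataFrame(
        {
            "sample": samples,
            "gene": target_gene,
            "delta_ct_case": d_case.values,
            "delta_ct_calibrator": d_cal.values,
            "delta_delta_ct": ddct.values,
            "ratio": ratio.values,
            "call": np.where(ratio.values < low_threshold, "low", "high"),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Risk factors and risk score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskProfile:
    patient_id: str
    rf_count: int
    risk_score: float
    group: str


def call_risk_profile(
    rel_5p: pd.DataFrame,
    rel_3p: pd.DataFrame,
    weights: Tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Per-patient risk factors and risk score from the two arm ratios.

    ``rel_5p``/``rel_3p`` are outputs of :func:`ddct_relative_expression`
    (columns ``sample`` and ``ratio``). One risk factor is counted when the
    5p ratio is > 1 (upregulated) and one when the 3p ratio is < 1
    (downregulated); exactly 1.0 contributes neither. The risk score is
    ``w5 * z(log2 ratio_5p) - w3 * z(log2 ratio_3p)`` with cohort
    z-standardization, so it rises with 5p and falls with 3p expression.
    """
    a = rel_5p.set_index("sample")["ratio"]
    b = rel_3p.set_index("sample")["ratio"]
    patients = a.index.intersection(b.index)
    if len(patients) < len(a.index.union(b.index)):
        raise InputError("every patient must have both arms measured")
    r5, r3 = a[patients].to_numpy(float), b[patients].to_numpy(float)
    rf = (r5 > 1.0).astype(int) + (r3 < 1.0).astype(int)
    w5, w3 = weights
    score = w5 * _zscore(np.log2(r5)) - w3 * _zscore(np.log2(r3))
    return pd.DataFrame(
        {
            "patient_id": patients,
            "rf_count": rf,
            "risk_score": score,
            "group": [f"RF{c}" for c in rf],
        }
    ).reset_index(drop=True)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def cox_risk_weights(
    expr_5p: Sequence[float],
    expr_3p: Sequence[float],
    survival: pd.DataFrame,
) -> Tuple[float, float]:
    """Estimate risk-score weights (w5, w3) from a proportional-hazards fit
    of survival on the two standardized log arm expressions.

    Returned so that ``w5 * z5 - w3 * z3`` has a positive log-hazard slope
    for the fitted model (w3 is the negated 3p coefficient).
    """
    from lifelines import CoxPHFitter

    df = pd.DataFrame(
        {
            "z5": _zscore(np.log2(np.asarray(expr_5p, float))),
            "z3": _zscore(np.log2(np.asarray(expr_3p, float))),
            "time": survival["time"].to_numpy(float),
            "event": survival["event"].to_numpy(bool),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(cph.params_["z5"]), float(-cph.params_["z3"])


# ---------------------------------------------------------------------------
# Arm-pair trend classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeRule:
    """Dysregulation rule for one arm: a paired Wilcoxon signed-rank gate at
    ``alpha`` combined with a minimum median tumor/normal fold change."""

    alpha: float = 0.05
    min_fold: float = 2.0


def classify_arm_direction(
    tumor: Sequence[float], normal: Sequence[float], rule: DeRule = DeRule()
) -> str:
    """``up``/``down``/``unchanged`` call for one arm from paired samples."""
    t = np.asarray(tumor, float)
    n = np.asarray(normal, float)
    if t.shape != n.shape:
        raise InputError("tumor and normal vectors must be paired (equal length)")
    if len(t) < 3:
        raise InputError("need at least 3 sample pairs")
    logr = np.log2(t) - np.log2(n)
    med = np.median(logr)
    if abs(med) < np.log2(rule.min_fold):
        return "unchanged"
    if np.allclose(logr, 0):
        return "unchanged"
    p = stats.wilcoxon(logr, alternative="two-sided").pvalue
    if p >= rule.alpha:
        return "unchanged"
    return "up" if med > 0 else "down"


def classify_arm_trend(
    tumor_5p: Sequence[float],
    normal_5p: Sequence[float],
    tumor_3p: Sequence[float],
    normal_3p: Sequence[float],
    rule: DeRule = DeRule(),
) -> Dict[str, str]:
    """Trend of one arm pair across a paired cohort.

    ``same`` = both arms move in the same direction, ``opposite`` = the two
    arms move in opposite directions, ``single`` = only one arm moves,
    ``none`` = neither does.
    """
    d5 = classify_arm_direction(tumor_5p, normal_5p, rule)
    d3 = classify_arm_direction(tumor_3p, normal_3p, rule)
    if d5 == "unchanged" and d3 == "unchanged":
        trend = "none"
    elif d5 == "unchanged" or d3 == "unchanged":
        trend = "single"
    elif d5 == d3:
        trend = "same"
    else:
        trend = "opposite"
    return {"direction_5p": d5, "direction_3p": d3, "trend": trend}


def classify_cohort_trends(cohort: pd.DataFrame, rule: DeRule = DeRule()) -> pd.DataFrame:
    """Apply :func:`classify_arm_trend` to every pair of a tidy cohort table
    (columns ``pair_id, arm, patient_id, normal, tumor``)."""
    rows = []
    for pair_id, sub in cohort.groupby("pair_id", sort=True):
        p5 = sub[sub["arm"] == "5p"].sort_values("patient_id")
        p3 = sub[sub["arm"] == "3p"].sort_values("patient_id")
        res = classify_arm_trend(
            p5["tumor"].values, p5["normal"].values, p3["tumor"].values, p3["normal"].values, rule
        )
        rows.append({"pair_id": pair_id, **res})
    return pd.DataFrame(rows)


def arm_trend_summary(trends: Iterable[str]) -> pd.DataFrame:
    """Counts and proportions per trend class; proportions sum to 1."""
    labels = list(trends)
    if not labels:
        raise InputError("no arm pairs supplied")
    counts = pd.Series(labels).value_counts()
    out = pd.DataFrame({"count": counts})
    out["proportion"] = out["count"] / out["count"].sum()
    out.index.name = "trend"
    return out.sort_index()


# ---------------------------------------------------------------------------
# Absolute quantification
# ---------------------------------------------------------------------------

def copy_number_from_mass(amount_g: float, length_bp: float, strandedness: str = "double") -> float:
    """Template copies from nucleic-acid mass.

    copies = 6.02e23 * amount(g) / (length(bp or nt) * 308.95(g/mol) * 2)
    for double-stranded molecules; single-stranded input drops the
    factor 2.
    """
    if length_bp <= 0:
        raise InputError("length must be > 0")
    if amount_g < 0:
        raise InputError("amount must be >= 0")
    if strandedness not in ("single", "double"):
        raise InputError("strandedness must be 'single' or 'double'")
    strands = 2.0 if strandedness == "double" else 1.0
    return AVOGADRO * amount_g / (length_bp * MEAN_BASE_MW * strands)


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of Ct on log10(copies) from a dilution series."""

    slope: float  # cycles per log10(copies); negative for valid curves
    intercept: float  # Ct at 1 copy
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 10^(-1/slope) - 1 (1.0 means
        perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(copies: Sequence[float], ct: Sequence[float]) -> StandardCurve:
    """Fit a qPCR standard curve from a dilution series of (copies, Ct)."""
    x = np.log10(np.asarray(copies, float))
    y = np.asarray(ct, float)
    if len(x) < 3 or len(np.unique(x)) < 3:
        raise InputError("need >= 3 distinct dilution points")
    if x.max() - x.min() < 2.0:
        raise InputError("dilution series must span >= 2 log10")
    res = stats.linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2))


def absolute_quantify(ct: float, curve: StandardCurve) -> float:
    """Invert a standard curve: copies = 10^((Ct - intercept)/slope)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


# ---------------------------------------------------------------------------
# Survival stratification
# ---------------------------------------------------------------------------

def km_logrank(
    survival: pd.DataFrame, group_col: str = "group"
) -> Tuple[Dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group plus the (multivariate) log-rank test.

    ``survival`` needs columns ``time, event`` and ``group_col``. Returns
    ``(curves, statistic, p_value)`` where each curve is a step-function
    table with columns ``time, survival`` starting at S(0)=1.
    """
    groups = survival[group_col].unique()
    if len(groups) < 2:
        raise InputError("need >= 2 groups")
    if not survival["event"].any():
        raise InputError("need >= 1 observed event overall")
    curves: Dict[str, pd.DataFrame] = {}
    for g in groups:
        sub = survival[survival[group_col] == g]
        if len(sub) == 0:
            raise InputError(f"group {g!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
        )
    res = multivariate_logrank_test(
        survival["time"], survival[group_col], survival["event"]
    )
    return curves, float(res.test_statistic), float(res.p_value)


def median_split_groups(scores: Mapping[str, float]) -> Dict[str, str]:
    """Label patients ``high``/``low`` by the median of their risk scores
    (ties go to the high group)."""
    vals = np.array(list(scores.values()), float)
    med = np.median(vals)
    return {p: ("high" if s >= med else "low") for p, s in scores.items()}
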
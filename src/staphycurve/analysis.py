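"""Group comparisons and correlations over a cohort with computed metrics.

Continuous variables are compared across the three groups with classical
one-way ANOVA; categorical variables with Pearson's chi-square (no
continuity correction, no exact test — small expected counts are only
warned about).  Post-hoc pairwise comparisons use Student's two-sample
t-test with Bonferroni adjustment (raw p times the number of pairs,
capped at 1); a Welch switch is provided.  Associations between curvature
parameters and severity variables use Pearson correlation with the
two-sided t-based p-value (a Spearman switch is provided).

Refractive-error rows exclude pseudophakic eyes; foveoschisis-height
correlations are restricted to the MTM group and CNV-size correlations to
the mCNV group.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Cohort, Group
from .errors import ValidationError

#: Continuous per-eye variables compared across groups, in table order.
CONTINUOUS_VARIABLES = [
    "age_years", "bcva_logmar", "axial_length_mm", "refractive_error_d",
    "sct_um",
    "h_nasal", "h_temporal", "h_superior", "h_inferior",
    "h_horizontal", "h_vertical", "h_total",
    "coef_a_horizontal", "coef_a_vertical", "coef_a_average",
    "ci_horizontal", "ci_vertical", "ci_average",
]
CATEGORICAL_VARIABLES = ["sex", "staphyloma_type", "metapm_category"]
CURVATURE_PARAMETERS = ["h_total", "coef_a_average", "ci_average"]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class PairwiseT:
    t: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class Correlation:
    r: float
    p: float
    n: int


def one_way_anova(groups: dict[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA over labelled groups.

    Zero within-group variance with distinct group means is reported as a
    degenerate result with infinite F and p = 0 rather than an error.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValidationError("ANOVA needs >= 2 groups with >= 2 values each")
    n = sum(len(a) for a in arrays)
    k = len(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if all(np.ptp(a) == 0 for a in arrays):  # constant within every group
        means = [a.mean() for a in arrays]
        if np.ptp(means) == 0:
            return AnovaResult(np.nan, k - 1, n - k, np.nan, degenerate=True)
        return AnovaResult(np.inf, k - 1, n - k, 0.0, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    return AnovaResult(float(f), k - 1, n - k, float(p))


def bonferroni_pairwise_t(
    groups: dict[str, Sequence[float]], equal_var: bool = True
) -> dict[tuple[str, str], PairwiseT]:
    """Pairwise two-sample t-tests with Bonferroni adjustment.

    The adjusted p is the raw p multiplied by the number of pairs, capped
    at 1.  ``equal_var=False`` switches to Welch's t.
    """
    labels = list(groups.keys())
    pairs = list(itertools.combinations(labels, 2))
    out: dict[tuple[str, str], PairwiseT] = {}
    for a, b in pairs:
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValidationError("each group needs >= 2 values")
        t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        out[(a, b)] = PairwiseT(
            t=float(t), p_raw=float(p), p_adjusted=min(1.0, float(p) * len(pairs))
        )
    return out


def chi_square_test(table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if np.any(arr < 0):
        raise ValidationError("counts must be nonnegative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError("contingency table has an all-zero row or column")
    res = stats.chi2_contingency(arr, correction=False)
    if np.any(res.expected_freq < 5):
        warnings.warn(
            "chi-square expected count below 5; asymptotic p may be inaccurate",
            stacklevel=2,
        )
    return ChiSquareResult(statistic=float(res.statistic), df=int(res.dof),
                           p=float(res.pvalue))


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> Correlation:
    """Correlation with two-sided p.  ``method`` may be 'spearman'."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("correlation needs >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("correlation inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return Correlation(r=float(r), p=float(p), n=len(x))


@dataclass
class ComparisonReport:
    """Tables-1/2/3-style comparison of a cohort.

    ``continuous`` maps variable -> {group -> (mean, sd, n)} plus the ANOVA;
    ``posthoc`` maps variable -> pairwise Bonferroni results; ``categorical``
    maps variable -> (contingency DataFrame, chi-square); ``correlations``
    maps (group, curvature parameter, covariate) -> Correlation;
    ``inter_metric`` maps (parameter, parameter) -> Correlation pooled over
    all groups.
    """

    continuous: dict[str, dict] = field(default_factory=dict)
    posthoc: dict[str, dict[tuple[str, str], PairwiseT]] = field(default_factory=dict)
    categorical: dict[str, dict] = field(default_factory=dict)
    correlations: dict[tuple[str, str, str], Correlation] = field(default_factory=dict)
    inter_metric: dict[tuple[str, str], Correlation] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def corr(c: Correlation) -> dict:
            return {"r": c.r, "p": c.p, "n": c.n}

        return {
            "continuous": {
                var: {
                    "groups": {
                        g: {"mean": m, "sd": s, "n": n}
                        for g, (m, s, n) in row["groups"].items()
                    },
                    "anova": None if row["anova"] is None else vars(row["anova"]),
                }
                for var, row in self.continuous.items()
            },
            "posthoc": {
                var: {f"{a}|{b}": vars(res) for (a, b), res in pairs.items()}
                for var, pairs in self.posthoc.items()
            },
            "categorical": {
                var: {
                    "table": row["table"].to_dict(),
                    "chi_square": None
                    if row["chi_square"] is None
                    else vars(row["chi_square"]),
                }
                for var, row in self.categorical.items()
            },
            "correlations": {
                "|".join(key): corr(c) for key, c in self.correlations.items()
            },
            "inter_metric": {
                "|".join(key): corr(c) for key, c in self.inter_metric.items()
            },
        }


def cohort_frame(cohort: Cohort, metrics: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Flatten a cohort (plus optional external metrics table) to a DataFrame.

    ``metrics``, when given, must be indexed by (patient_id, eye) or carry
    those columns; it overrides metrics carried on the records.
    """
    rows = []
    for rec in cohort.records:
        row = {
            "patient_id": rec.patient_id,
            "eye": rec.eye.value,
            "group": rec.group.value,
            "age_years": rec.age_years,
            "sex": rec.sex.value,
            "bcva_logmar": rec.bcva_logmar,
            "axial_length_mm": rec.axial_length_mm,
            "refractive_error_d": rec.refractive_error_d,
            "pseudophakic": rec.pseudophakic,
            "staphyloma_type": rec.staphyloma_type.value,
            "metapm_category": rec.metapm_category,
            "sct_um": rec.sct_um,
            "fsh_um": rec.fsh_um,
            "cnv_size_da": rec.cnv_size_da,
        }
        if rec.metrics is not None:
            row.update(rec.metrics.as_dict())
        rows.append(row)
    frame = pd.DataFrame(rows)
    if metrics is not None:
        m = metrics.reset_index() if metrics.index.names != [None] else metrics.copy()
        frame = frame.drop(
            columns=[c for c in m.columns if c not in ("patient_id", "eye")
                     and c in frame.columns],
            errors="ignore",
        ).merge(m, on=["patient_id", "eye"], how="left")
    return frame


def build_report(
    cohort: Cohort,
    metrics: Optional[pd.DataFrame] = None,
    equal_var: bool = True,
    correlation_method: str = "pearson",
) -> ComparisonReport:
    """Assemble the full group-comparison and correlation report.

    Pseudophakic eyes are excluded from refractive-error rows and
    refractive-error correlations; FSH correlations use MTM eyes only and
    CNV-size correlations mCNV eyes only.  Zero-variance ANOVA rows are
    flagged degenerate instead of raising.
    """
    frame = cohort_frame(cohort, metrics)
    required = {"group"} | set(CURVATURE_PARAMETERS)
    missing = sorted(required - set(frame.columns))
    if missing:
        raise ValidationError(f"cohort is missing required columns: {missing}")
    report = ComparisonReport()
    group_labels = [g.value for g in Group if (frame["group"] == g.value).any()]

    for var in CONTINUOUS_VARIABLES:
        if var not in frame.columns:
            continue
        sub = frame
        if var == "refractive_error_d":
            sub = frame[~frame["pseudophakic"].astype(bool)]
        values = {
            g: sub.loc[sub["group"] == g, var].dropna().to_numpy()
            for g in group_labels
        }
        values = {g: v for g, v in values.items() if len(v) > 0}
        summary = {
            g: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                int(len(v)))
            for g, v in values.items()
        }
        anova = None
        if len(values) >= 2 and all(len(v) >= 2 for v in values.values()):
            anova = one_way_anova(values)
            if not anova.degenerate:
                report.posthoc[var] = bonferroni_pairwise_t(values, equal_var)
        report.continuous[var] = {"groups": summary, "anova": anova}

    for var in CATEGORICAL_VARIABLES:
        if var not in frame.columns:
            continue
        table = pd.crosstab(frame["group"], frame[var]).reindex(group_labels)
        chi = None
        trimmed = table.loc[:, table.sum(axis=0) > 0].dropna(how="all")
        if trimmed.shape[0] >= 2 and trimmed.shape[1] >= 2:
            chi = chi_square_test(trimmed.to_numpy())
        report.categorical[var] = {"table": table, "chi_square": chi}

    severity_map = [
        ("axial_length_mm", None),
        ("refractive_error_d", None),
        ("fsh_um", Group.MTM.value),
        ("cnv_size_da", Group.MCNV.value),
    ]
    for g in group_labels:
        gframe = frame[frame["group"] == g]
        for covariate, only_group in severity_map:
            if only_group is not None and g != only_group:
                continue
            sub = gframe
            if covariate == "refractive_error_d":
                sub = gframe[~gframe["pseudophakic"].astype(bool)]
            for param in CURVATURE_PARAMETERS:
                pair = sub[[param, covariate]].dropna()
                if len(pair) < 3:
                    continue
                try:
                    corr = pearson_correlation(
                        pair[param], pair[covariate], method=correlation_method
                    )
                except ValidationError:
                    continue
                report.correlations[(g, param, covariate)] = corr

    for pa, pb in itertools.combinations(CURVATURE_PARAMETERS, 2):
        pair = frame[[pa, pb]].dropna()
        if len(pair) >= 3:
            try:
                report.inter_metric[(pa, pb)] = pearson_correlation(
                    pair[pa], pair[pb], method=correlation_method
                )
            except ValidationError:
                pass
    return report


def plot_correlation_triptych(cohort: Cohort, path, metrics=None) -> None:
    """Scatterplots of the three pairwise curvature-parameter correlations."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = cohort_frame(cohort, metrics)
    pairs = list(itertools.combinations(CURVATURE_PARAMETERS, 2))
    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 4))
    for ax, (pa, pb) in zip(np.atleast_1d(axes), pairs):
        for g, sub in frame.groupby("group"):
            ax.scatter(sub[pa], sub[pb], s=12, label=g, alpha=0.7)
        ax.set_xlabel(pa)
        ax.set_ylabel(pb)
    np.atleast_1d(axes)[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
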
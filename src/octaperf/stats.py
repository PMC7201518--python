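"""Longitudinal statistics for paired perfusion metrics.

Reproduces the statistical surface of a paired pre/post OCTA study:

- per-metric paired comparison, with the test chosen by normality of
  the paired differences (Shapiro-Wilk at alpha = 0.05: paired t-test
  if normal, Wilcoxon signed-rank otherwise);
- Pearson/Spearman correlations between quantitative variables;
- prediction of metric *change* from baseline covariates: a univariate
  Spearman screen per predictor followed by a multivariable ordinary
  least squares fit (no stepwise selection; complete cases only).

Eyes are treated as independent units by default — the convention of
the study design this mirrors, where both eyes of some patients enter
the cohort — with an optional cluster-robust covariance by patient.
p-values are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

RETINOPATHY_GRADES = ("mild NPDR", "moderate NPDR", "severe NPDR", "PDR")

#: perfusion metric columns recognized by the report builder
METRIC_COLUMNS = ("vd_percent", "skeleton_vd_percent", "fd", "faz_area_mm2")


@dataclass
class ClinicalRecord:
    """Baseline clinical covariates for one eye."""

    eye_id: str
    logmar_cdva: float = np.nan
    cmt_um: float = np.nan
    pft_um: float = np.nan
    iop_mmhg: float = np.nan
    hba1c_percent: float = np.nan
    dm_type: int = 2
    dm_duration_yr: float = np.nan
    hypertension: bool = False
    retinopathy_grade: str = "moderate NPDR"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.cmt_um) and self.cmt_um < 275:
            raise ValueError(
                "baseline CMT below the 275 um inclusion threshold for"
                " center-involving macular edema"
            )
        if self.retinopathy_grade not in RETINOPATHY_GRADES:
            raise ValueError(f"unknown retinopathy grade {self.retinopathy_grade!r}")

    @property
    def retinopathy_rank(self) -> int:
        return RETINOPATHY_GRADES.index(self.retinopathy_grade)


@dataclass
class PairedResult:
    """Summary of one paired pre/post comparison (one table row)."""

    metric: str
    n_pairs: int
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    change_mean: float
    change_sd: float
    percent_change: float
    test: str  # 'paired t-test' | 'wilcoxon signed rank' | 'degenerate'
    p_value: float
    normal_differences: bool
    degenerate: bool = False


class CohortTable:
    """Tidy cohort container: one row per (eye_id, timepoint) holding
    perfusion metrics, joined with per-eye baseline clinical covariates.

    ``df`` must contain columns ``eye_id`` and ``timepoint`` ('pre' /
    'post'); each eye may appear at most once per timepoint. Paired
    analyses use complete pairs only.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"eye_id", "timepoint"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        dup = df.duplicated(subset=["eye_id", "timepoint"])
        if dup.any():
            raise ValueError("each eye may appear at most once per timepoint")
        bad = set(df["timepoint"]) - {"pre", "post"}
        if bad:
            raise ValueError(f"unknown timepoints {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_metrics(cls, metrics, clinical=None) -> "CohortTable":
        """Build from PerfusionMetrics objects plus optional
        ClinicalRecord objects (joined on eye_id)."""
        rows = [vars(m).copy() for m in metrics]
        df = pd.DataFrame(rows)
        if clinical:
            cdf = pd.DataFrame([vars(c).copy() for c in clinical])
            cdf["retinopathy_rank"] = [c.retinopathy_rank for c in clinical]
            df = df.merge(cdf, on="eye_id", how="left")
        return cls(df)

    @classmethod
    def from_csv(cls, metrics_csv, clinical_csv=None) -> "CohortTable":
        df = pd.read_csv(metrics_csv)
        if clinical_csv is not None:
            cdf = pd.read_csv(clinical_csv)
            if "retinopathy_grade" in cdf.columns and "retinopathy_rank" not in cdf.columns:
                cdf["retinopathy_rank"] = [
                    RETINOPATHY_GRADES.index(g) for g in cdf["retinopathy_grade"]
                ]
            df = df.merge(cdf, on="eye_id", how="left")
        return cls(df)

    def paired(self, column: str) -> pd.DataFrame:
        """Complete pre/post pairs of one metric column, indexed by eye."""
        wide = self.df.pivot(index="eye_id", columns="timepoint", values=column)
        if "pre" not in wide.columns or "post" not in wide.columns:
            raise ValueError(f"no complete pre/post pairs for {column!r}")
        return wide.dropna(subset=["pre", "post"])

    def baseline(self) -> pd.DataFrame:
        """Pre-treatment rows, indexed by eye."""
        return self.df[self.df["timepoint"] == "pre"].set_index("eye_id")


def paired_compare(
    pre, post, normality_alpha: float = 0.05, metric: str = ""
) -> PairedResult:
    """Compare paired measurements, selecting the test by normality.

    Shapiro-Wilk is run on the paired differences; if its p-value
    exceeds ``normality_alpha`` the differences are treated as normal
    and a paired t-test is used, otherwise the Wilcoxon signed-rank
    test. Constant differences make both tests degenerate: the result
    is flagged, with p = 1 for identically zero differences and the
    exact sign-test probability otherwise.
    """
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    n = len(pre)
    if n < 5:
        raise ValueError("paired comparison requires >= 5 complete pairs")
    diff = post - pre

    summary = dict(
        metric=metric,
        n_pairs=n,
        pre_mean=float(pre.mean()),
        pre_sd=float(pre.std(ddof=1)),
        post_mean=float(post.mean()),
        post_sd=float(post.std(ddof=1)),
        change_mean=float(diff.mean()),
        change_sd=float(diff.std(ddof=1)),
        percent_change=float(100.0 * diff.mean() / pre.mean())
        if pre.mean() != 0
        else np.nan,
    )

    if np.ptp(diff) == 0.0:  # constant differences: both tests degenerate
        if diff[0] == 0.0:
            p = 1.0
        else:  # exact two-sided sign-test probability, all signs equal
            p = min(1.0, 2.0 * 0.5**n)
        return PairedResult(
            **summary,
            test="degenerate",
            p_value=float(p),
            normal_differences=False,
            degenerate=True,
        )

    sw_p = float(sps.shapiro(diff).pvalue)
    normal = sw_p > normality_alpha
    if normal:
        test = "paired t-test"
        p = float(sps.ttest_rel(post, pre).pvalue)
    else:
        test = "wilcoxon signed rank"
        p = float(sps.wilcoxon(post, pre).pvalue)
    return PairedResult(
        **summary, test=test, p_value=p, normal_differences=normal
    )


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p (Pearson or Spearman)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 5:
        raise ValueError("correlation requires n >= 5")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


@dataclass
class RegressionReport:
    """Univariate screen plus multivariable OLS for one change outcome."""

    outcome: str
    univariate: pd.DataFrame  # predictor, spearman_r, p
    coefficients: pd.DataFrame  # predictor, coef, se, t, p
    r_squared: float
    n_obs: int
    condition_number: float
    collinear: bool
    model: object = field(repr=False, default=None)


def change_predictors(
    cohort: CohortTable,
    metric: str,
    predictors,
    *,
    condition_limit: float = 1e6,
    cluster_by: str | None = None,
) -> RegressionReport:
    """Predict the pre-to-post change in ``metric`` from baseline data.

    Runs a univariate Spearman screen of each baseline predictor
    against the change, then a multivariable OLS of change on all
    predictors jointly (complete cases). A design condition number
    above ``condition_limit`` flags collinearity. ``cluster_by`` selects
    cluster-robust (patient-level) covariance; default off, treating
    both eyes of a patient as independent.
    """
    pairs = cohort.paired(metric)
    change = (pairs["post"] - pairs["pre"]).rename("change")
    base = cohort.baseline()
    missing = [p for p in predictors if p not in base.columns]
    if missing:
        raise ValueError(f"unknown predictor columns {missing}")
    data = base[list(predictors)].join(change, how="inner")
    if cluster_by is not None:
        data = data.join(base[[cluster_by]], how="left", rsuffix="_cl")
    data = data.dropna()
    n = len(data)
    if n < 5 * max(len(list(predictors)), 1):
        raise ValueError(
            f"{n} complete cases insufficient for {len(list(predictors))} predictors"
        )

    uni_rows = []
    for p in predictors:
        x = data[p].to_numpy(dtype=np.float64)
        if np.ptp(x) == 0:
            uni_rows.append({"predictor": p, "spearman_r": np.nan, "p": np.nan})
            continue
        r, pv = correlate(x, data["change"].to_numpy(), method="spearman")
        uni_rows.append({"predictor": p, "spearman_r": r, "p": pv})
    univariate = pd.DataFrame(uni_rows)

    X = sm.add_constant(data[list(predictors)].astype(np.float64))
    model = sm.OLS(data["change"].astype(np.float64), X)
    if cluster_by is not None:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": data[cluster_by]})
    else:
        fit = model.fit()
    coefficients = pd.DataFrame(
        {
            "predictor": X.columns,
            "coef": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    cond = float(np.linalg.cond(X.to_numpy()))
    return RegressionReport(
        outcome=metric,
        univariate=univariate,
        coefficients=coefficients,
        r_squared=float(fit.rsquared),
        n_obs=n,
        condition_number=cond,
        collinear=cond > condition_limit,
        model=fit,
    )


def build_report(
    cohort: CohortTable,
    metrics=None,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired summary table: one row per metric with pre/post mean+-SD,
    change, percent change, the test used, and its p-value.

    ``metrics`` defaults to every recognized perfusion metric column
    present in the cohort with at least five complete pairs.
    """
    if metrics is None:
        metrics = [c for c in METRIC_COLUMNS if c in cohort.df.columns]
    rows = []
    for m in metrics:
        pairs = cohort.paired(m)
        if len(pairs) < 5:
            continue
        res = paired_compare(
            pairs["pre"].to_numpy(),
            pairs["post"].to_numpy(),
            normality_alpha=normality_alpha,
            metric=m,
        )
        rows.append(vars(res))
    report = pd.DataFrame(rows)
    return report


def format_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`build_report` output."""
    lines = []
    for _, r in report.iterrows():
        lines.append(
            f"{r['metric']:>22s}  pre {r['pre_mean']:7.3f} ± {r['pre_sd']:6.3f}"
            f"  post {r['post_mean']:7.3f} ± {r['post_sd']:6.3f}"
            f"  change {r['change_mean']:+7.3f} ± {r['change_sd']:6.3f}"
            f"  ({r['percent_change']:+5.1f}%)"
            f"  {r['test']}, p = {r['p_value']:.4g}"
        )
    return "\n".join(lines)
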
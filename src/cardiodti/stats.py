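"""Cohort statistics: normality, group comparison, regression and ROC.

Conventions follow the common small-animal imaging reporting style: values
as mean ± SEM, Shapiro–Wilk normality screening, two-tailed pooled-variance
(Student's) t-tests, ordinary least-squares regression with t-based 95%
confidence bands, and empirical ROC curves with the Mann–Whitney AUC,
DeLong confidence intervals, Youden-index optimal cutoffs and Wilson score
intervals on sensitivity/specificity.

Per-segment comparisons are reported without multiplicity adjustment, the
asterisk convention of the exploratory bull's-eye analyses this mirrors;
Benjamini–Hochberg adjusted values are emitted alongside so a reader can
apply the stricter criterion, and the report carries a prominent note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint


class SampleSizeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# elementary tests


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro–Wilk W statistic and p-value (3 ≤ n ≤ 5000).

    A constant sample has no defined W; a ``ValueError`` is raised (the
    normality question is meaningless at zero variance).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise SampleSizeError(f"Shapiro–Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def unpaired_t(group_a, group_b) -> tuple[float, int, float]:
    """Two-tailed unpaired Student's t-test (pooled variance).

    Returns (t, df, p) with df = n_a + n_b − 2.  Degenerate zero-variance
    cases are resolved deterministically: equal means give t=0, p=1; unequal
    means give infinite t, p=0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SampleSizeError("need n >= 2 per group")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test (available behind a flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    res = sps.ttest_ind(a, b, equal_var=False)
    df = res.df if hasattr(res, "df") else np.nan
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_ci: tuple[float, float]
    intercept_se: float
    slope_se: float
    n: int
    confidence: float

    def prediction_band(self, x_new) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pointwise confidence band for the mean prediction at x_new."""
        x_new = np.asarray(x_new, dtype=float)
        yhat = self.intercept + self.slope * x_new
        tcrit = sps.t.ppf(0.5 + self.confidence / 2.0, self.n - 2)
        se = np.sqrt(
            self._sigma2 * (1.0 / self.n + (x_new - self._xbar) ** 2 / self._sxx)
        )
        return yhat, yhat - tcrit * se, yhat + tcrit * se

    # filled in by the fitting routine
    _sigma2: float = field(default=np.nan, repr=False)
    _xbar: float = field(default=np.nan, repr=False)
    _sxx: float = field(default=np.nan, repr=False)


def linear_regression_ci(x, y, confidence: float = 0.95) -> RegressionResult:
    """OLS simple linear regression with t-based slope CI and mean band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise SampleSizeError("need n >= 3 for regression")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant x: singular design")
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    sigma2 = sse / (n - 2)
    slope_se = float(np.sqrt(sigma2 / sxx))
    intercept_se = float(np.sqrt(sigma2 * (1.0 / n + xbar**2 / sxx)))
    if slope_se == 0:
        p = 0.0 if slope != 0 else 1.0
        tcrit = 0.0
    else:
        tstat = slope / slope_se
        p = float(2.0 * sps.t.sf(abs(tstat), n - 2))
        tcrit = sps.t.ppf(0.5 + confidence / 2.0, n - 2)
    res = RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        p_value=p,
        slope_ci=(float(slope - tcrit * slope_se), float(slope + tcrit * slope_se)),
        intercept_se=intercept_se,
        slope_se=slope_se,
        n=int(n),
        confidence=float(confidence),
    )
    res._sigma2 = float(sigma2)
    res._xbar = float(xbar)
    res._sxx = float(sxx)
    return res


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCResult:
    auc: float
    auc_ci: tuple[float, float]
    p_value: float
    cutoff: float | None
    sensitivity: float | None
    specificity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None
    direction: str
    n_disease: int
    n_control: int

    def as_dict(self) -> dict:
        return asdict(self)


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the pairwise probability of correct ranking, ties counted 1/2."""
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via placement values."""
    psi = np.where(
        pos[:, None] > neg[None, :], 1.0, np.where(pos[:, None] == neg[None, :], 0.5, 0.0)
    )
    v10 = psi.mean(axis=1)  # per-disease placement
    v01 = psi.mean(axis=0)  # per-control placement
    m, n = len(pos), len(neg)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_analysis(
    scores_disease,
    scores_control,
    positive_direction: str = "higher",
) -> ROCResult:
    """Empirical ROC analysis of a continuous biomarker.

    AUC is the Mann–Whitney pairwise-ranking probability (ties ½); its 95%
    CI and the two-sided p-value for AUC = 0.5 come from the DeLong
    variance.  The optimal cutoff maximizes the Youden index
    J = sensitivity + specificity − 1, breaking ties toward higher
    sensitivity (then the less extreme threshold); sensitivity/specificity
    at the cutoff carry Wilson 95% score intervals.  With
    ``positive_direction="higher"``, scores at or above the cutoff are
    called diseased; with ``"lower"``, scores at or below.
    """
    if positive_direction not in ("higher", "lower"):
        raise ValueError("positive_direction must be 'higher' or 'lower'")
    pos = np.asarray(scores_disease, dtype=float)
    neg = np.asarray(scores_control, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise SampleSizeError("need >= 2 subjects per group")
    sign = 1.0 if positive_direction == "higher" else -1.0
    p_al = sign * pos
    n_al = sign * neg

    auc = _auc_mann_whitney(p_al, n_al)
    var = _delong_variance(p_al, n_al)
    se = np.sqrt(var)
    if se > 0:
        z = (auc - 0.5) / se
        p_value = float(2.0 * sps.norm.sf(abs(z)))
        ci = (max(0.0, auc - 1.959963984540054 * se), min(1.0, auc + 1.959963984540054 * se))
    else:
        # degenerate placements (e.g. complete separation): the asymptotic
        # variance collapses; report the point value with a degenerate CI
        p_value = 1.0 if auc == 0.5 else 0.0
        ci = (auc, auc)

    if np.ptp(np.concatenate([p_al, n_al])) == 0:
        return ROCResult(
            auc=0.5,
            auc_ci=(0.5, 0.5),
            p_value=1.0,
            cutoff=None,
            sensitivity=None,
            specificity=None,
            sensitivity_ci=None,
            specificity_ci=None,
            direction=positive_direction,
            n_disease=pos.size,
            n_control=neg.size,
        )

    thresholds = np.unique(np.concatenate([p_al, n_al]))
    best = None
    for t in thresholds:
        sens = float(np.mean(p_al >= t))
        spec = float(np.mean(n_al < t))
        j = sens + spec - 1.0
        key = (j, sens, -t)  # Youden, then sensitivity, then lower threshold
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t_star, sens, spec = best
    sens_ci = proportion_confint(round(sens * pos.size), pos.size, method="wilson")
    spec_ci = proportion_confint(round(spec * neg.size), neg.size, method="wilson")
    return ROCResult(
        auc=auc,
        auc_ci=(float(ci[0]), float(ci[1])),
        p_value=p_value,
        cutoff=float(sign * t_star),
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
        direction=positive_direction,
        n_disease=pos.size,
        n_control=neg.size,
    )


# ---------------------------------------------------------------------------
# cohort model / results


DEFAULT_ROC_DIRECTIONS = {
    "fa": "higher",
    "c_planar": "higher",
    "c_spherical": "lower",
    "c_linear": "higher",
    "md": "higher",
    "abs_e2a": "lower",
    "lv_mass_index": "lower",
}


class CohortModel:
    """Two-group cohort analysis over per-subject imaging metrics.

    Parameters
    ----------
    metrics : DataFrame
        One row per subject; must contain ``group_col`` plus numeric metric
        columns (global and/or region-prefixed, e.g. ``fa``,
        ``fa_inferior``).
    group_col, control_label, disease_label : str
        Group assignment; every other column is treated as a metric.

    ``fit()`` runs normality screening, Student's t-tests, configured
    regressions and ROC analyses, and returns a :class:`CohortResults`.
    """

    def __init__(
        self,
        metrics: pd.DataFrame,
        group_col: str = "group",
        control_label: str = "control",
        disease_label: str = "disease",
    ):
        if group_col not in metrics.columns:
            raise ValueError(f"missing group column {group_col!r}")
        self.metrics = metrics.copy()
        self.group_col = group_col
        self.control_label = control_label
        self.disease_label = disease_label
        counts = metrics[group_col].value_counts()
        for label in (control_label, disease_label):
            if counts.get(label, 0) < 2:
                raise SampleSizeError(f"need >= 2 subjects in group {label!r}")

    @property
    def metric_columns(self) -> list[str]:
        return [
            c
            for c in self.metrics.columns
            if c != self.group_col and pd.api.types.is_numeric_dtype(self.metrics[c])
        ]

    def _split(self, column: str):
        g = self.metrics[[self.group_col, column]].dropna()
        ctrl = g.loc[g[self.group_col] == self.control_label, column].to_numpy(float)
        dis = g.loc[g[self.group_col] == self.disease_label, column].to_numpy(float)
        return dis, ctrl

    def fit(
        self,
        roc_metrics: tuple = ("fa", "c_planar", "c_spherical"),
        roc_directions: dict | None = None,
        regressions: tuple = (("lv_mass_index", "c_planar"),),
        welch: bool = False,
    ) -> "CohortResults":
        directions = dict(DEFAULT_ROC_DIRECTIONS)
        if roc_directions:
            directions.update(roc_directions)

        rows = []
        excluded = []
        for col in self.metric_columns:
            dis, ctrl = self._split(col)
            n_missing = len(self.metrics) - len(dis) - len(ctrl)
            if n_missing:
                excluded.append({"metric": col, "n_missing": int(n_missing)})
            if len(dis) < 2 or len(ctrl) < 2:
                continue
            test = welch_t if welch else unpaired_t
            t, df, p = test(ctrl, dis)
            row = {
                "metric": col,
                "mean_control": float(ctrl.mean()),
                "sem_control": float(ctrl.std(ddof=1) / np.sqrt(len(ctrl))),
                "mean_disease": float(dis.mean()),
                "sem_disease": float(dis.std(ddof=1) / np.sqrt(len(dis))),
                "n_control": len(ctrl),
                "n_disease": len(dis),
                "t": t,
                "df": df,
                "p_value": p,
            }
            for tag, arr in (("control", ctrl), ("disease", dis)):
                try:
                    w, pw = shapiro_wilk(arr)
                except ValueError:
                    w, pw = np.nan, np.nan
                row[f"shapiro_w_{tag}"] = w
                row[f"shapiro_p_{tag}"] = pw
            rows.append(row)
        group_table = pd.DataFrame(rows)
        if len(group_table):
            finite = group_table["p_value"].notna()
            adj = np.full(len(group_table), np.nan)
            if finite.any():
                adj[finite.to_numpy()] = multipletests(
                    group_table.loc[finite, "p_value"], method="fdr_bh"
                )[1]
            group_table["p_value_bh"] = adj
            group_table["significant_unadjusted"] = group_table["p_value"] < 0.05

        reg_results = {}
        for xcol, ycol in regressions:
            if xcol not in self.metrics.columns or ycol not in self.metrics.columns:
                continue
            sub = self.metrics[[xcol, ycol]].dropna()
            if len(sub) >= 3 and np.ptp(sub[xcol].to_numpy()) > 0:
                reg_results[f"{ycol}_vs_{xcol}"] = linear_regression_ci(
                    sub[xcol].to_numpy(float), sub[ycol].to_numpy(float)
                )

        roc_results = {}
        for col in roc_metrics:
            if col not in self.metrics.columns:
                continue
            dis, ctrl = self._split(col)
            if len(dis) >= 2 and len(ctrl) >= 2:
                base = col.rsplit("_", 1)[0] if col not in directions else col
                direction = directions.get(col, directions.get(base, "higher"))
                roc_results[col] = roc_analysis(dis, ctrl, positive_direction=direction)

        return CohortResults(
            model=self,
            group_table=group_table,
            regressions=reg_results,
            roc=roc_results,
            excluded=excluded,
        )


@dataclass
class CohortResults:
    """Fitted cohort comparison: group tests, regressions and ROC curves."""

    model: CohortModel
    group_table: pd.DataFrame
    regressions: dict[str, RegressionResult]
    roc: dict[str, ROCResult]
    excluded: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Cohort analysis (mean ± SEM; two-tailed unpaired Student's t-test)",
            "NOTE: per-segment/per-metric p-values are NOT adjusted for multiple",
            "comparisons; Benjamini–Hochberg values are in column p_value_bh.",
            "",
        ]
        for _, r in self.group_table.iterrows():
            star = "*" if r["p_value"] < 0.05 else " "
            lines.append(
                f"{r['metric']:<28s} control {r['mean_control']:.4g} ± {r['sem_control']:.2g}"
                f"  disease {r['mean_disease']:.4g} ± {r['sem_disease']:.2g}"
                f"  t={r['t']:+.3f} p={r['p_value']:.4f}{star}"
            )
        if self.regressions:
            lines.append("")
            for name, reg in self.regressions.items():
                lines.append(
                    f"regression {name}: slope={reg.slope:.4g} "
                    f"[{reg.slope_ci[0]:.4g}, {reg.slope_ci[1]:.4g}], "
                    f"r²={reg.r_squared:.3f}, p={reg.p_value:.4f}"
                )
        if self.roc:
            lines.append("")
            for name, r in self.roc.items():
                lines.append(
                    f"ROC {name:<22s} AUC={r.auc:.3f} "
                    f"({r.auc_ci[0]:.2f}–{r.auc_ci[1]:.2f}) p={r.p_value:.4f} "
                    f"cutoff={r.cutoff if r.cutoff is None else round(r.cutoff, 4)} "
                    f"sens={r.sensitivity} spec={r.specificity}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def _reg(reg: RegressionResult) -> dict:
            d = asdict(reg)
            for k in ("_sigma2", "_xbar", "_sxx"):
                d.pop(k, None)
            d["slope_ci"] = list(d["slope_ci"])
            return d

        def _roc(r: ROCResult) -> dict:
            d = r.as_dict()
            for k in ("auc_ci", "sensitivity_ci", "specificity_ci"):
                if d[k] is not None:
                    d[k] = list(d[k])
            return d

        return {
            "note": "p-values unadjusted for multiplicity; see p_value_bh",
            "group_table": self.group_table.to_dict(orient="records"),
            "regressions": {k: _reg(v) for k, v in self.regressions.items()},
            "roc": {k: _roc(v) for k, v in self.roc.items()},
            "excluded": self.excluded,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @staticmethod
    def read_json(path) -> dict:
        with open(path) as fh:
            return json.load(fh)


def build_cohort_report(
    manifest: pd.DataFrame,
    metrics: pd.DataFrame,
    roc_metrics: tuple = ("fa", "c_planar", "c_spherical", "fa_inferior", "fa_septal"),
    regressions: tuple = (("lv_mass_index", "c_planar"),),
    subject_col: str = "subject_id",
) -> CohortResults:
    """Join a cohort manifest with per-subject metrics and run the analysis."""
    merged = manifest.merge(metrics, on=subject_col, how="inner")
    model = CohortModel(merged.drop(columns=[subject_col]))
    return model.fit(roc_metrics=roc_metrics, regressions=regressions)
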
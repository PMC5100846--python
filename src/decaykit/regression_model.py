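"""Multiple-regression model building for mRNA degradation rates.

The degradation rate constant is modeled as a linear function of
transformed transcript properties. Model building follows two routes that
should agree: (1) screen predictors by univariate significance, include
all with p < alpha, then backward-eliminate the least significant until
every term is significant; (2) add predictors in order of ascending
univariate p, resolving conflicts between a new term and a term it
renders insignificant by retained variance explained. A greedy AIC
reduction is available as a cross-check. Categorical structure (GO SLIM
function, RNA-binding-protein targets) enters as binary indicators on top
of the continuous model ("model++"), and one-way ANOVA quantifies the
variance a single categorical labeling explains.

AIC follows the statsmodels Gaussian-likelihood convention,
n*ln(2*pi*RSS/n) + n + 2(k+1); only differences between nested models on
the same rows are meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .predictor_table import PredictorTable

__all__ = [
    "FittedModel",
    "ScreenResult",
    "CategoricalAnnotation",
    "OutlierReport",
    "VarianceSummary",
    "fit_ols",
    "univariate_screen",
    "backward_stepwise",
    "forward_stepwise",
    "aic_reduce",
    "categorical_anova",
    "annotation_indicators",
    "model_plus_plus",
    "nested_f_test",
    "rank_sum_compare",
    "residual_outliers",
    "variance_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class FittedModel:
    """An ordinary-least-squares fit of rate constants on predictor terms."""

    terms: tuple[str, ...]
    coefficients: pd.Series  # includes "const"
    std_errors: pd.Series
    p_values: pd.Series
    r_squared: float
    adj_r_squared: float
    aic: float
    n_used: int
    residuals: pd.Series  # indexed by gene, complete-case rows only
    fitted: pd.Series
    selection_log: list = field(default_factory=list)

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals.to_numpy() ** 2))

    @property
    def df_resid(self) -> int:
        return self.n_used - len(self.terms) - 1

    def term_p_values(self) -> pd.Series:
        return self.p_values.drop("const")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Two-sided (1 - alpha) t-intervals for all coefficients."""
        crit = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {
                "low": self.coefficients - crit * self.std_errors,
                "high": self.coefficients + crit * self.std_errors,
            }
        )


@dataclass(frozen=True)
class ScreenResult:
    """Univariate association of one predictor with the rate constant."""

    predictor: str
    r_squared: float
    p_value: float
    sign: str  # "+" or "-"


@dataclass(frozen=True)
class CategoricalAnnotation:
    """Per-gene categorical labels: GO SLIM terms and RBP target sets."""

    gene_id: str
    go_slim_terms: frozenset = frozenset()
    rbp_targets: frozenset = frozenset()


def _complete_cases(table: PredictorTable, terms: Sequence[str]) -> pd.DataFrame:
    missing = [t for t in terms if t not in table.data.columns]
    if missing:
        raise KeyError(f"unknown predictors: {missing}")
    frame = table.data[list(terms)].copy()
    frame["k_deg"] = table.response
    return frame.dropna()


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank >= mat.shape[1]:
        return
    # identify offenders: columns nearly perfectly explained by the rest
    cols = [c for c in X.columns if c != "const"]
    offenders = []
    for c in cols:
        others = [o for o in X.columns if o != c]
        beta, *_ = np.linalg.lstsq(X[others].to_numpy(), X[c].to_numpy(), rcond=None)
        resid = X[c].to_numpy() - X[others].to_numpy() @ beta
        denom = np.var(X[c].to_numpy())
        if denom == 0 or np.sum(resid**2) / (len(resid) * denom) < 1e-10:
            offenders.append(c)
    raise ValueError(f"rank-deficient design; collinear terms: {offenders or cols}")


def fit_ols(table: PredictorTable, terms: Sequence[str]) -> FittedModel:
    """OLS of the rate constant on the given predictor terms.

    Rows are the complete cases over the chosen terms and the response.
    Per-term p-values are two-sided t-tests on the coefficients.
    """
    terms = list(dict.fromkeys(terms))
    if len(terms) < 1:
        raise ValueError("at least one term is required")
    frame = _complete_cases(table, terms)
    if len(frame) < len(terms) + 2:
        raise ValueError(
            f"insufficient complete-case rows ({len(frame)}) for {len(terms)} terms"
        )
    X = sm.add_constant(frame[terms], has_constant="add")
    _check_rank(X)
    res = sm.OLS(frame["k_deg"], X).fit()
    return FittedModel(
        terms=tuple(terms),
        coefficients=res.params,
        std_errors=res.bse,
        p_values=res.pvalues,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        aic=float(res.aic),
        n_used=int(res.nobs),
        residuals=pd.Series(res.resid, index=frame.index),
        fitted=pd.Series(res.fittedvalues, index=frame.index),
    )


def univariate_screen(table: PredictorTable) -> list[ScreenResult]:
    """Single-predictor fits for every column, sorted by ascending p.

    Ties are broken by predictor name so the ordering (and everything
    downstream of it) is deterministic. Columns whose fit fails are
    logged and skipped rather than aborting the screen.
    """
    results = []
    for name in table.predictors:
        try:
            model = fit_ols(table, [name])
        except (ValueError, KeyError) as exc:
            logger.warning("screen: skipping %s (%s)", name, exc)
            continue
        coef = model.coefficients[name]
        results.append(
            ScreenResult(
                predictor=name,
                r_squared=model.r_squared,
                p_value=float(model.p_values[name]),
                sign="+" if coef >= 0 else "-",
            )
        )
    results.sort(key=lambda r: (r.p_value, r.predictor))
    return results


def _screened_candidates(table: PredictorTable, alpha: float) -> list[ScreenResult]:
    screen = univariate_screen(table)
    passed = [r for r in screen if r.p_value < alpha]
    if not passed:
        raise ValueError("no predictors pass screening")
    return passed


def backward_stepwise(
    table: PredictorTable,
    alpha: float = 0.05,
    candidates: Sequence[str] | None = None,
) -> FittedModel:
    """Backward elimination from the univariately-significant predictors.

    Starting from all predictors with univariate p < alpha, refit and
    remove the single term with the highest p while any term has
    p >= alpha (ties broken alphabetically). The final model retains only
    significant terms; the removal order is recorded in selection_log.
    """
    if candidates is None:
        candidates = [r.predictor for r in _screened_candidates(table, alpha)]
    terms = sorted(candidates)
    if not terms:
        raise ValueError("no predictors pass screening")
    log: list[dict] = []
    while True:
        model = fit_ols(table, terms)
        pvals = model.term_p_values()
        worst_p = pvals.max()
        if worst_p < alpha:
            break
        offenders = sorted(pvals[pvals == worst_p].index)
        drop = offenders[0]
        log.append({"action": "remove", "term": drop, "p_value": float(worst_p)})
        terms = [t for t in terms if t != drop]
        if not terms:
            raise ValueError("all candidates eliminated; no significant model")
    model.selection_log = log
    return model


def forward_stepwise(
    table: PredictorTable,
    alpha: float = 0.05,
    candidates: Sequence[ScreenResult] | None = None,
) -> FittedModel:
    """Forward selection in order of ascending univariate p.

    Each candidate (only those univariately significant at alpha) is added
    in turn. If the new term is itself insignificant in the joint fit it
    is removed again. If it displaces an existing term (renders it
    insignificant), the models with either term are compared and the one
    explaining more variance is retained. The decision log records every
    add/reject/swap.
    """
    if candidates is None:
        candidates = _screened_candidates(table, alpha)
    if not candidates:
        raise ValueError("no predictors pass screening")
    log: list[dict] = []
    terms: list[str] = []
    for cand in candidates:
        name = cand.predictor
        if name in terms:
            continue
        trial_terms = terms + [name]
        trial = fit_ols(table, trial_terms)
        pvals = trial.term_p_values()
        if pvals[name] >= alpha:
            log.append({"action": "reject", "term": name, "p_value": float(pvals[name])})
            continue
        displaced = sorted(t for t in terms if pvals[t] >= alpha)
        while displaced:
            # compare: keep the new term (drop the worst displaced term)
            # vs keep the displaced term (no new term)
            old = displaced[0]
            with_new = fit_ols(table, [t for t in trial_terms if t != old])
            with_old = fit_ols(table, terms)
            if with_new.r_squared >= with_old.r_squared:
                log.append(
                    {"action": "swap", "added": name, "removed": old,
                     "r2_with_new": with_new.r_squared, "r2_with_old": with_old.r_squared}
                )
                trial_terms = [t for t in trial_terms if t != old]
                trial = with_new
                pvals = trial.term_p_values()
                displaced = sorted(t for t in trial_terms if t != name and pvals[t] >= alpha)
            else:
                log.append(
                    {"action": "keep_existing", "rejected": name, "kept": old,
                     "r2_with_new": with_new.r_squared, "r2_with_old": with_old.r_squared}
                )
                trial_terms = None
                break
        if trial_terms is None:
            continue
        if trial.term_p_values()[name] >= alpha:
            log.append({"action": "reject", "term": name})
            continue
        log.append({"action": "add", "term": name})
        terms = trial_terms
    if not terms:
        raise ValueError("forward selection retained no terms")
    model = fit_ols(table, terms)
    model.selection_log = log
    return model


def aic_reduce(table: PredictorTable, start_terms: Sequence[str]) -> FittedModel:
    """Greedy backward elimination minimizing AIC.

    Repeatedly drop the single term whose removal lowers AIC the most;
    stop when no removal improves AIC. Final AIC <= starting AIC.
    """
    terms = list(dict.fromkeys(start_terms))
    model = fit_ols(table, terms)
    log: list[dict] = []
    while len(terms) > 1:
        best_drop, best_model = None, None
        for t in sorted(terms):
            trial = fit_ols(table, [x for x in terms if x != t])
            if trial.aic < model.aic and (best_model is None or trial.aic < best_model.aic):
                best_drop, best_model = t, trial
        if best_drop is None:
            break
        log.append({"action": "remove", "term": best_drop, "aic": best_model.aic})
        terms = [x for x in terms if x != best_drop]
        model = best_model
    model.selection_log = log
    return model


def categorical_anova(
    response: pd.Series, labels: pd.Series
) -> tuple[float, float]:
    """One-way ANOVA of the rate constant on a single categorical labeling.

    Returns (R^2, p) where R^2 = between-group SS / total SS and p is the
    F-test p-value. Requires >= 2 categories with >= 2 members among the
    jointly non-missing genes.
    """
    frame = pd.DataFrame({"y": response, "g": labels}).dropna()
    counts = frame["g"].value_counts()
    counts = counts[counts >= 2]
    if len(counts) < 2:
        raise ValueError("need at least 2 categories with at least 2 members")
    frame = frame[frame["g"].isin(counts.index)]
    y = frame["y"].to_numpy()
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    if ss_total == 0:
        raise ValueError("response has zero variance")
    groups = [g["y"].to_numpy() for _, g in frame.groupby("g", observed=True)]
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    k, n = len(groups), len(y)
    r2 = ss_between / ss_total
    ss_within = ss_total - ss_between
    if ss_within <= 0:
        return r2, 0.0
    f_stat = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(stats.f.sf(f_stat, k - 1, n - k))
    return r2, p


def annotation_indicators(
    annotations: Iterable[CategoricalAnnotation],
    genes: Sequence[str],
    min_prevalence: int = 10,
) -> pd.DataFrame:
    """Binary indicator columns (go:<term>, rbp:<name>) over the gene list.

    Categories with fewer than ``min_prevalence`` member genes among
    ``genes`` are dropped to keep the design's degrees of freedom in
    check. Genes without annotations get 0 everywhere (absence of a label
    is informative, not missing).
    """
    by_gene = {a.gene_id: a for a in annotations}
    columns: dict[str, np.ndarray] = {}
    all_go = sorted({t for a in by_gene.values() for t in a.go_slim_terms})
    all_rbp = sorted({t for a in by_gene.values() for t in a.rbp_targets})
    for prefix, labels, getter in (
        ("go", all_go, lambda a: a.go_slim_terms),
        ("rbp", all_rbp, lambda a: a.rbp_targets),
    ):
        for label in labels:
            vec = np.array(
                [1.0 if (g in by_gene and label in getter(by_gene[g])) else 0.0 for g in genes]
            )
            if vec.sum() >= min_prevalence:
                columns[f"{prefix}:{label}"] = vec
    return pd.DataFrame(columns, index=pd.Index(genes))


def model_plus_plus(
    table: PredictorTable,
    reduced: FittedModel,
    annotations: Iterable[CategoricalAnnotation],
    min_prevalence: int = 10,
) -> FittedModel:
    """Refit the reduced continuous model with categorical indicators added.

    Adds one binary column per sufficiently prevalent GO SLIM term and RBP
    target on top of the reduced model's terms. Indicators are complete
    (0/1 for every gene), so the complete-case rows match the reduced
    model's and R^2 can only increase.
    """
    indicators = annotation_indicators(annotations, table.genes, min_prevalence)
    if indicators.shape[1] == 0:
        return replace(reduced, selection_log=list(reduced.selection_log))
    data = pd.concat([table.data, indicators], axis=1)
    augmented = PredictorTable(data, table.response, dict(table.transforms))
    return fit_ols(augmented, list(reduced.terms) + list(indicators.columns))


def nested_f_test(full: FittedModel, reduced: FittedModel) -> tuple[float, float]:
    """Partial F-test of a full model against a nested reduced model.

    Both fits must use the same rows. Returns (F, p). A reduced model with
    zero extra df relative to the full model returns (0, 1).
    """
    if full.n_used != reduced.n_used:
        raise ValueError("models were fitted on different row sets")
    df_diff = len(full.terms) - len(reduced.terms)
    if df_diff <= 0:
        return 0.0, 1.0
    num = (reduced.rss - full.rss) / df_diff
    den = full.rss / full.df_resid
    if den == 0:
        return float("inf"), 0.0
    f_stat = num / den
    return float(f_stat), float(stats.f.sf(f_stat, df_diff, full.df_resid))


def rank_sum_compare(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two rate distributions.

    Uses exact enumeration when both groups have n <= 10 and there are no
    ties across the pooled sample, otherwise the normal approximation with
    continuity and tie correction. Returns (U statistic, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class OutlierReport:
    """Genes whose residuals sit far above the mean residual."""

    genes: pd.Index
    fraction: float
    threshold: float
    summary: pd.DataFrame  # per-feature medians: outliers vs rest


def residual_outliers(
    model: FittedModel,
    table: PredictorTable,
    sd_threshold: float = 2.0,
) -> OutlierReport:
    """Flag genes with residual > mean + sd_threshold x SD (one-sided).

    These are transcripts degrading faster than the model predicts. The
    summary compares their per-feature medians against the remaining
    genes, for characterizing what the model misses.
    """
    resid = model.residuals
    sd = float(resid.std(ddof=1))
    # an exact fit leaves only float noise in the residuals; treat its
    # spread as zero relative to the scale of the measured response
    scale = float((model.fitted + resid).std(ddof=1))
    if sd == 0 or np.isnan(sd) or (scale > 0 and sd < 1e-10 * scale):
        threshold = float("inf")
        flagged = resid.index[[]]
    else:
        threshold = float(resid.mean() + sd_threshold * sd)
        flagged = resid.index[resid > threshold]
    rest = resid.index.difference(flagged)
    feats = table.data.loc[resid.index]
    summary = pd.DataFrame(
        {
            "outlier_median": feats.loc[flagged].median(),
            "rest_median": feats.loc[rest].median(),
        }
    )
    return OutlierReport(
        genes=flagged,
        fraction=len(flagged) / len(resid) if len(resid) else 0.0,
        threshold=threshold,
        summary=summary,
    )


@dataclass
class VarianceSummary:
    """Signed univariate R^2 per predictor plus full-model R^2 values."""

    table: pd.DataFrame
    scatter: pd.DataFrame  # measured vs modeled rate per gene


def variance_summary(
    screen: Sequence[ScreenResult],
    model: FittedModel,
    model_pp: FittedModel,
    response: pd.Series | None = None,
) -> VarianceSummary:
    """Combine screening and model fits into one variance-explained report.

    One row per screened predictor (R^2 signed by the direction of the
    univariate association), plus rows for the continuous model and for
    model++ (continuous + categorical). Scatter data pair each modeled
    rate with the measured one for the model++ rows.
    """
    rows = [
        {
            "term": r.predictor,
            "kind": "univariate",
            "r_squared": r.r_squared,
            "signed_r_squared": r.r_squared if r.sign == "+" else -r.r_squared,
            "p_value": r.p_value,
        }
        for r in screen
    ]
    for label, m in (("model", model), ("model++", model_pp)):
        rows.append(
            {
                "term": label,
                "kind": "model",
                "r_squared": m.r_squared,
                "signed_r_squared": m.r_squared,
                "p_value": float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    measured = (
        response.loc[model_pp.fitted.index]
        if response is not None
        else model_pp.fitted + model_pp.residuals
    )
    scatter = pd.DataFrame(
        {"measured": measured, "modeled": model_pp.fitted}, index=model_pp.fitted.index
    )
    return VarianceSummary(table=table, scatter=scatter)


def plot_variance_summary(summary: VarianceSummary, path) -> None:
    """Minimal two-panel figure: signed R^2 per term, modeled vs measured."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    table = summary.table.sort_values("signed_r_squared")
    colors = [
        "gray" if k == "model" else ("firebrick" if s >= 0 else "seagreen")
        for k, s in zip(table["kind"], table["signed_r_squared"])
    ]
    ax1.barh(table["term"], table["signed_r_squared"], color=colors)
    ax1.axvline(0, color="black", lw=0.8)
    ax1.set_xlabel("signed $R^2$ (direction of association)")
    ax2.scatter(summary.scatter["measured"], summary.scatter["modeled"], s=4, alpha=0.3)
    lims = [summary.scatter.min().min(), summary.scatter.max().max()]
    ax2.plot(lims, lims, color="gray", lw=0.8)
    ax2.set_xlabel("measured rate (min$^{-1}$)")
    ax2.set_ylabel("modeled rate (min$^{-1}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
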
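"""Expression-stratified survival analysis and nonparametric group tests.

Patient cohorts are split by a gene's expression — extreme deciles
(bottom 10% vs top 10%) or a median split — and compared with the
Kaplan-Meier product-limit estimator and the log-rank (Mantel-Cox) test.
Two-group expression comparisons use the Mann-Whitney test, multi-group
comparisons (e.g. across molecular subtypes) the Kruskal-Wallis test.
Kaplan-Meier and log-rank computations are delegated to ``lifelines``;
the stratification rules and the mutation-association sweep are defined
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .types import SurvivalTable, ValidationError

logger = logging.getLogger("channelscreen")


def stratify_quantile(
    values: pd.Series, lo: float = 0.10, hi: float = 0.90
) -> pd.Series:
    """Label the bottom and top expression quantiles; exclude the middle.

    low: value <= Q(lo); high: value >= Q(hi); everything else excluded.
    Quantiles use linear interpolation between order statistics.
    """
    if not (0 <= lo < hi <= 1):
        raise ValidationError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    if len(values) < 10:
        raise ValidationError("quantile stratification needs >= 10 samples")
    x = values.to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValidationError("all expression values identical: strata undefined")
    q_lo = float(np.quantile(x, lo))
    q_hi = float(np.quantile(x, hi))
    if q_lo >= q_hi:
        raise ValidationError(
            f"quantile cutoffs coincide (Q({lo})={q_lo}, Q({hi})={q_hi}); strata overlap"
        )
    labels = pd.Series("excluded", index=values.index, name="stratum")
    labels[values <= q_lo] = "low"
    labels[values >= q_hi] = "high"
    return labels


def stratify_median(values: pd.Series, median_value: float | None = None) -> pd.Series:
    """Median split: high strictly above the median, low at or below.

    An externally supplied median (e.g. one computed on a wider cohort)
    overrides the within-sample median.
    """
    if len(values) < 2:
        raise ValidationError("median stratification needs >= 2 samples")
    med = float(np.median(values.to_numpy(dtype=float))) if median_value is None else median_value
    labels = pd.Series("low", index=values.index, name="stratum")
    labels[values > med] = "high"
    return labels


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) after each distinct event time."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # number at risk at each event time
    events: np.ndarray         # deaths at each event time
    median: float | None       # first time S(t) <= 0.5, None if never reached

    def __post_init__(self) -> None:
        s = self.survival
        if s.size and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValidationError("survival curve must be non-increasing within [0, 1]")


def km_estimate(table: SurvivalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Samples censored exactly at an event time count as at risk for that
    time (the standard convention). With no events the curve is flat at 1
    and the median undefined.
    """
    if len(table) == 0:
        raise ValidationError("empty survival table")
    t = table.data["time"].to_numpy(dtype=float)
    e = table.data["event"].to_numpy(dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    et = kmf.event_table
    ev = et[et["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=int)
    events = ev["observed"].to_numpy(dtype=int)
    survival = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMCurve(times, survival, at_risk, events, median)


@dataclass(frozen=True)
class LogRankResult:
    """Two-group log-rank (Mantel-Cox) test: chi-square on 1 df."""

    chi2: float
    p_value: float

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValidationError("log-rank statistic must be non-negative")
        if not (0 < self.p_value <= 1):
            raise ValidationError("p-value must lie in (0, 1]")


def logrank_test(table: SurvivalTable, strata: pd.Series) -> LogRankResult:
    """Log-rank test between exactly two strata of a survival table.

    ``strata`` maps sample id to a group label; samples labelled
    ``excluded`` (or absent) are dropped first.
    """
    df = table.data.join(strata.rename("stratum_"), how="inner")
    df = df[df["stratum_"] != "excluded"]
    groups = sorted(df["stratum_"].dropna().unique())
    if len(groups) != 2:
        raise ValidationError(f"log-rank needs exactly 2 non-empty strata, got {groups}")
    a = df[df["stratum_"] == groups[0]]
    b = df[df["stratum_"] == groups[1]]
    for name, g in ((groups[0], a), (groups[1], b)):
        if g["event"].sum() == 0 and g["time"].sum() == 0:
            raise ValidationError(f"stratum {name!r} has no events and no follow-up")
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return LogRankResult(float(res.test_statistic), float(res.p_value))


def mann_whitney(
    x, y, alternative: str = "two-sided", use_continuity: bool = False
) -> tuple[float, float]:
    """Mann-Whitney U with rank-sum U and a method chosen by sample size.

    Exact p for min(n1, n2) <= 8 with no ties; otherwise the normal
    approximation with tie correction (no continuity correction by
    default, so the two-group case agrees with Kruskal-Wallis).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=use_continuity
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with chi-square(k-1) p-value."""
    if len(groups) < 2:
        raise ValidationError("kruskal_wallis needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        raise ValidationError("all observations identical: H undefined after tie correction")
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def mutation_association(
    expression: pd.DataFrame,
    mutation_flags: pd.DataFrame,
    min_mutant: int = 3,
) -> pd.DataFrame:
    """Mann-Whitney mutant-vs-wildtype expression tests per (gene, mutation).

    ``expression`` is gene x isolate; ``mutation_flags`` is isolate x
    mutated-gene with values ``mutant``/``wildtype`` (or booleans).
    Mutations carried by fewer than ``min_mutant`` isolates — or lacking
    any wildtype isolate — are skipped.
    """
    shared = [i for i in expression.columns if i in mutation_flags.index]
    if not shared:
        raise ValidationError("no isolates shared between expression and mutation tables")
    flags = mutation_flags.loc[shared]
    rows = []
    for mutation in flags.columns:
        col = flags[mutation]
        if col.dtype == object:
            is_mut = col == "mutant"
        else:
            is_mut = col.astype(bool)
        mutants = [i for i in shared if is_mut[i]]
        wildtypes = [i for i in shared if not is_mut[i]]
        if len(mutants) < min_mutant:
            logger.info(
                "mutation %r present in %d < %d isolates; skipped", mutation,
                len(mutants), min_mutant,
            )
            continue
        if not wildtypes:
            logger.info("mutation %r has no wildtype isolates; skipped", mutation)
            continue
        for gene in expression.index:
            u, p = mann_whitney(
                expression.loc[gene, mutants], expression.loc[gene, wildtypes]
            )
            rows.append(
                {"gene": gene, "mutation": mutation, "n_mutant": len(mutants),
                 "n_wildtype": len(wildtypes), "U": u, "p_value": p}
            )
    return pd.DataFrame(rows)
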
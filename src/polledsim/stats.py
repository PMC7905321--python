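"""Cross-replicate summaries, genetic trends and scenario contrasts.

Replicates are the experimental unit throughout: per-year metrics are
averaged over replicates with SEM and t-based 95% confidence intervals,
genetic trends are ordinary least-squares slopes of birth-cohort mean TBV
on birth year fitted per replicate and then averaged, and scenario
contrasts are all-pairs Tukey HSD tests on the replicate-level values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .genetics import hwe_genotype_frequencies

#: Yearly metrics worth summarising by default.
DEFAULT_METRICS = (
    "horned_allele_freq",
    "cohort_mean_tbv",
    "cohort_mean_f",
    "n_sires_used",
    "n_sires_hom_polled",
    "n_open_cows",
    "n_sold_beef",
)


def summarize(
    replicate_series: pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-year, per-sector mean, SEM and t-based CI over replicates.

    ``replicate_series`` is the tidy frame produced by ``run_scenario``
    (one row per replicate x year x sector).  Requires at least two
    replicates so the SEM is defined.
    """
    n_reps = replicate_series["replicate"].nunique()
    if n_reps < 2:
        raise ValueError("at least two replicates are required to summarise")
    rows = []
    grouped = replicate_series.groupby(["year", "sector"], sort=True)
    tcrit = sps.t.ppf(0.5 + ci_level / 2.0, df=n_reps - 1)
    for (year, sector), g in grouped:
        for metric in metrics:
            vals = g[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]  # years with no births carry NaN
            if vals.size == 0:
                mean = sem = float("nan")
            else:
                mean = float(vals.mean())
                sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            rows.append(
                {
                    "year": year,
                    "sector": sector,
                    "metric": metric,
                    "mean": mean,
                    "sem": sem,
                    "ci_low": mean - tcrit * sem,
                    "ci_high": mean + tcrit * sem,
                }
            )
    return pd.DataFrame(rows)


def genetic_trend(cohort_mean_tbv_by_year: pd.Series | np.ndarray, years=None) -> float:
    """OLS slope ($/year) of cohort mean TBV on birth year."""
    if isinstance(cohort_mean_tbv_by_year, pd.Series):
        y = cohort_mean_tbv_by_year.to_numpy(dtype=float)
        x = (
            np.asarray(years, dtype=float)
            if years is not None
            else cohort_mean_tbv_by_year.index.to_numpy(dtype=float)
        )
    else:
        y = np.asarray(cohort_mean_tbv_by_year, dtype=float)
        x = np.asarray(years, dtype=float) if years is not None else np.arange(y.size, dtype=float)
    ok = np.isfinite(y)  # years with no surviving births carry no cohort mean
    x, y = x[ok], y[ok]
    if y.size < 3:
        raise ValueError("at least three years are required for a trend")
    if np.ptp(x) == 0:
        raise ValueError("birth years are constant; the trend is undefined")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def genetic_trends(replicate_series: pd.DataFrame, sector: str) -> np.ndarray:
    """Per-replicate genetic-trend slopes for one sector."""
    out = []
    for _, g in replicate_series[replicate_series["sector"] == sector].groupby("replicate"):
        g = g.sort_values("year")
        out.append(genetic_trend(g["cohort_mean_tbv"].to_numpy(), g["year"].to_numpy()))
    return np.array(out)


def compare_scenarios(
    year20_values: dict[str, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    """All-pairs Tukey HSD on replicate-level values of one metric.

    ``year20_values`` maps scenario name to the per-replicate values of the
    metric (typically at the final year).  Returns one row per scenario
    pair with the mean difference, adjusted p-value and significance flag;
    an empty frame if fewer than two scenarios are given.
    """
    names = [k for k, v in year20_values.items() if len(v) > 0]
    if len(names) < 2:
        return pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"]
        )
    values = np.concatenate([np.asarray(year20_values[k], dtype=float) for k in names])
    labels = np.concatenate([np.full(len(year20_values[k]), k) for k in names])
    if np.unique(labels).size != len(names) or any(
        len(year20_values[k]) < 2 for k in names
    ):
        raise ValueError("each scenario needs at least two replicate values")
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )
    return frame


def project_genotype_frequencies(q_horned: float) -> dict[str, float]:
    """Hardy-Weinberg genotype shares implied by a final allele frequency."""
    f_pp, f_het, f_hom = hwe_genotype_frequencies(q_horned)
    return {"horned": f_pp, "het_polled": f_het, "hom_polled": f_hom}
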
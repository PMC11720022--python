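"""Median-split survival screening: KM curves, log-rank tests, BH-FDR.

For each gene, patients are split at the median of its expression (high =
strictly above the median; ties at the median join the low group), the
two groups' survival is estimated by the Kaplan-Meier product-limit
estimator, compared with the two-group log-rank (Mantel-Haenszel) test,
and p-values are Benjamini-Hochberg adjusted across the tested gene list
within one endpoint.  Median survival is the earliest time the KM
estimate drops to <= 0.5, reported as "not reached" (NaN in memory, "NR"
on disk) when the curve never does.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from statsmodels.stats.multitest import multipletests

from interactome.io import ValidationError, atomic_write

__all__ = [
    "KMEstimate",
    "fdr_adjust",
    "km_curve",
    "logrank_test",
    "median_split",
    "read_screen_results",
    "run_survival_screen",
    "write_screen_results",
]

logger = logging.getLogger(__name__)

ENDPOINTS = ("os", "dfs")


def median_split(values: pd.Series) -> tuple[list, list]:
    """Split samples at the median expression of one gene.

    High group: strictly above the median.  Low group: at or below
    (ties at the median go low).  Raises when either group would be empty
    (all values identical).
    """
    values = values.dropna()
    if len(values) < 4:
        raise ValidationError("median split needs >= 4 non-missing values")
    median = values.median()
    high = values.index[values > median].tolist()
    low = values.index[values <= median].tolist()
    if not high or not low:
        raise ValidationError(
            "degenerate median split: all values identical, one group empty"
        )
    return high, low


@dataclass
class KMEstimate:
    """Product-limit survival estimate: step function plus median."""

    survival: pd.Series  # S(t) at each distinct observed time, step function
    median: float  # months; NaN when the curve never reaches 0.5

    @property
    def median_reached(self) -> bool:
        return not math.isnan(self.median)


def km_curve(times: np.ndarray, events: np.ndarray) -> KMEstimate:
    """Kaplan-Meier estimate of S(t) with right censoring.

    ``events`` is boolean/0-1 (1 = event observed, 0 = censored).
    """
    times = np.asarray(times, float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValidationError("km_curve needs at least one record")
    if (times < 0).any() or not np.isfinite(times).all():
        raise ValidationError("negative or non-finite survival times")
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    surv = fitter.survival_function_.iloc[:, 0]
    surv.index.name = "time"
    median = fitter.median_survival_time_
    if math.isinf(median):
        median = float("nan")
    return KMEstimate(survival=surv, median=float(median))


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2 statistic on 1 df, p-value)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if times_a.size == 0 or times_b.size == 0:
        raise ValidationError("log-rank test needs both groups nonempty")
    if int(events_a.sum()) + int(events_b.sum()) == 0:
        raise ValidationError("log-rank test undefined with zero total events")
    result = _lifelines_logrank(
        times_a, times_b, event_observed_A=events_a, event_observed_B=events_b
    )
    return float(result.test_statistic), float(result.p_value)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_survival_screen(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    genes: list[str],
    endpoint: str = "os",
) -> pd.DataFrame:
    """Median-split KM/log-rank screen over a gene list for one endpoint.

    ``clinical`` is indexed by sample with columns ``{endpoint}_months``
    and ``{endpoint}_event``.  Genes absent from the expression matrix
    are skipped with a warning; FDR is adjusted across the genes actually
    tested.  Results keep the input gene order.
    """
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"endpoint must be one of {ENDPOINTS}")
    time_col, event_col = f"{endpoint}_months", f"{endpoint}_event"
    if time_col not in clinical.columns or event_col not in clinical.columns:
        raise ValidationError(f"clinical table lacks {time_col}/{event_col}")
    if not genes:
        return _empty_results()

    shared = [s for s in expr.columns if s in clinical.index]
    if not shared:
        raise ValidationError("no overlapping samples between expression and clinical")
    clin = clinical.loc[shared, [time_col, event_col]].dropna()

    rows = []
    for gene in genes:
        if gene not in expr.index:
            logger.warning("gene %s absent from expression matrix; skipped", gene)
            continue
        values = expr.loc[gene, clin.index].dropna()
        if len(values) < 4:
            logger.warning("gene %s: <4 usable samples; skipped", gene)
            continue
        try:
            high, low = median_split(values)
        except ValidationError as exc:
            logger.warning("gene %s: %s; skipped", gene, exc)
            continue
        t_hi = clin.loc[high, time_col].to_numpy()
        e_hi = clin.loc[high, event_col].to_numpy().astype(bool)
        t_lo = clin.loc[low, time_col].to_numpy()
        e_lo = clin.loc[low, event_col].to_numpy().astype(bool)
        km_hi, km_lo = km_curve(t_hi, e_hi), km_curve(t_lo, e_lo)
        chi2, p_raw = logrank_test(t_hi, e_hi, t_lo, e_lo)
        rows.append(
            {
                "gene": gene,
                "endpoint": endpoint,
                "n_high": len(high),
                "n_low": len(low),
                "median_high": km_hi.median,
                "median_low": km_lo.median,
                "chi2": chi2,
                "p_raw": p_raw,
            }
        )
    if not rows:
        return _empty_results()
    results = pd.DataFrame(rows)
    results["p_fdr"] = fdr_adjust(results["p_raw"].to_numpy())
    return results


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "gene",
            "endpoint",
            "n_high",
            "n_low",
            "median_high",
            "median_low",
            "chi2",
            "p_raw",
            "p_fdr",
        ]
    )


def write_screen_results(results: pd.DataFrame, path) -> None:
    """Write screen results CSV; unreached medians serialized as "NR"."""
    out = results.copy()
    for col in ("median_high", "median_low"):
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "NR" if (isinstance(v, float) and math.isnan(v)) else v
            )
    with atomic_write(path) as tmp:
        out.to_csv(tmp, index=False)


def read_screen_results(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in ("median_high", "median_low"):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col].replace("NR", np.nan))
    return table
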
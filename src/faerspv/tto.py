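"""Time-to-onset (TTO) analysis with Weibull modelling.

TTO is the number of days from the start of target-drug therapy
(earliest full START_DT of the report) to adverse-event onset (EVENT_DT).
Records with partial or missing dates, or with onset before start, are
excluded with per-reason counts.  The pooled TTO sample is summarized
(median, IQR, range, 30-day histogram) and fitted with a two-parameter
Weibull distribution by maximum likelihood; the shape parameter
classifies the hazard over time: beta < 1 means early failure (risk
concentrated right after initiation), beta = 1 a constant hazard
(random failure), beta > 1 wear-out failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .ingest import _parse_date_column

logger = logging.getLogger(__name__)

__all__ = ["compute_tto", "summarize_tto", "fit_weibull", "TTOSummary", "WeibullFit"]

_Z = 1.959963984540054


def compute_tto(demo: pd.DataFrame, ther: pd.DataFrame, case_set: set[int],
                drug: pd.DataFrame | None = None,
                target_canonical: str | None = None) -> tuple[pd.DataFrame, dict[str, int]]:
    """TTO records for the case set, with per-reason exclusion counts.

    ``demo`` must be normalized (``event_date`` present).  When ``drug``
    (standardized) and ``target_canonical`` are given, therapy rows are
    restricted to the target drug's sequence numbers; otherwise the
    earliest full START_DT of the report is used.
    Returns a frame with columns PRIMARYID, tto_days and a dict of
    exclusion counts (no_start, no_event, negative).
    """
    th = ther.copy()
    th["PRIMARYID"] = pd.to_numeric(th["PRIMARYID"], errors="coerce").astype("Int64")
    th = th[th["PRIMARYID"].isin(case_set)]
    if drug is not None and target_canonical is not None and "DSG_DRUG_SEQ" in th.columns:
        dr = drug.copy()
        dr["PRIMARYID"] = pd.to_numeric(dr["PRIMARYID"], errors="coerce").astype("Int64")
        tgt = dr[dr["canonical_name"] == target_canonical]
        if "DRUG_SEQ" in tgt.columns:
            key = set(map(tuple, tgt[["PRIMARYID", "DRUG_SEQ"]].astype(str).to_numpy()))
            pairs = th[["PRIMARYID", "DSG_DRUG_SEQ"]].astype(str).apply(tuple, axis=1)
            th = th[pairs.isin(key)]
    th["start"] = _parse_date_column(th["START_DT"])
    start = th.dropna(subset=["start"]).groupby("PRIMARYID")["start"].min()

    dm = demo.set_index(pd.to_numeric(demo["PRIMARYID"], errors="coerce").astype("Int64"))
    dm = dm[dm.index.isin(case_set)]
    event = dm["event_date"]

    excluded = {"no_start": 0, "no_event": 0, "negative": 0}
    rows = []
    for pid in sorted(case_set):
        s = start.get(pid, pd.NaT)
        e = event.get(pid, pd.NaT)
        if pd.isna(s):
            excluded["no_start"] += 1
            continue
        if pd.isna(e):
            excluded["no_event"] += 1
            continue
        days = (e - s).days
        if days < 0:
            excluded["negative"] += 1
            continue
        rows.append({"PRIMARYID": pid, "tto_days": float(days)})
    logger.info("compute_tto: %d usable records, excluded %s", len(rows), excluded)
    return pd.DataFrame(rows, columns=["PRIMARYID", "tto_days"]), excluded


@dataclass(frozen=True)
class TTOSummary:
    n: int
    median: float
    q1: float
    q3: float
    min: float
    max: float
    bins: pd.DataFrame  # columns: bin_start, bin_end, count, percent

    @property
    def first_month_percent(self) -> float:
        return float(self.bins.iloc[0]["percent"])


def summarize_tto(tto_days: np.ndarray | pd.Series, bin_width: int = 30) -> TTOSummary:
    """Median/IQR/range and a 30-day-bin histogram of onset times.

    Quantiles use the median-unbiased convention.  The first bin is
    [0, 30] inclusive (day-0 events count as first-month); later bins are
    left-open, (30, 60], (60, 90], ...
    """
    t = np.asarray(tto_days, dtype=float)
    if t.size == 0:
        raise ValueError("empty TTO sample")
    q1, med, q3 = np.quantile(t, [0.25, 0.5, 0.75], method="median_unbiased")
    edges = np.arange(0, np.max(t) + bin_width, bin_width)
    if len(edges) < 2 or edges[-1] < np.max(t):
        edges = np.append(edges, (edges[-1] if len(edges) else 0) + bin_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == 0:
            count = int(np.sum((t >= 0) & (t <= hi)))
        else:
            count = int(np.sum((t > lo) & (t <= hi)))
        rows.append({"bin_start": lo, "bin_end": hi, "count": count,
                     "percent": 100.0 * count / t.size})
    bins = pd.DataFrame(rows)
    assert bins["count"].sum() == t.size
    return TTOSummary(n=t.size, median=float(med), q1=float(q1), q3=float(q3),
                      min=float(np.min(t)), max=float(np.max(t)), bins=bins)


@dataclass(frozen=True)
class WeibullFit:
    scale_alpha: float
    scale_ci: tuple[float, float]
    shape_beta: float
    shape_ci: tuple[float, float]
    n: int
    log_likelihood: float
    failure_type: str  # 'early' | 'random' | 'wear-out'


def _weibull_negloglik(theta: np.ndarray, t: np.ndarray) -> float:
    ln_alpha, ln_beta = theta
    beta = np.exp(ln_beta)
    z = np.exp((np.log(t) - ln_alpha) * beta)
    return -float(np.sum(ln_beta - beta * ln_alpha + (beta - 1) * np.log(t) - z))


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                 - f(x - ei + ej) + f(x - ei - ej)) / (4 * h * h)
    return H


def fit_weibull(tto_days: np.ndarray | pd.Series) -> WeibullFit:
    """Maximum-likelihood Weibull fit with Wald CIs on the log parameters.

    Zero onset times are replaced by half a day (the distribution has
    support t > 0; same-day onsets are real).  The 95% CIs come from the
    inverse observed information on (ln alpha, ln beta), back-transformed.
    Failure type is 'early' when the shape CI lies entirely below 1,
    'wear-out' when entirely above, 'random' otherwise.
    """
    t = np.asarray(tto_days, dtype=float).copy()
    if t.size < 10:
        raise ValueError("need at least 10 onset times for a Weibull fit")
    if t.size < 30:
        logger.warning("fit_weibull: only %d records; estimates unstable", t.size)
    if np.any(t < 0):
        raise ValueError("negative onset times must be excluded upstream")
    t[t == 0] = 0.5

    # Method-of-moments-flavoured start: exponential scale, unit shape.
    theta0 = np.array([np.log(np.mean(t)), 0.0])
    res = optimize.minimize(_weibull_negloglik, theta0, args=(t,), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    if not res.success:
        raise RuntimeError(f"Weibull MLE did not converge: {res}")
    if res.fun > _weibull_negloglik(theta0, t) + 1e-9:
        raise RuntimeError("optimizer ended above the starting likelihood")
    ln_alpha, ln_beta = res.x
    H = _numeric_hessian(lambda th: _weibull_negloglik(th, t), res.x)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    alpha = float(np.exp(ln_alpha))
    beta = float(np.exp(ln_beta))
    a_ci = (alpha * np.exp(-_Z * se[0]), alpha * np.exp(_Z * se[0]))
    b_ci = (beta * np.exp(-_Z * se[1]), beta * np.exp(_Z * se[1]))
    if b_ci[1] < 1.0:
        ftype = "early"
    elif b_ci[0] > 1.0:
        ftype = "wear-out"
    else:
        ftype = "random"
    return WeibullFit(scale_alpha=alpha, scale_ci=(float(a_ci[0]), float(a_ci[1])),
                      shape_beta=beta, shape_ci=(float(b_ci[0]), float(b_ci[1])),
                      n=int(t.size), log_likelihood=float(-res.fun),
                      failure_type=ftype)
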
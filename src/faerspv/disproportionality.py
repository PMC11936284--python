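"""Disproportionality statistics for spontaneous-report signal detection.

Implements the four standard algorithms on a 2x2 drug-event contingency
table with cells (a, b, c, d), margins n1 = a+b (target-drug pairs),
n2 = a+c (event pairs), total N, and expected count E = n1*n2/N:

* **ROR** — reporting odds ratio ad/(bc) with the Woolf log-scale 95% CI.
* **PRR** — proportional reporting ratio [a/(a+b)]/[c/(c+d)] with its
  log-scale 95% CI, plus the 2x2 chi-squared statistic (Yates-corrected by
  default).
* **BCPNN IC** — the information component, a shrunken log2 observed/
  expected ratio.  The default variant is the moment approximation of the
  Bayesian confidence propagation neural network with Beta/Dirichlet
  hyperpriors all equal to 1 on the margins and 2 on the joint cell;
  ``variant="noren"`` selects the gamma-approximation credible bound.
* **MGPS EBGM** — the empirical-Bayes geometric mean of the posterior
  relative reporting rate under a two-component gamma mixture prior fitted
  across all cells by maximum marginal likelihood (negative-binomial
  mixture), with EB05 the 5th posterior percentile.

A drug-event pair is a *signal* when it satisfies all four criteria
simultaneously (configurable thresholds; the customary quartet by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ror", "prr_chi2", "bcpnn_ic", "fit_mgps", "ebgm", "evaluate_signal",
    "compute_signal_table", "invert_published_stats",
    "RorResult", "PrrResult", "IcResult", "EbgmResult", "MgpsPrior",
    "SignalThresholds", "InvertedTable",
]

_Z = 1.959963984540054  # two-sided 95% normal quantile
_LN2 = np.log(2.0)


def _cells(ct) -> tuple[float, float, float, float]:
    return float(ct.a), float(ct.b), float(ct.c), float(ct.d)


# ---------------------------------------------------------------------------
# Frequentist statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RorResult:
    point: float
    low: float
    high: float
    corrected: bool  # 0.5 added to all four cells because of a zero cell


@dataclass(frozen=True)
class PrrResult:
    point: float
    low: float
    high: float
    chi2: float
    yates: bool
    corrected: bool


def ror(ct) -> RorResult:
    """Reporting odds ratio with Woolf 95% CI.

    Any zero cell triggers the 0.5 continuity correction on all four cells
    (flagged in the result) so the estimate stays finite.
    """
    a, b, c, d = _cells(ct)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorResult(point, point * np.exp(-_Z * se), point * np.exp(_Z * se), corrected)


def chi2_statistic(ct, yates: bool = True) -> float:
    """Pearson chi-squared of the 2x2 table, optionally Yates-corrected."""
    a, b, c, d = _cells(ct)
    O = np.array([a, b, c, d])
    N = O.sum()
    n1, n2 = a + b, a + c
    E = np.array([n1 * n2, n1 * (N - n2), (N - n1) * n2, (N - n1) * (N - n2)]) / N
    if np.any(E == 0):
        return float("nan")
    y = 0.5 if yates else 0.0
    dev = np.abs(O - E) - y
    dev = np.maximum(dev, 0.0)  # correction never overshoots past zero
    return float(np.sum(dev ** 2 / E))


def prr_chi2(ct, yates: bool = True) -> PrrResult:
    """Proportional reporting ratio with 95% CI and the table chi-squared.

    The CI uses the delta-method variance 1/a - 1/(a+b) + 1/c - 1/(c+d) on
    the log scale.  A zero a or c cell triggers the 0.5 correction on all
    cells for the PRR (the chi-squared always uses the raw counts).
    """
    chi2 = chi2_statistic(ct, yates=yates)
    a, b, c, d = _cells(ct)
    corrected = a == 0 or c == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    point = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = np.sqrt(max(var, 0.0))
    return PrrResult(point, point * np.exp(-_Z * se), point * np.exp(_Z * se),
                     chi2, yates, corrected)


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IcResult:
    ic: float
    ic025: float
    variant: str


def bcpnn_ic(ct, variant: str = "bate1998") -> IcResult:
    """Information component and its lower 95% bound.

    ``bate1998`` is the original moment approximation: with joint prior
    weight 1 on the cell and marginal priors Beta(1, 1) inside Beta(2, 2)
    totals, IC025 = E(IC) - 2 sd(IC).  ``noren`` is the later credibility-
    interval approximation IC = log2[(a+0.5)/(E+0.5)] with an asymptotic
    expansion for the 2.5th percentile.
    """
    a, b, c, d = _cells(ct)
    N = a + b + c + d
    n1, n2 = a + b, a + c
    if variant == "bate1998":
        a1p = b1p = 1.0   # marginal prior weights
        ap = bp = 2.0     # marginal prior totals
        g11 = 1.0
        gamma = g11 * (N + ap) * (N + bp) / ((n1 + a1p) * (n2 + b1p))
        ic = np.log2((a + g11) * (N + ap) * (N + bp)
                     / ((N + gamma) * (n1 + a1p) * (n2 + b1p)))
        var = (1 / _LN2) ** 2 * (
            (N - a + gamma - g11) / ((a + g11) * (1 + N + gamma))
            + (N - n1 + ap - a1p) / ((n1 + a1p) * (1 + N + ap))
            + (N - n2 + bp - b1p) / ((n2 + b1p) * (1 + N + bp))
        )
        return IcResult(float(ic), float(ic - 2 * np.sqrt(var)), variant)
    if variant == "noren":
        E = n1 * n2 / N
        ic = np.log2((a + 0.5) / (E + 0.5))
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
        return IcResult(float(ic), float(ic025), variant)
    raise ValueError(f"unknown BCPNN variant {variant!r}")


# ---------------------------------------------------------------------------
# MGPS: empirical-Bayes gamma-Poisson shrinker
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the relative reporting rate.

    The true rate lambda of a cell is Gamma(alpha1, beta1) with probability
    Q and Gamma(alpha2, beta2) otherwise (shape/rate parameterization, so
    each component has mean alpha/beta).  ``loglik`` is the maximized
    marginal log-likelihood over the cells used for fitting.
    """

    Q: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 < self.Q < 1.0:
            raise ValueError("Q must lie in (0, 1)")
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")


#: DuMouchel's customary starting point for the mixture fit.
DUMOUCHEL_START = MgpsPrior(Q=1 / 3, alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0)


def _component_logpmf(a: np.ndarray, E: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    # Marginal of Poisson(lambda*E) with lambda ~ Gamma(alpha, beta):
    # negative binomial with size alpha and success prob beta/(beta+E).
    return stats.nbinom.logpmf(a, alpha, beta / (beta + E))


def mgps_marginal_loglik(a: np.ndarray, E: np.ndarray, prior: MgpsPrior) -> float:
    """Marginal log-likelihood of the observed cells under a mixture prior."""
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    l1 = _component_logpmf(a, E, prior.alpha1, prior.beta1) + np.log(prior.Q)
    l2 = _component_logpmf(a, E, prior.alpha2, prior.beta2) + np.log1p(-prior.Q)
    return float(np.sum(np.logaddexp(l1, l2)))


def _unpack(theta: np.ndarray) -> MgpsPrior:
    return MgpsPrior(Q=float(special.expit(theta[4])),
                     alpha1=float(np.exp(theta[0])), beta1=float(np.exp(theta[1])),
                     alpha2=float(np.exp(theta[2])), beta2=float(np.exp(theta[3])))


def fit_mgps(a: np.ndarray, E: np.ndarray, n_restarts: int = 4,
             seed: int = 0) -> MgpsPrior:
    """Fit the 5 mixture hyperparameters by maximum marginal likelihood.

    Bounded quasi-Newton optimization in log/logit space from the
    DuMouchel starting point plus ``n_restarts`` jittered restarts; the
    best optimum is returned with its log-likelihood.  Fewer than 20 cells
    triggers a warning (the prior is then weakly identified).
    """
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    if a.shape != E.shape or a.ndim != 1:
        raise ValueError("a and E must be 1-d arrays of equal length")
    if np.any(E <= 0):
        raise ValueError("expected counts must be positive")
    if len(a) < 20:
        logger.warning("fit_mgps: only %d cells; prior weakly identified", len(a))

    def nll(theta: np.ndarray) -> float:
        return -mgps_marginal_loglik(a, E, _unpack(theta))

    s = DUMOUCHEL_START
    theta0 = np.array([np.log(s.alpha1), np.log(s.beta1),
                       np.log(s.alpha2), np.log(s.beta2), special.logit(s.Q)])
    rng = np.random.default_rng(seed)
    starts = [theta0] + [theta0 + rng.normal(0, 1.0, size=5) for _ in range(n_restarts)]
    bounds = [(-12.0, 12.0)] * 4 + [(-10.0, 10.0)]
    best = None
    for t0 in starts:
        res = optimize.minimize(nll, t0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    prior = _unpack(best.x)
    loglik = -best.fun
    if not np.isfinite(loglik):
        raise RuntimeError(f"MGPS fit produced non-finite likelihood: {best}")
    start_ll = mgps_marginal_loglik(a, E, s)
    if loglik < start_ll - 1e-6:
        raise RuntimeError("optimizer ended below its starting point "
                           f"({loglik:.3f} < {start_ll:.3f})")
    return replace(prior, loglik=loglik)


@dataclass(frozen=True)
class EbgmResult:
    ebgm: float
    eb05: float
    posterior_q: float  # posterior weight of the first mixture component


def posterior_mixture(a: float, E: float, prior: MgpsPrior) -> tuple[float, tuple, tuple]:
    """Posterior of lambda given the cell: mixture of two gammas.

    Returns (Q*, (shape1, rate1), (shape2, rate2)) where Q* is the
    posterior weight of the first component from the marginal
    negative-binomial densities.
    """
    l1 = _component_logpmf(np.array([a]), np.array([E]), prior.alpha1, prior.beta1)[0]
    l2 = _component_logpmf(np.array([a]), np.array([E]), prior.alpha2, prior.beta2)[0]
    w1 = np.log(prior.Q) + l1
    w2 = np.log1p(-prior.Q) + l2
    qstar = float(np.exp(w1 - np.logaddexp(w1, w2)))
    return qstar, (prior.alpha1 + a, prior.beta1 + E), (prior.alpha2 + a, prior.beta2 + E)


def ebgm(ct_or_a, E: float | None = None, *, prior: MgpsPrior) -> EbgmResult:
    """Empirical-Bayes geometric mean and 5th posterior percentile.

    Accepts either a contingency table (using its ``a`` and expected
    count) or the pair (a, E) directly.  EBGM = exp E[ln lambda | a]
    under the gamma-mixture posterior; EB05 solves the posterior CDF for
    0.05 by bracketed root-finding.
    """
    if E is None:
        a, E = float(ct_or_a.a), float(ct_or_a.expected)
    else:
        a = float(ct_or_a)
    qstar, (s1, r1), (s2, r2) = posterior_mixture(a, E, prior)
    mean_log = qstar * (special.digamma(s1) - np.log(r1)) \
        + (1 - qstar) * (special.digamma(s2) - np.log(r2))
    ebgm_val = float(np.exp(mean_log))

    def cdf(x: float) -> float:
        return (qstar * stats.gamma.cdf(x, s1, scale=1 / r1)
                + (1 - qstar) * stats.gamma.cdf(x, s2, scale=1 / r2))

    q1 = stats.gamma.ppf(0.05, s1, scale=1 / r1)
    q2 = stats.gamma.ppf(0.05, s2, scale=1 / r2)
    lo, hi = 0.5 * min(q1, q2), 2.0 * max(q1, q2)
    while cdf(lo) > 0.05:
        lo *= 0.5
    while cdf(hi) < 0.05:
        hi *= 2.0
    eb05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12, rtol=1e-12))
    return EbgmResult(ebgm_val, eb05, qstar)


# ---------------------------------------------------------------------------
# Signal evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalThresholds:
    """The customary four-algorithm signal criteria, all configurable."""

    min_n: int = 3                 # minimum a for ROR/PRR rules
    ror_ci_low: float = 1.0        # ROR rule: CI lower bound strictly above this
    prr_min: float = 2.0           # PRR rule: point estimate at or above this ...
    chi2_min: float = 4.0          # ... with chi-squared at or above this
    ic025_min: float = 0.0         # BCPNN rule: IC025 strictly above this
    eb05_min: float = 2.0          # MGPS rule: EB05 strictly above this

    def __post_init__(self) -> None:
        if self.min_n < 1 or self.prr_min <= 0 or self.chi2_min <= 0 or self.eb05_min <= 0:
            raise ValueError("thresholds must be strictly positive")


def evaluate_signal(n: int, ror_res: RorResult, prr_res: PrrResult,
                    ic_res: IcResult, eb_res: EbgmResult,
                    thresholds: SignalThresholds = SignalThresholds()) -> dict[str, bool]:
    """Apply the per-algorithm rules and their conjunction."""
    t = thresholds
    flags = {
        "flag_ror": n >= t.min_n and ror_res.low > t.ror_ci_low,
        "flag_prr": n >= t.min_n and prr_res.point >= t.prr_min and prr_res.chi2 >= t.chi2_min,
        "flag_bcpnn": ic_res.ic025 > t.ic025_min,
        "flag_mgps": eb_res.eb05 > t.eb05_min,
    }
    flags["signal"] = all(flags.values())
    return flags


def compute_signal_table(tables: dict, prior: MgpsPrior | None = None,
                         thresholds: SignalThresholds = SignalThresholds(),
                         yates: bool = True,
                         bcpnn_variant: str = "bate1998") -> pd.DataFrame:
    """All four statistics plus flags for every term in a table map.

    The MGPS prior is fitted across all supplied cells unless one is
    passed in (e.g. to reuse the unstratified prior inside a sex stratum).
    """
    terms = list(tables)
    a = np.array([tables[t].a for t in terms], dtype=float)
    E = np.array([tables[t].expected for t in terms], dtype=float)
    if prior is None:
        prior = fit_mgps(a, E)
    rows = []
    for term, ai, Ei in zip(terms, a, E):
        ct = tables[term]
        r = ror(ct)
        p = prr_chi2(ct, yates=yates)
        ic = bcpnn_ic(ct, variant=bcpnn_variant)
        eb = ebgm(ai, Ei, prior=prior)
        row = {"term": term, "a": ct.a, "b": ct.b, "c": ct.c, "d": ct.d, "E": Ei,
               "ROR": r.point, "ROR_low": r.low, "ROR_high": r.high,
               "PRR": p.point, "PRR_low": p.low, "PRR_high": p.high,
               "chi2": p.chi2, "IC": ic.ic, "IC025": ic.ic025,
               "EBGM": eb.ebgm, "EBGM05": eb.eb05,
               "corrected": r.corrected or p.corrected}
        row.update(evaluate_signal(ct.a, r, p, ic, eb, thresholds))
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(["signal", "a"], ascending=False, ignore_index=True)
    df.attrs["mgps_prior"] = prior
    return df


# ---------------------------------------------------------------------------
# Inverting published statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InvertedTable:
    """A 2x2 table (real-valued cells) recovered from printed statistics."""

    a: float
    b: float
    c: float
    d: float
    residual: float
    yates: bool

    @property
    def N(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def n1(self) -> float:
        return self.a + self.b

    @property
    def n2(self) -> float:
        return self.a + self.c

    @property
    def expected(self) -> float:
        return self.n1 * self.n2 / self.N


def invert_published_stats(a: float, ror_point: float, ror_ci: tuple[float, float],
                           chi2: float, yates_try_both: bool = True,
                           tol: float = 0.02) -> InvertedTable:
    """Recover (b, c, d) from a printed (a, ROR, ROR 95% CI, chi-squared) row.

    Solves the 3-equation system {ROR = ad/(bc); Woolf variance
    sum(1/cell) = ((ln U - ln L) / (2 z))^2; chi2(a,b,c,d) = printed chi2}
    for positive reals.  The first two equations are solved in closed form
    given b, leaving a 1-d bracketed root-find on the chi-squared (both
    chi-squared conventions are attempted when ``yates_try_both``).
    Raises if the best relative chi-squared residual exceeds ``tol``.

    Useful for validating a signal table against published rows when the
    underlying database is not redistributable.
    """
    L, U = ror_ci
    if not (0 < L < U):
        raise ValueError("ROR CI must satisfy 0 < low < high")
    if a < 1:
        raise ValueError("a must be >= 1")
    woolf_var = ((np.log(U) - np.log(L)) / (2 * _Z)) ** 2
    w = woolf_var - 1 / a
    if w <= 0:
        raise ValueError("CI width implies non-positive 1/b + 1/c + 1/d")
    R = float(ror_point)

    # Given b, the ROR point and Woolf variance equations are solved
    # exactly: 1/c + 1/d = w - 1/b with d = R*b*c/a gives
    # c = (1 + a/(R*b)) / (w - 1/b), d = R*b*c/a.  The remaining unknown b
    # is pinned by the chi-squared equation via 1-d bracketed root-finding.
    def table_for_b(b: float, yates: bool) -> InvertedTable:
        u = w - 1 / b
        c = (1 + a / (R * b)) / u
        d = R * b * c / a
        return InvertedTable(a, b, c, d, 0.0, yates)

    def chi2_gap(b: float, yates: bool) -> float:
        return chi2_statistic(table_for_b(b, yates), yates=yates) / chi2 - 1.0

    # The ROR point, Woolf variance and chi-squared are all invariant under
    # the b <-> c transpose, so the system generically has a mirror pair of
    # solutions.  In a spontaneous-report database the target drug's margin
    # is far smaller than a reported event's comparator margin, so the
    # b <= c branch is the meaningful one; it is preferred whenever its
    # residual is competitive.
    conventions = (True, False) if yates_try_both else (True,)
    candidates: list[InvertedTable] = []
    b_grid = np.geomspace((1 / w) * (1 + 1e-9) + 1e-12, 1e12, 800)
    for yates in conventions:
        gaps = np.array([chi2_gap(b, yates) for b in b_grid])
        ok = np.isfinite(gaps)
        b_roots = [
            optimize.brentq(chi2_gap, b_grid[i], b_grid[i + 1], args=(yates,),
                            xtol=1e-12, rtol=1e-14)
            for i in np.nonzero(ok[:-1] & ok[1:]
                                & (np.sign(gaps[:-1]) != np.sign(gaps[1:])))[0]
        ]
        # printed rounding can leave the curve just short of the target;
        # keep the closest approach on each transpose branch as fallback
        on_low_branch = np.array([table_for_b(b, yates).b <= table_for_b(b, yates).c
                                  for b in b_grid])
        for branch in (on_low_branch, ~on_low_branch):
            sel = ok & branch
            if not sel.any():
                continue
            i = int(np.nanargmin(np.abs(np.where(sel, gaps, np.nan))))
            lo, hi = b_grid[max(i - 1, 0)], b_grid[min(i + 1, len(b_grid) - 1)]
            res = optimize.minimize_scalar(lambda b: abs(chi2_gap(b, yates)),
                                           bounds=(lo, hi), method="bounded",
                                           options={"xatol": 1e-10})
            b_roots.append(float(res.x))
        for b_root in b_roots:
            t = table_for_b(b_root, yates)
            candidates.append(InvertedTable(t.a, t.b, t.c, t.d,
                                            abs(chi2_gap(b_root, yates)), yates))
    if not candidates:
        raise ValueError("no consistent table found (no finite candidates)")
    best_res = min(t.residual for t in candidates)
    window = max(1.5 * best_res, best_res + 1e-6)
    eligible = [t for t in candidates if t.residual <= window]
    preferred = [t for t in eligible if t.b <= t.c] or eligible
    # ties between chi-squared conventions go to the Yates default
    best = min(preferred, key=lambda t: (t.residual, not t.yates))
    yates_hits = [t for t in preferred if t.yates]
    if yates_hits and min(t.residual for t in yates_hits) <= window:
        best = min(yates_hits, key=lambda t: t.residual)
    if best.residual > tol:
        raise ValueError(f"no consistent table found (best residual {best.residual})")
    return best
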
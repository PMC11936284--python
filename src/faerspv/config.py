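"""Simulation configuration for the synthetic FAERS-like report generator.

The default categorical margins (sex, age band, serious outcome, reporter
occupation, reporting country, reporting year) reproduce the composition of
a real spontaneous-report case series for a recently approved drug, so that
descriptive summaries computed downstream land on realistic percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimConfig", "DEFAULT_TARGET_DRUG", "DEFAULT_TARGET_VARIANTS"]

DEFAULT_TARGET_DRUG = "sodium zirconium cyclosilicate"
DEFAULT_TARGET_VARIANTS = (
    "LOKELMA",
    "Lokelma",
    "SODIUM ZIRCONIUM CYCLOSILICATE",
    "Sodium zirconium cyclosilicate",
    "sodium  zirconium cyclosilicate.",
)

# Margins of the emulated case series (counts over 1,154 reports; outcome
# codes over 932 outcome entries).
_SEX_COUNTS = {"M": 559, "F": 335, "UNK": 260}
_AGE_COUNTS = {"<45": 28, "45-64": 106, "65-74": 120, ">74": 333, "UNK": 567}
_OUTCOME_COUNTS = {"DE": 481, "OT": 224, "HO": 184, "LT": 34, "DS": 8, "RI": 1}
_COUNTRY_COUNTS = {"US": 884, "JP": 197, "CN": 16, "GB": 16, "CO": 10, "OTHER": 31}
_REPORTER_COUNTS = {"MD": 392, "CN": 353, "PH": 338, "HP": 5, "UNK": 66}
_YEAR_COUNTS = {2018: 7, 2019: 100, 2020: 157, 2021: 202, 2022: 269, 2023: 419}


def _normalize(counts: dict) -> dict:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def _check_distribution(name: str, probs: dict) -> None:
    vals = np.asarray(list(probs.values()), dtype=float)
    if np.any(vals < 0):
        raise ValueError(f"{name}: negative probability")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name}: probabilities sum to {vals.sum():.12f}, not 1")


@dataclass
class SimConfig:
    """Parameters of the synthetic spontaneous-report universe.

    Attributes
    ----------
    n_reports
        Number of distinct cases to generate (before duplicate submissions).
    n_background_drugs
        Size of the comparator drug vocabulary.
    n_pts
        Number of adverse-event preferred terms (PT0001..), excluding the
        filler term PT0000 assigned to reports whose Bernoulli draws yield
        no event.
    n_socs
        Number of system organ classes the PT vocabulary is mapped onto.
    target_drug_share
        Fraction of cases whose primary-suspect drug is the target drug.
    pt_base_rates
        Per-report occurrence probability of each PT among comparator-drug
        reports.  Default is Zipf-like: 0.05 / rank.
    planted_rr
        Map PT id -> true relative reporting rate lambda; the target-drug
        occurrence probability of that PT is min(1, base_rate * lambda).
        PTs not listed have lambda = 1 (no signal).
    tto_shape, tto_scale
        Weibull shape (dimensionless) and scale (days) of the planted
        time-to-onset distribution.  Defaults emulate an early-failure
        profile (shape < 1, median onset about a month).
    duplicate_rate
        Fraction of cases submitted a second time under a new PRIMARYID
        sharing the CASEID, with a later FDA_DT.
    bad_date_rate
        Fraction of EVENT_DT / START_DT values truncated to YYYYMM or YYYY
        or blanked, to exercise partial-date handling.
    """

    n_reports: int = 10_000
    n_background_drugs: int = 50
    n_pts: int = 100
    n_socs: int = 10
    target_drug_share: float = 0.1
    pt_base_rates: np.ndarray | None = None
    planted_rr: dict[str, float] = field(default_factory=dict)
    sex_probs: dict[str, float] = field(default_factory=lambda: _normalize(_SEX_COUNTS))
    age_group_probs: dict[str, float] = field(default_factory=lambda: _normalize(_AGE_COUNTS))
    outcome_probs: dict[str, float] = field(default_factory=lambda: _normalize(_OUTCOME_COUNTS))
    country_probs: dict[str, float] = field(default_factory=lambda: _normalize(_COUNTRY_COUNTS))
    reporter_probs: dict[str, float] = field(default_factory=lambda: _normalize(_REPORTER_COUNTS))
    year_probs: dict[int, float] = field(default_factory=lambda: _normalize(_YEAR_COUNTS))
    tto_shape: float = 0.62
    tto_scale: float = 95.51
    duplicate_rate: float = 0.05
    bad_date_rate: float = 0.05
    target_drug: str = DEFAULT_TARGET_DRUG
    target_variants: tuple[str, ...] = DEFAULT_TARGET_VARIANTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if self.n_background_drugs < 1 or self.n_pts < 1 or self.n_socs < 1:
            raise ValueError("vocabulary sizes must be positive")
        if not 0.0 < self.target_drug_share < 1.0:
            raise ValueError("target_drug_share must lie in (0, 1)")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1)")
        if not 0.0 <= self.bad_date_rate < 1.0:
            raise ValueError("bad_date_rate must lie in [0, 1)")
        if self.tto_shape <= 0 or self.tto_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        for name in ("sex_probs", "age_group_probs", "outcome_probs",
                     "country_probs", "reporter_probs", "year_probs"):
            _check_distribution(name, getattr(self, name))
        if self.pt_base_rates is None:
            self.pt_base_rates = 0.05 / np.arange(1, self.n_pts + 1, dtype=float)
        else:
            self.pt_base_rates = np.asarray(self.pt_base_rates, dtype=float)
            if self.pt_base_rates.shape != (self.n_pts,):
                raise ValueError("pt_base_rates must have length n_pts")
            if np.any(self.pt_base_rates < 0) or np.any(self.pt_base_rates > 1):
                raise ValueError("pt_base_rates must lie in [0, 1]")
        for pt, lam in self.planted_rr.items():
            if lam < 0:
                raise ValueError(f"planted_rr[{pt}] must be >= 0")
            rate = self.pt_base_rates[self.pt_index(pt)] * lam
            if rate > 1:
                warnings.warn(
                    f"planted_rr[{pt}] = {lam} drives the target occurrence "
                    f"probability to {rate:.3f}; capping at 1",
                    stacklevel=2,
                )

    def pt_name(self, index: int) -> str:
        """1-based PT id, e.g. pt_name(7) == 'PT0007'."""
        return f"PT{index:04d}"

    def pt_index(self, pt: str) -> int:
        idx = int(pt.removeprefix("PT"))
        if not 1 <= idx <= self.n_pts:
            raise KeyError(f"unknown PT id {pt!r}")
        return idx - 1
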
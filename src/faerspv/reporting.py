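"""Descriptive case-series tables and end-to-end pipeline orchestration.

The descriptive table mirrors the usual "clinical characteristics" layout
of a pharmacovigilance case series: one block each for sex, age band,
serious outcome, reporter occupation, reporting region and reporting year,
with counts and half-up-rounded percentages.  The outcome block's
denominator is the number of outcome *entries* (a report may carry several
outcome codes), every other block's denominator is the number of reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimConfig
from .contingency import build_pt_tables, load_pt2soc, rollup_soc, stratify_by_sex
from .disproportionality import SignalThresholds, compute_signal_table
from .ingest import (deduplicate, load_synonym_map, normalize_reports, read_tables,
                     select_target_reports, standardize_drug)
from .synthetic import generate_database, write_database
from .tto import compute_tto, fit_weibull, summarize_tto

logger = logging.getLogger(__name__)

__all__ = ["round_percent", "describe_cases", "annual_trend", "run_pipeline",
           "DescriptiveTable"]

AGE_BANDS = [("<45", 0.0, 45.0), ("45-64", 45.0, 65.0),
             ("65-74", 65.0, 75.0), (">74", 75.0, np.inf)]
OUTCOME_ORDER = ["DE", "HO", "LT", "DS", "CA", "RI", "OT"]


def round_percent(count: int, denom: int) -> float:
    """Percentage rounded half-up to 2 decimals (table style)."""
    if denom == 0:
        return float("nan")
    pct = Decimal(count) * 100 / Decimal(denom)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DescriptiveTable:
    """Blocks of (category, count, percent); percentages per block denominator."""

    blocks: dict[str, list[tuple[str, int, float]]]
    n_reports: int
    n_outcome_entries: int

    def block_percent(self, block: str, categories: list[str]) -> float:
        """Aggregate share of several categories: sum of their rounded
        percentages, matching how such tables quote combined shares."""
        pcts = {cat: p for cat, _, p in self.blocks[block]}
        return round(sum(pcts[c] for c in categories), 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"block": b, "category": cat, "count": n, "percent": p}
                for b, entries in self.blocks.items() for cat, n, p in entries]
        return pd.DataFrame(rows)


def _count_block(values: pd.Series, order: list[str] | None = None) -> list[tuple[str, int]]:
    counts = values.value_counts()
    if order:
        cats = [c for c in order if c in counts.index]
        cats += [c for c in counts.index if c not in cats]
    else:
        cats = list(counts.index)
    return [(c, int(counts[c])) for c in cats]


def describe_cases(demo_cases: pd.DataFrame, outc_cases: pd.DataFrame) -> DescriptiveTable:
    """Descriptive table for a deduplicated case set.

    ``demo_cases`` must be normalized (sex, age_years, fda_date present);
    ``outc_cases`` holds the OUTC rows of the case set.
    """
    n = len(demo_cases)
    if n == 0:
        raise ValueError("empty case set")
    blocks: dict[str, list[tuple[str, int, float]]] = {}

    sex = demo_cases["sex"].replace({"M": "Male", "F": "Female", "unknown": "Unknown"})
    blocks["sex"] = [(c, k, round_percent(k, n))
                     for c, k in _count_block(sex, ["Female", "Male", "Unknown"])]

    age = demo_cases["age_years"]
    band = pd.Series("Unknown", index=demo_cases.index, dtype=object)
    for name, lo, hi in AGE_BANDS:
        band[(age >= lo) & (age < hi)] = name
    order = [b[0] for b in AGE_BANDS] + ["Unknown"]
    blocks["age"] = [(c, k, round_percent(k, n)) for c, k in _count_block(band, order)]

    oc = outc_cases["OUTC_COD"].astype(str).str.strip().str.upper()
    n_outc = len(oc)
    blocks["outcome"] = [(c, k, round_percent(k, n_outc))
                         for c, k in _count_block(oc, OUTCOME_ORDER)]

    rep = demo_cases.get("OCCP_COD", pd.Series("", index=demo_cases.index))
    rep = rep.astype(str).str.strip().str.upper().replace("", "Unknown")
    blocks["reporter"] = [(c, k, round_percent(k, n)) for c, k in _count_block(rep)]

    region = demo_cases.get("OCCR_COUNTRY", pd.Series("", index=demo_cases.index))
    region = region.astype(str).str.strip().replace("", "Unknown")
    blocks["region"] = [(c, k, round_percent(k, n)) for c, k in _count_block(region)]

    year = demo_cases["fda_date"].dt.year.astype("Int64").astype(str).replace("<NA>", "unknown")
    blocks["year"] = [(c, k, round_percent(k, n))
                      for c, k in sorted(_count_block(year), key=lambda x: x[0])]

    return DescriptiveTable(blocks=blocks, n_reports=n, n_outcome_entries=n_outc)


def annual_trend(demo_cases: pd.DataFrame) -> dict[str, int]:
    """Case counts per FDA receipt year; missing year under 'unknown'."""
    year = demo_cases["fda_date"].dt.year
    counts: dict[str, int] = {}
    for y, k in year.value_counts(dropna=False).items():
        counts["unknown" if pd.isna(y) else str(int(y))] = int(k)
    return dict(sorted(counts.items()))


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def run_pipeline(input_dir: str | Path, out_dir: str | Path,
                 target_drug: str | None = None,
                 roles: set[str] = frozenset({"PS"}),
                 thresholds: SignalThresholds = SignalThresholds(),
                 sex_subgroups: bool = True) -> dict:
    """Ingest -> dedup -> select -> count -> signals -> TTO -> reports.

    ``input_dir`` must hold DEMO/DRUG/REAC/OUTC/THER.txt plus synonyms.tsv
    (and optionally pt2soc.tsv and manifest.json, as written by the
    simulator).  All artifacts are written to ``out_dir`` as CSV plus a
    plain-text run manifest; returns the manifest dict.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "input_dir": str(input_dir),
                      "stages": {}}

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    tables = read_tables({k: input_dir / f"{k}.txt"
                          for k in ("DEMO", "DRUG", "REAC", "OUTC", "THER")})
    demo = normalize_reports(tables["DEMO"])
    stage("ingest", demo=len(demo), drug=len(tables["DRUG"]), reac=len(tables["REAC"]))

    demo, removed = deduplicate(demo)
    kept = set(demo["PRIMARYID"].dropna().astype("int64"))
    drug = tables["DRUG"][pd.to_numeric(tables["DRUG"]["PRIMARYID"]).isin(kept)]
    reac = tables["REAC"][pd.to_numeric(tables["REAC"]["PRIMARYID"]).isin(kept)]
    outc = tables["OUTC"][pd.to_numeric(tables["OUTC"]["PRIMARYID"]).isin(kept)]
    ther = tables["THER"][pd.to_numeric(tables["THER"]["PRIMARYID"]).isin(kept)]
    stage("deduplicate", removed=removed, reports=len(demo))

    synonyms = load_synonym_map(input_dir / "synonyms.tsv")
    if target_drug is None:
        target_drug = next(iter(synonyms.values()))
    drug = standardize_drug(drug, synonyms)
    case_set = select_target_reports(drug, target_drug, roles)
    stage("select_target", target_drug=target_drug, cases=len(case_set))

    demo_cases = demo[demo["PRIMARYID"].isin(case_set)]
    outc_cases = outc[pd.to_numeric(outc["PRIMARYID"]).isin(case_set)]
    desc = describe_cases(demo_cases, outc_cases)
    desc.to_frame().to_csv(out_dir / "descriptive.csv", index=False)
    trend = annual_trend(demo_cases)
    pd.Series(trend, name="count").rename_axis("year").to_csv(out_dir / "annual_trend.csv")

    pt_tables = build_pt_tables(reac, case_set)
    signal_pt = compute_signal_table(pt_tables, thresholds=thresholds)
    signal_pt.to_csv(out_dir / "signals_pt.csv", index=False)
    prior = signal_pt.attrs["mgps_prior"]
    stage("signals_pt", terms=len(signal_pt), signals=int(signal_pt["signal"].sum()))

    pt2soc_path = input_dir / "pt2soc.tsv"
    if pt2soc_path.exists():
        soc_tables = rollup_soc(reac, case_set, load_pt2soc(pt2soc_path))
        signal_soc = compute_signal_table(soc_tables, thresholds=thresholds)
        signal_soc.to_csv(out_dir / "signals_soc.csv", index=False)
        stage("signals_soc", terms=len(signal_soc))
    else:
        logger.warning("no pt2soc.tsv; skipping SOC rollup")
        manifest["stages"]["signals_soc"] = "skipped (no pt2soc.tsv)"

    if sex_subgroups:
        for sex in ("M", "F"):
            strat = stratify_by_sex(reac, demo, sex, case_set)
            if not strat:
                continue
            sub = compute_signal_table(strat, prior=prior, thresholds=thresholds)
            sub.to_csv(out_dir / f"signals_pt_{sex}.csv", index=False)
            stage(f"signals_{sex}", terms=len(sub), signals=int(sub["signal"].sum()))

    ttos, excluded = compute_tto(demo, ther, case_set, drug, target_drug)
    stage("tto", usable=len(ttos), **excluded)
    if len(ttos) >= 10:
        summ = summarize_tto(ttos["tto_days"])
        fit = fit_weibull(ttos["tto_days"])
        pd.DataFrame([{
            "n": summ.n, "median": summ.median, "q1": summ.q1, "q3": summ.q3,
            "min": summ.min, "max": summ.max,
            "scale_alpha": fit.scale_alpha, "scale_low": fit.scale_ci[0],
            "scale_high": fit.scale_ci[1], "shape_beta": fit.shape_beta,
            "shape_low": fit.shape_ci[0], "shape_high": fit.shape_ci[1],
            "failure_type": fit.failure_type,
        }]).to_csv(out_dir / "tto_summary.csv", index=False)
        summ.bins.to_csv(out_dir / "tto_histogram.csv", index=False)
        stage("weibull", shape=round(fit.shape_beta, 4), failure_type=fit.failure_type)
    else:
        logger.warning("too few TTO records (%d) for a Weibull fit", len(ttos))
        manifest["stages"]["weibull"] = f"skipped ({len(ttos)} records)"

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def simulate_to_dir(config: SimConfig, out_dir: str | Path) -> dict:
    """Generate a synthetic universe and write it; returns its manifest."""
    db = generate_database(config)
    write_database(db, out_dir)
    return db.manifest
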
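"""Synthetic FAERS-like database generator with known ground truth.

Generates the five quarterly-dialect ASCII tables (DEMO, DRUG, REAC, OUTC,
THER) for a universe containing one target drug plus a background drug
vocabulary, with planted relative-reporting rates per preferred term,
planted duplicate case submissions, partial/invalid dates, and
Weibull-distributed onset times — so every downstream pipeline stage can be
validated against the generative truth.

Generative model
----------------
Each of ``n_reports`` cases is independently a target-drug case with
probability ``target_drug_share`` (realised as an exact count).  A target
case mentions PT *j* with probability ``min(1, base_rate_j * lambda_j)``;
a comparator case with probability ``base_rate_j``; draws are independent
across PTs, so the signal cell count for PT *j* is Binomial(n_target,
min(1, base_j * lambda_j)).  A case with no Bernoulli hit receives the
filler term ``PT0000`` (so every report carries at least one reaction
without perturbing the per-PT binomial truth).  Onset time is
``round(Weibull(shape, scale))`` days from therapy start; FDA receipt
follows onset by 0-60 days.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = ["SyntheticDatabase", "generate_database", "planted_truth", "write_database"]

FILLER_PT = "PT0000"
FILLER_SOC = "SOC00"

_SEX_FIELD = {"M": "M", "F": "F", "UNK": ""}
_AGE_BOUNDS = {"<45": (1, 44), "45-64": (45, 64), "65-74": (65, 74), ">74": (75, 100)}


@dataclass
class SyntheticDatabase:
    """In-memory synthetic universe: the five raw tables plus ground truth."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    truth: pd.DataFrame
    pt2soc: pd.DataFrame
    synonyms: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {"DEMO": self.demo, "DRUG": self.drug, "REAC": self.reac,
                "OUTC": self.outc, "THER": self.ther}


def _choice(rng: np.random.Generator, probs: dict, n: int) -> np.ndarray:
    keys = np.array(list(probs.keys()), dtype=object)
    p = np.array(list(probs.values()), dtype=float)
    return keys[rng.choice(len(keys), size=n, p=p)]


def _format_dates(days: np.ndarray) -> np.ndarray:
    """Days-since-epoch ints -> YYYYMMDD strings."""
    ts = pd.to_datetime(days, unit="D", origin="unix")
    return ts.strftime("%Y%m%d").to_numpy(dtype=object)


def _corrupt_dates(rng: np.random.Generator, dates: np.ndarray, rate: float) -> np.ndarray:
    """Truncate a fraction of YYYYMMDD strings to YYYYMM/YYYY or blank them."""
    out = dates.copy()
    hit = rng.random(len(out)) < rate
    mode = rng.choice(3, size=len(out), p=[0.5, 0.3, 0.2])
    for i in np.nonzero(hit)[0]:
        if mode[i] == 0:
            out[i] = out[i][:6]
        elif mode[i] == 1:
            out[i] = out[i][:4]
        else:
            out[i] = ""
    return out


def planted_truth(config: SimConfig) -> pd.DataFrame:
    """Ground-truth table: per PT the true relative rate and expected signal cell.

    ``expected_a = n_target * min(1, base_rate * lambda)`` with
    ``n_target = round(target_drug_share * n_reports)``.
    """
    n_target = int(round(config.target_drug_share * config.n_reports))
    rows = []
    for j in range(config.n_pts):
        pt = config.pt_name(j + 1)
        lam = float(config.planted_rr.get(pt, 1.0))
        p = min(1.0, config.pt_base_rates[j] * lam)
        rows.append({
            "pt": pt,
            "base_rate": config.pt_base_rates[j],
            "lambda": lam,
            "target_rate": p,
            "expected_a": n_target * p,
        })
    return pd.DataFrame(rows)


def generate_database(config: SimConfig) -> SyntheticDatabase:
    """Draw one synthetic universe. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    n_target = int(round(config.target_drug_share * n))

    caseid = 100_000_001 + np.arange(n, dtype=np.int64)
    primaryid = caseid * 10 + 1  # FAERS style: CASEID || version digit
    is_target = np.zeros(n, dtype=bool)
    is_target[rng.permutation(n)[:n_target]] = True

    sex = _choice(rng, config.sex_probs, n)
    age_band = _choice(rng, config.age_group_probs, n)
    country = _choice(rng, config.country_probs, n)
    reporter = _choice(rng, config.reporter_probs, n)
    outcome = _choice(rng, config.outcome_probs, n)
    year = _choice(rng, config.year_probs, n).astype(int)

    age = np.empty(n, dtype=object)
    age_cod = np.empty(n, dtype=object)
    for band, (lo, hi) in _AGE_BOUNDS.items():
        idx = np.nonzero(age_band == band)[0]
        age[idx] = rng.integers(lo, hi + 1, size=len(idx)).astype(str)
        age_cod[idx] = "YR"
    unk = age_band == "UNK"
    age[unk] = ""
    age_cod[unk] = ""

    # Therapy start uniform within the report year (leaving December so the
    # 0-60 day receipt lag rarely crosses the year boundary), onset after a
    # Weibull-distributed whole number of days.
    year_start = (pd.to_datetime(year.astype(str) + "0101") - pd.Timestamp("1970-01-01")).days.to_numpy()
    start_day = year_start + rng.integers(0, 334, size=n)
    tto_days = np.rint(rng.weibull(config.tto_shape, size=n) * config.tto_scale).astype(np.int64)
    event_day = start_day + tto_days
    fda_day = event_day + rng.integers(0, 61, size=n)

    start_dt = _format_dates(start_day)
    event_dt = _format_dates(event_day)
    fda_dt = _format_dates(fda_day)
    # FDA_DT stays intact (the dedup rule keys on it); onset-side dates carry
    # the planted corruption.
    event_dt = _corrupt_dates(rng, event_dt, config.bad_date_rate)
    start_dt = _corrupt_dates(rng, start_dt, config.bad_date_rate)

    # Reactions: independent Bernoulli per PT, per report.
    truth = planted_truth(config)
    reac_pid: list[np.ndarray] = []
    reac_pt: list[np.ndarray] = []
    any_hit = np.zeros(n, dtype=bool)
    p_base = config.pt_base_rates
    p_target = truth["target_rate"].to_numpy()
    for j in range(config.n_pts):
        u = rng.random(n)
        hit = u < np.where(is_target, p_target[j], p_base[j])
        idx = np.nonzero(hit)[0]
        if len(idx):
            reac_pid.append(primaryid[idx])
            reac_pt.append(np.full(len(idx), config.pt_name(j + 1), dtype=object))
        any_hit |= hit
    none_idx = np.nonzero(~any_hit)[0]
    if len(none_idx):
        reac_pid.append(primaryid[none_idx])
        reac_pt.append(np.full(len(none_idx), FILLER_PT, dtype=object))
    reac = pd.DataFrame({
        "PRIMARYID": np.concatenate(reac_pid),
        "PT": np.concatenate(reac_pt),
    }).sort_values(["PRIMARYID", "PT"], kind="stable", ignore_index=True)

    # Drugs: 1 + Poisson(1) per report; the first entry is the primary
    # suspect.  Background reports occasionally list the target drug as a
    # concomitant, exercising the role filter downstream.
    bg_names = np.array([f"BGDRUG{k:03d}" for k in range(1, config.n_background_drugs + 1)],
                        dtype=object)
    n_drugs = 1 + rng.poisson(1.0, size=n)
    drug_rows = {"PRIMARYID": [], "DRUG_SEQ": [], "ROLE_COD": [], "DRUGNAME": []}
    ther_rows = {"PRIMARYID": [], "DSG_DRUG_SEQ": [], "START_DT": []}
    variants = np.array(config.target_variants, dtype=object)
    primary_name = np.where(
        is_target,
        variants[rng.integers(0, len(variants), size=n)],
        bg_names[rng.integers(0, len(bg_names), size=n)],
    )
    extra_roles = np.array(["SS", "C", "I"], dtype=object)
    target_as_concomitant = (~is_target) & (rng.random(n) < 0.01)
    for i in range(n):
        k = n_drugs[i]
        names = [primary_name[i]]
        roles = ["PS"]
        for _ in range(k - 1):
            names.append(bg_names[rng.integers(0, len(bg_names))])
            roles.append(extra_roles[rng.integers(0, len(extra_roles))])
        if target_as_concomitant[i]:
            names.append(variants[rng.integers(0, len(variants))])
            roles.append("C")
        for seq, (nm, rl) in enumerate(zip(names, roles), start=1):
            drug_rows["PRIMARYID"].append(primaryid[i])
            drug_rows["DRUG_SEQ"].append(seq)
            drug_rows["ROLE_COD"].append(rl)
            drug_rows["DRUGNAME"].append(nm)
        ther_rows["PRIMARYID"].append(primaryid[i])
        ther_rows["DSG_DRUG_SEQ"].append(1)
        ther_rows["START_DT"].append(start_dt[i])
    drug = pd.DataFrame(drug_rows)
    ther = pd.DataFrame(ther_rows)

    demo = pd.DataFrame({
        "PRIMARYID": primaryid,
        "CASEID": caseid,
        "FDA_DT": fda_dt,
        "EVENT_DT": event_dt,
        "SEX": [_SEX_FIELD[s] for s in sex],
        "AGE": age,
        "AGE_COD": age_cod,
        "OCCP_COD": ["" if r == "UNK" else r for r in reporter],
        "OCCR_COUNTRY": country,
    })
    outc = pd.DataFrame({"PRIMARYID": primaryid, "OUTC_COD": outcome})

    # Duplicate submissions: a fraction of cases is re-submitted under a new
    # PRIMARYID (version digit 2) with a strictly later FDA_DT; the child
    # tables are copied under the new id.
    n_dup = int(round(config.duplicate_rate * n))
    dup_idx = rng.permutation(n)[:n_dup]
    if n_dup:
        dup_pid = caseid[dup_idx] * 10 + 2
        dup_fda = _format_dates(fda_day[dup_idx] + rng.integers(1, 181, size=n_dup))
        dup_demo = demo.iloc[dup_idx].copy()
        dup_demo["PRIMARYID"] = dup_pid
        dup_demo["FDA_DT"] = dup_fda
        pid_map = dict(zip(primaryid[dup_idx], dup_pid))

        def _copy_rows(df: pd.DataFrame) -> pd.DataFrame:
            sub = df[df["PRIMARYID"].isin(pid_map)].copy()
            sub["PRIMARYID"] = sub["PRIMARYID"].map(pid_map)
            return sub

        demo = pd.concat([demo, dup_demo], ignore_index=True)
        drug = pd.concat([drug, _copy_rows(drug)], ignore_index=True)
        reac = pd.concat([reac, _copy_rows(reac)], ignore_index=True)
        outc = pd.concat([outc, _copy_rows(outc)], ignore_index=True)
        ther = pd.concat([ther, _copy_rows(ther)], ignore_index=True)

    pts = [FILLER_PT] + [config.pt_name(j + 1) for j in range(config.n_pts)]
    socs = [FILLER_SOC] + [f"SOC{(j % config.n_socs) + 1:02d}" for j in range(config.n_pts)]
    pt2soc = pd.DataFrame({"pt": pts, "soc": socs})

    synonyms = pd.DataFrame({
        "canonical": [config.target_drug] * len(config.target_variants),
        "variant": list(config.target_variants),
    })

    manifest = {
        "seed": int(config.seed),
        "n_reports": int(n),
        "n_target_reports": int(n_target),
        "n_duplicate_primaryids": int(n_dup),
        "target_drug": config.target_drug,
        "tto_shape": float(config.tto_shape),
        "tto_scale": float(config.tto_scale),
    }
    return SyntheticDatabase(demo=demo, drug=drug, reac=reac, outc=outc, ther=ther,
                             truth=truth, pt2soc=pt2soc, synonyms=synonyms,
                             manifest=manifest)


def write_database(db: SyntheticDatabase, outdir: str | Path) -> dict[str, Path]:
    """Write the five '$'-delimited ASCII tables plus truth/mapping sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in db.tables.items():
        p = outdir / f"{name}.txt"
        df.to_csv(p, sep="$", index=False)
        paths[name] = p
    db.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    db.pt2soc.to_csv(outdir / "pt2soc.tsv", sep="\t", index=False, header=False)
    db.synonyms.to_csv(outdir / "synonyms.tsv", sep="\t", index=False, header=False)
    (outdir / "manifest.json").write_text(json.dumps(db.manifest, indent=2) + "\n")
    paths["truth"] = outdir / "truth.tsv"
    paths["pt2soc"] = outdir / "pt2soc.tsv"
    paths["synonyms"] = outdir / "synonyms.tsv"
    return paths
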
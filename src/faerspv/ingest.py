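"""Reading, cleaning and deduplicating FAERS-dialect quarterly tables.

FAERS quarterly ASCII files are '$'-delimited with one header row.  This
module parses them into normalized pandas frames, applies the standard
case-level deduplication rule (per CASEID keep the submission with the
latest FDA_DT, ties broken by the higher PRIMARYID), standardizes verbatim
drug names against a synonym dictionary, and selects the target-drug case
set by drug role code.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParsedDate", "parse_date", "read_table", "read_tables", "normalize_reports",
    "deduplicate", "load_synonym_map", "standardize_drug", "select_target_reports",
]

MANDATORY_COLUMNS = {
    "DEMO": ["PRIMARYID", "CASEID", "FDA_DT"],
    "DRUG": ["PRIMARYID", "DRUGNAME", "ROLE_COD"],
    "REAC": ["PRIMARYID", "PT"],
    "OUTC": ["PRIMARYID", "OUTC_COD"],
    "THER": ["PRIMARYID", "START_DT"],
}

#: AGE_COD -> divisor converting to years (FAERS convention).
AGE_UNIT_TO_YEARS = {"YR": 1.0, "DEC": 0.1, "MON": 12.0, "WK": 52.18,
                     "DY": 365.25, "HR": 8766.0}


@dataclass(frozen=True)
class ParsedDate:
    """A FAERS date field: full YYYYMMDD, partial YYYYMM/YYYY, or missing."""

    kind: str                      # 'full' | 'partial' | 'missing'
    value: pd.Timestamp | None     # set only when kind == 'full'
    year: int | None = None
    month: int | None = None

    @property
    def is_full(self) -> bool:
        return self.kind == "full"


_MISSING = ParsedDate("missing", None)


def parse_date(s: object) -> ParsedDate:
    """Parse a FAERS date string.

    YYYYMMDD gives a full date; YYYYMM and YYYY are partial; anything else
    (including impossible calendar dates such as 20230230) is missing.
    """
    if s is None or (isinstance(s, float) and np.isnan(s)):
        return _MISSING
    s = str(s).strip()
    if not s.isdigit():
        return _MISSING
    if len(s) == 8:
        try:
            return ParsedDate("full", pd.Timestamp(f"{s[:4]}-{s[4:6]}-{s[6:]}"),
                              int(s[:4]), int(s[4:6]))
        except ValueError:
            logger.debug("impossible calendar date %r treated as missing", s)
            return _MISSING
    if len(s) == 6:
        if 1 <= int(s[4:6]) <= 12:
            return ParsedDate("partial", None, int(s[:4]), int(s[4:6]))
        return _MISSING
    if len(s) == 4:
        return ParsedDate("partial", None, int(s))
    return _MISSING


def _parse_date_column(col: pd.Series) -> pd.Series:
    """Vectorized full-date parse: YYYYMMDD -> Timestamp, else NaT."""
    s = col.astype(str).str.strip()
    ok = s.str.fullmatch(r"\d{8}")
    out = pd.to_datetime(s.where(ok), format="%Y%m%d", errors="coerce")
    return out


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one '$'-delimited table; column names are case-insensitive.

    Malformed rows (wrong field count) are skipped and counted in the log.
    Raises ``ValueError`` naming any absent mandatory column.
    """
    kind = kind.upper()
    if kind not in MANDATORY_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    skipped = []
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False,
                     engine="python", on_bad_lines=lambda row: skipped.append(row))
    if skipped:
        logger.warning("%s: skipped %d malformed rows", path, len(skipped))
    df.columns = [c.strip().upper() for c in df.columns]
    # Older quarters call the sex column GNDR_COD.
    if kind == "DEMO" and "SEX" not in df.columns and "GNDR_COD" in df.columns:
        df = df.rename(columns={"GNDR_COD": "SEX"})
    missing = [c for c in MANDATORY_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table {path}: missing mandatory column(s) {missing}")
    return df


def read_tables(paths: dict[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Read the DEMO/DRUG/REAC/OUTC/THER tables given a kind->path map."""
    return {kind.upper(): read_table(p, kind) for kind, p in paths.items()}


def _age_to_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    val = pd.to_numeric(age, errors="coerce")
    unit = age_cod.astype(str).str.strip().str.upper().replace("", "YR")
    div = unit.map(AGE_UNIT_TO_YEARS)
    years = val / div
    years[years >= 150] = np.nan
    years[years < 0] = np.nan
    return years


def normalize_reports(demo: pd.DataFrame) -> pd.DataFrame:
    """Normalize the DEMO table into typed report records.

    Adds ``fda_date`` (Timestamp or NaT), ``event_date`` (full dates only),
    ``sex`` in {M, F, unknown}, and ``age_years``.  The input frame is not
    modified.
    """
    out = demo.copy()
    out["PRIMARYID"] = pd.to_numeric(out["PRIMARYID"], errors="coerce").astype("Int64")
    out["fda_date"] = _parse_date_column(out["FDA_DT"])
    if "EVENT_DT" in out.columns:
        out["event_date"] = _parse_date_column(out["EVENT_DT"])
    if "SEX" in out.columns:
        sex = out["SEX"].astype(str).str.strip().str.upper()
        out["sex"] = sex.where(sex.isin(["M", "F"]), "unknown")
    else:
        out["sex"] = "unknown"
    if "AGE" in out.columns:
        out["age_years"] = _age_to_years(out["AGE"], out.get("AGE_COD", pd.Series("", index=out.index)))
    else:
        out["age_years"] = np.nan
    return out


def deduplicate(demo: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep one submission per CASEID: latest FDA_DT, then highest PRIMARYID.

    Submissions with an unparseable FDA_DT lose to any dated submission of
    the same case.  Returns the reduced frame and the number of rows
    removed.  Idempotent.
    """
    df = demo if "fda_date" in demo.columns else normalize_reports(demo)
    pid = pd.to_numeric(df["PRIMARYID"], errors="coerce")
    order = df.assign(_fda=df["fda_date"], _pid=pid).sort_values(
        ["_fda", "_pid"], na_position="first", kind="stable")
    keep = order.drop_duplicates("CASEID", keep="last").index
    removed = len(df) - len(keep)
    if removed:
        logger.info("deduplicate: removed %d duplicate submissions", removed)
    return df.loc[df.index.isin(keep)].copy(), removed


_norm_re = re.compile(r"[^a-z0-9 ]+")


def _normalize_name(name: str) -> str:
    s = _norm_re.sub(" ", str(name).lower())
    return " ".join(s.split())


def load_synonym_map(path: str | Path) -> dict[str, str]:
    """Load a canonical<TAB>variant synonym table into variant->canonical.

    A variant claimed by two different canonicals is an error.
    """
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        canonical, _, variant = line.partition("\t")
        canonical = canonical.strip()
        for key in (_normalize_name(variant), _normalize_name(canonical)):
            if not key:
                continue
            if key in mapping and mapping[key] != canonical:
                raise ValueError(
                    f"synonym conflict: {key!r} maps to both "
                    f"{mapping[key]!r} and {canonical!r}")
            mapping[key] = canonical
    return mapping


def standardize_drug(drug: pd.DataFrame, synonym_map: dict[str, str]) -> pd.DataFrame:
    """Attach a ``canonical_name`` column by normalized dictionary lookup.

    Matching is case-insensitive and whitespace/punctuation-collapsed;
    unmatched names get a null canonical and the row is retained.
    """
    out = drug.copy()
    normalized = out["DRUGNAME"].map(_normalize_name)
    out["canonical_name"] = normalized.map(synonym_map)
    n_match = out["canonical_name"].notna().sum()
    logger.info("standardize_drug: %d/%d entries matched", n_match, len(out))
    return out


def select_target_reports(drug: pd.DataFrame, canonical_drug: str,
                          roles: frozenset[str] | set[str] = frozenset({"PS"})) -> set[int]:
    """Primary IDs of reports listing the canonical drug in an accepted role.

    The default role set is primary suspect only; pass ``{"PS", "SS"}`` for
    a suspect-drug sensitivity analysis.  Expects ``standardize_drug``
    output and an already-deduplicated universe.
    """
    if "canonical_name" not in drug.columns:
        raise ValueError("run standardize_drug first")
    role = drug["ROLE_COD"].astype(str).str.strip().str.upper()
    mask = (drug["canonical_name"] == canonical_drug) & role.isin({r.upper() for r in roles})
    ids = set(pd.to_numeric(drug.loc[mask, "PRIMARYID"], errors="coerce").dropna().astype(np.int64))
    if not ids:
        logger.warning("select_target_reports: empty case set for %r", canonical_drug)
    return ids
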
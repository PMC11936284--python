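"""2x2 contingency tables per adverse-event term, with SOC rollup and sex strata.

The counting unit throughout is the drug-event *pair*: each distinct
(report, PT) combination contributes one pair.  For a given term the cells
are

    a  pairs from target-drug reports mentioning the term
    b  pairs from target-drug reports mentioning other terms
    c  pairs from comparator reports mentioning the term
    d  pairs from comparator reports mentioning other terms

so a+b is the same for every term (the case-set pair total) and the grand
total N is the pair count of the whole cleaned universe.  Pair-level
counting is the convention whose Woolf variances are compatible with
published confidence intervals at FAERS scale; report-level counting would
imply wider intervals for high-frequency terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["ContingencyTable", "load_pt2soc", "build_pt_tables", "rollup_soc",
           "stratify_by_sex", "tables_to_frame"]

UNMAPPED_SOC = "UNMAPPED"


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")
        if self.N < 1:
            raise ValueError("empty contingency table")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n1(self) -> int:
        """Target-drug margin a+b."""
        return self.a + self.b

    @property
    def n2(self) -> int:
        """Event margin a+c."""
        return self.a + self.c

    @property
    def expected(self) -> float:
        """Expected signal cell under independence, E = n1*n2/N."""
        return self.n1 * self.n2 / self.N


def load_pt2soc(path: str | Path) -> dict[str, str]:
    """Read a pt<TAB>soc mapping file (no header)."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        pt, _, soc = line.partition("\t")
        mapping[pt.strip()] = soc.strip()
    return mapping


def _unique_pairs(events: pd.DataFrame, term_col: str = "PT") -> pd.DataFrame:
    pairs = events[["PRIMARYID", term_col]].copy()
    pairs["PRIMARYID"] = pd.to_numeric(pairs["PRIMARYID"], errors="coerce").astype("Int64")
    pairs = pairs[pairs[term_col].astype(str).str.len() > 0]
    return pairs.drop_duplicates()


def build_pt_tables(events: pd.DataFrame, case_set: set[int],
                    term_col: str = "PT") -> dict[str, ContingencyTable]:
    """One 2x2 table per term over the whole pair universe.

    ``events`` holds the (PRIMARYID, term) occurrences of the *cleaned*
    universe — duplicate (report, term) rows are collapsed before counting.
    Terms absent from the case set still get a table (a = 0).
    """
    pairs = _unique_pairs(events, term_col)
    if pairs.empty:
        raise ValueError("event table is empty")
    in_case = pairs["PRIMARYID"].isin(case_set)
    n1 = int(in_case.sum())          # case-set pair total, constant across terms
    N = len(pairs)
    a_counts = pairs.loc[in_case, term_col].value_counts()
    ac_counts = pairs[term_col].value_counts()
    tables: dict[str, ContingencyTable] = {}
    for term, n2 in ac_counts.items():
        a = int(a_counts.get(term, 0))
        c = int(n2) - a
        tables[term] = ContingencyTable(a=a, b=n1 - a, c=c, d=N - n1 - c)
    return tables


def rollup_soc(events: pd.DataFrame, case_set: set[int],
               pt2soc: dict[str, str]) -> dict[str, ContingencyTable]:
    """SOC-level tables: a report with several PTs in one SOC counts once.

    PTs absent from the mapping fall into the ``UNMAPPED`` bucket.
    """
    ev = events[["PRIMARYID", "PT"]].copy()
    ev["SOC"] = ev["PT"].map(lambda pt: pt2soc.get(pt, UNMAPPED_SOC))
    return build_pt_tables(ev[["PRIMARYID", "SOC"]], case_set, term_col="SOC")


def stratify_by_sex(events: pd.DataFrame, demo: pd.DataFrame, sex: str,
                    case_set: set[int]) -> dict[str, ContingencyTable]:
    """Rebuild PT tables inside one sex stratum.

    Both the case set and the comparator background are restricted to
    reports of the given sex; unknown-sex reports drop out of both arms.
    """
    if sex not in {"M", "F"}:
        raise ValueError("sex stratum must be 'M' or 'F'")
    if "sex" not in demo.columns:
        raise ValueError("demo must be normalized (run normalize_reports)")
    ids = set(demo.loc[demo["sex"] == sex, "PRIMARYID"].dropna().astype("int64"))
    sub = events[pd.to_numeric(events["PRIMARYID"], errors="coerce").isin(ids)]
    stratum_cases = case_set & ids
    if not stratum_cases:
        import logging
        logging.getLogger(__name__).warning("sex stratum %s has no case pairs", sex)
        return {}
    return build_pt_tables(sub, stratum_cases)


def tables_to_frame(tables: dict[str, ContingencyTable]) -> pd.DataFrame:
    """Flatten a term->table map into a tidy frame (one row per term)."""
    rows = [{"term": t, "a": ct.a, "b": ct.b, "c": ct.c, "d": ct.d, "E": ct.expected}
            for t, ct in tables.items()]
    return pd.DataFrame(rows).sort_values("a", ascending=False, ignore_index=True)
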
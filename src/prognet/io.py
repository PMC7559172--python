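"""Readers and writers for study tables, scored edge lists, gene sets and gene lists.

The study table is a plain CSV with one row per published cohort.  The only
mandatory columns are ``hr``, ``ci_lower``, ``ci_upper`` and at least one
grouping column (``ethnicity``, ``specimen`` or ``n_patients``); all other
columns are optional metadata and are carried through untouched.

A curated table of eleven colorectal-cancer cohorts reporting overall-survival
hazard ratios for high miR-203 expression ships with the package and is the
canonical worked example (:func:`bundled_table1`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StudyRecord",
    "StudyTableError",
    "read_study_table",
    "write_study_table",
    "bundled_table1",
    "read_edge_list",
    "write_edge_list",
    "read_gene_sets",
    "write_gmt",
    "read_gene_list",
    "records_to_frame",
]

#: Columns every study table must provide.
MANDATORY_COLUMNS = ("hr", "ci_lower", "ci_upper")
#: At least one of these must be present to allow subgroup analysis.
GROUPING_COLUMNS = ("ethnicity", "specimen", "n_patients")


class StudyTableError(ValueError):
    """Raised for malformed study tables, edge lists or gene-set files."""


@dataclass
class StudyRecord:
    """One published cohort: survival effect estimate plus study metadata.

    ``hr`` is the hazard ratio comparing the high-expression to the
    low-expression group; ``ci_lower``/``ci_upper`` bound its confidence
    interval at level ``ci_level``.
    """

    study_id: str
    hr: float
    ci_lower: float
    ci_upper: float
    first_author: str | None = None
    year: int | None = None
    country: str | None = None
    ethnicity: str | None = None
    specimen: str | None = None
    n_patients: int | None = None
    males: int | None = None
    females: int | None = None
    median_age: float | None = None
    stage: str | None = None
    assay: str | None = None
    endogenous_control: str | None = None
    endpoint: str = "OS"
    followup_months: float | None = None
    ci_level: float = 0.95
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.ci_lower < self.ci_upper):
            raise StudyTableError(
                f"study {self.study_id!r}: CI bounds must satisfy "
                f"0 < lower < upper, got ({self.ci_lower}, {self.ci_upper})"
            )
        if not (self.ci_lower <= self.hr <= self.ci_upper):
            raise StudyTableError(
                f"study {self.study_id!r}: HR {self.hr} outside its CI "
                f"({self.ci_lower}, {self.ci_upper})"
            )
        if not (0 < self.ci_level < 1):
            raise StudyTableError(
                f"study {self.study_id!r}: ci_level must be in (0,1)"
            )
        if self.n_patients is not None and self.n_patients < 1:
            raise StudyTableError(f"study {self.study_id!r}: n_patients < 1")
        if (
            self.males is not None
            and self.females is not None
            and self.n_patients is not None
            and self.males + self.females > self.n_patients
        ):
            raise StudyTableError(
                f"study {self.study_id!r}: males + females exceeds n_patients"
            )

    @property
    def size_class(self) -> str | None:
        """'large' for n > 100, 'small' otherwise; None when N unknown."""
        if self.n_patients is None:
            return None
        return "large" if self.n_patients > 100 else "small"


_KNOWN = {
    "study_id", "first_author", "year", "country", "ethnicity", "specimen",
    "males", "females", "n_patients", "median_age", "stage", "assay",
    "endogenous_control", "endpoint", "followup_months", "hr", "ci_lower",
    "ci_upper", "ci_level",
}
_INT_FIELDS = {"year", "males", "females", "n_patients"}
_FLOAT_FIELDS = {"median_age", "followup_months", "hr", "ci_lower", "ci_upper", "ci_level"}


def _record_from_row(idx: int, row: pd.Series) -> StudyRecord:
    kwargs: dict = {}
    extra: dict = {}
    for col, val in row.items():
        if pd.isna(val) or (isinstance(val, str) and not val.strip()):
            continue
        if col in _KNOWN:
            if col in _INT_FIELDS:
                val = int(val)
            elif col in _FLOAT_FIELDS:
                val = float(val)
            kwargs[col] = val
        else:
            extra[col] = val
    kwargs.setdefault("study_id", f"study_{idx + 1}")
    try:
        return StudyRecord(extra=extra, **kwargs)
    except StudyTableError as err:
        raise StudyTableError(f"row {idx + 1}: {err}") from err


def read_study_table(path: str | Path) -> list[StudyRecord]:
    """Read a CSV study table, preserving row order and validating every row.

    Raises :class:`StudyTableError` naming the missing column when a mandatory
    column is absent, or carrying the 1-based data-row index when a row fails
    validation (e.g. inverted CI bounds).
    """
    df = pd.read_csv(path)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise StudyTableError(f"missing mandatory column {col!r}")
    if not any(c in df.columns for c in GROUPING_COLUMNS):
        raise StudyTableError(
            "study table needs at least one grouping column "
            f"(one of {', '.join(GROUPING_COLUMNS)})"
        )
    return [_record_from_row(i, row) for i, (_, row) in enumerate(df.iterrows())]


def records_to_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (extra columns appended)."""
    rows = []
    for rec in records:
        row = {k: getattr(rec, k) for k in _KNOWN}
        row.update(rec.extra)
        rows.append(row)
    return pd.DataFrame(rows)


def write_study_table(records: Sequence[StudyRecord], path: str | Path) -> None:
    """Write records back to CSV in the dialect :func:`read_study_table` reads."""
    df = records_to_frame(records)
    df = df.dropna(axis=1, how="all")
    df.to_csv(path, index=False)


def bundled_table1() -> list[StudyRecord]:
    """The packaged miR-203 / colorectal-cancer overall-survival study table.

    Eleven cohorts from seven publications (2008–2018): 7 Asian and 4
    non-Asian; 6 tissue and 5 serum specimens; 5 cohorts with more than 100
    patients.  Hazard ratios compare high versus low miR-203 expression for
    overall survival.
    """
    ref = resources.files("prognet.datasets") / "mir203_crc_os.csv"
    with resources.as_file(ref) as path:
        return read_study_table(path)


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a 2–3 column TSV edge list into an undirected scored graph.

    Duplicate node pairs are collapsed keeping the maximum score; self-loops
    are dropped with a logged warning.  Scores must lie in [0, 1]; a missing
    score column yields unscored edges.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise StudyTableError("edge list needs at least two columns")
    has_score = len(cols) >= 3
    graph = nx.Graph()
    for i, row in enumerate(df.itertuples(index=False)):
        a, b = str(row[0]).upper(), str(row[1]).upper()
        if a == b:
            logger.warning("dropping self-loop on %s (line %d)", a, i + 2)
            graph.add_node(a)
            continue
        if has_score:
            score = float(row[2])
            if not 0.0 <= score <= 1.0:
                raise StudyTableError(
                    f"line {i + 2}: score {score} outside [0, 1]"
                )
            if graph.has_edge(a, b):
                graph[a][b]["score"] = max(graph[a][b]["score"], score)
            else:
                graph.add_edge(a, b, score=score)
        else:
            graph.add_edge(a, b)
    return graph


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{term: gene set}`` (genes upper-cased, deduped).

    Each line is ``term<TAB>description<TAB>gene[<TAB>gene...]``; lines with
    fewer than three fields (i.e. zero genes) are format errors.
    """
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise StudyTableError(
                    f"GMT line {lineno}: expected term, description and "
                    f"at least one gene, got {len(fields)} fields"
                )
            term = fields[0]
            genes = {g.strip().upper() for g in fields[2:] if g.strip()}
            if not genes:
                raise StudyTableError(f"GMT line {lineno}: empty gene set")
            if term in collection:
                raise StudyTableError(f"GMT line {lineno}: duplicate term {term!r}")
            collection[term] = genes
    return collection


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a scored graph in the TSV dialect :func:`read_edge_list` reads."""
    rows = []
    for a, b, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        row = {"node_a": a, "node_b": b}
        if "score" in data:
            row["score"] = data["score"]
        rows.append(row)
    pd.DataFrame(rows, columns=["node_a", "node_b", "score"]).dropna(
        axis=1, how="all"
    ).to_csv(path, sep="\t", index=False)


def write_gmt(collection: dict[str, set[str]], path: str | Path) -> None:
    """Write gene sets in the GMT dialect :func:`read_gene_sets` reads."""
    with open(path, "w") as fh:
        for term in sorted(collection):
            genes = sorted(collection[term])
            fh.write("\t".join([term, "na", *genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a query gene list (one symbol per line), upper-cased, deduped."""
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            sym = line.strip().upper()
            if sym:
                seen.setdefault(sym, None)
    return list(seen)
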
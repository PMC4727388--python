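"""Packaged in-print tables: temperature-responsive genes and candidate regulators.

Two small tables ship with the package as TSV:

* the 41 candidate immediate temperature-responsive genes (Day 0 FPT →
  Day 3 MPT screen), including one transcript whose log2 fold change is
  infinite because it is undetected at Day 0;
* the 28 rows of candidate sexual-development genes with putative
  transcriptional regulatory function (25 unique genes across the
  per-interval comparisons, 9 of them transcription factors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "Table1Record",
    "Table2Record",
    "load_table1_fixture",
    "load_table2_fixture",
    "FixtureError",
]


class FixtureError(RuntimeError):
    """A packaged fixture file is missing or malformed."""


@dataclass(frozen=True)
class Table1Record:
    description: str
    accession: str
    log2fc: float          # may be math.inf (undetected at baseline)
    fdr: float
    direction: str         # "up" or "down"
    primary_ontology: str | None

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.log2fc)


@dataclass(frozen=True)
class Table2Record:
    comparison: str
    gene_id: str
    gene_symbol: str
    description: str
    molecule_type: str
    expression: str        # "Up" or "Down"
    timespan: str          # "Long", "Short" or "Ambiguous"


def _read_packaged_tsv(name: str):
    try:
        text = (resources.files("tsdnet") / "data" / name).read_text(encoding="utf-8")
    except (FileNotFoundError, OSError) as exc:
        raise FixtureError(f"packaged fixture {name!r} not found") from exc
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FixtureError(f"packaged fixture {name!r} is empty")
    header = lines[0].split("\t")
    rows = []
    for k, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise FixtureError(f"{name}: line {k} has {len(cells)} fields, expected {len(header)}")
        rows.append(dict(zip(header, cells)))
    return rows


def load_table1_fixture() -> list[Table1Record]:
    """The 41 candidate temperature-responsive genes (17 up, 24 down)."""
    records = []
    for row in _read_packaged_tsv("table1_temperature_responsive.tsv"):
        try:
            log2fc = float(row["log2fc"])  # "inf" parses to math.inf
            fdr = float(row["fdr"])
        except (KeyError, ValueError) as exc:
            raise FixtureError(f"malformed temperature-responsive record: {row}") from exc
        direction = row["direction"]
        if direction not in ("up", "down"):
            raise FixtureError(f"bad direction {direction!r}")
        if not 0 < fdr < 1:
            raise FixtureError(f"FDR {fdr} outside (0, 1)")
        if direction == "up" and not (log2fc > 0 or math.isinf(log2fc)):
            raise FixtureError(f"up record with log2fc {log2fc}")
        if direction == "down" and not log2fc < 0:
            raise FixtureError(f"down record with log2fc {log2fc}")
        ontology = row["primary_ontology"]
        records.append(
            Table1Record(
                description=row["description"],
                accession=row["accession"],
                log2fc=log2fc,
                fdr=fdr,
                direction=direction,
                primary_ontology=None if ontology == "N/A" else ontology,
            )
        )
    if len(records) != 41:
        raise FixtureError(f"expected 41 temperature-responsive records, got {len(records)}")
    return records


def load_table2_fixture() -> list[Table2Record]:
    """Candidate regulators per comparison; 25 unique gene symbols."""
    records = []
    for row in _read_packaged_tsv("table2_candidate_regulators.tsv"):
        if row["expression"] not in ("Up", "Down"):
            raise FixtureError(f"bad expression label {row['expression']!r}")
        if row["timespan"] not in ("Long", "Short", "Ambiguous"):
            raise FixtureError(f"bad timespan label {row['timespan']!r}")
        records.append(
            Table2Record(
                comparison=row["comparison"],
                gene_id=row["gene_id"],
                gene_symbol=row["gene_symbol"],
                description=row["description"],
                molecule_type=row["molecule_type"],
                expression=row["expression"],
                timespan=row["timespan"],
            )
        )
    symbols = {r.gene_symbol for r in records}
    if len(symbols) != 25:
        raise FixtureError(f"expected 25 unique gene symbols, got {len(symbols)}")
    return records
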
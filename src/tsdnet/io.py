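"""Readers and writers for the pipeline's tab-separated artifacts.

Dialects (all tab-separated, header line, floats at 6 significant
digits):

* expression matrix — first column ``gene_id``, remaining columns sample ids;
* sample sheet — ``sample_id, condition, day, replicate``;
* DEG table — ``gene_id, log2fc, p_raw, q_bh, significant, direction``
  with literal ``inf``/``-inf`` allowed in the fold-change column;
* screen members — ``gene_id, screen, direction, provenance``;
* network edge list — ``source, target, weight, type``;
* robustness report — ``source, target, kind, freq_noise, freq_prior,
  robust, high_robust``;
* model — JSON.

Every reader/writer pair round-trips valid artifacts exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .diffexpr import ComparisonSpec, DEGTable, Thresholds
from .grn import GRNModel
from .robustness import RobustnessReport
from .simulate import ExpressionMatrix

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_deg_table",
    "write_deg_table",
    "write_screen_result",
    "write_edge_list",
    "read_model",
    "write_model",
    "write_robustness_report",
    "ParseError",
]

_FLOAT_FMT = "%.6g"


class ParseError(ValueError):
    pass


def _check_header(path: Path, required, got):
    missing = [c for c in required if c not in got]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file, no header")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _check_header(Path(path), ["sample_id", "condition", "day", "replicate"], df.columns)
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample_id(s) {dupes}")
    bad = ~df["condition"].isin(["MPT", "FPT"])
    if bad.any():
        raise ParseError(f"{path}: bad condition value(s) {df.loc[bad, 'condition'].tolist()}")
    try:
        df["day"] = df["day"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer day or replicate: {exc}") from exc
    return df[["sample_id", "condition", "day", "replicate"]]


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_expression_matrix(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    df = _read_tsv(matrix_path)
    if df.columns[0] != "gene_id":
        raise ParseError(f"{matrix_path}: first column must be gene_id, got {df.columns[0]!r}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ParseError(f"{matrix_path}: duplicate gene_id(s) {dupes}")
    sample_cols = list(df.columns[1:])
    if len(set(sample_cols)) != len(sample_cols):
        raise ParseError(f"{matrix_path}: duplicate sample column names")
    values = df.set_index("gene_id")
    for col in sample_cols:
        converted = pd.to_numeric(values[col], errors="coerce")
        if converted.isna().any():
            row = values.index[converted.isna()][0]
            raise ParseError(
                f"{matrix_path}: non-numeric expression value at gene {row!r}, column {col!r}"
            )
        values[col] = converted
    samples = read_sample_sheet(sample_sheet_path)
    if set(samples["sample_id"]) != set(sample_cols):
        raise ParseError("sample sheet and matrix columns disagree")
    samples = samples.set_index("sample_id").loc[sample_cols].reset_index()
    return ExpressionMatrix(values=values, samples=samples)


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", float_format=_FLOAT_FMT)
    write_sample_sheet(matrix.samples, sample_sheet_path)


def write_deg_table(table: DEGTable, path) -> None:
    out = table.records.copy()
    out["significant"] = out["significant"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_deg_table(path, comparison: ComparisonSpec | None = None,
                   thresholds: Thresholds = Thresholds()) -> DEGTable:
    df = _read_tsv(path)
    _check_header(Path(path), ["gene_id", "log2fc", "p_raw", "q_bh", "significant", "direction"], df.columns)
    records = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "log2fc": df["log2fc"].astype(float),  # literal inf/-inf parse
            "p_raw": df["p_raw"].astype(float),
            "q_bh": df["q_bh"].astype(float),
            "significant": df["significant"].astype(int).astype(bool),
            "direction": df["direction"],
        }
    )
    comparison = comparison or ComparisonSpec(Path(path).stem, ("FPT", 0), ("MPT", 3))
    return DEGTable(comparison=comparison, records=records, thresholds=thresholds)


def write_screen_result(result, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)


def write_edge_list(model: GRNModel, path) -> None:
    """TSV edge list: gene→gene weights and input→gene weights."""
    rows = []
    n = len(model.genes)
    for i in range(n):
        for j in range(n):
            if i != j and model.A[i, j] != 0:
                rows.append((model.genes[j], model.genes[i], model.A[i, j], "gene"))
        if model.b[i] != 0:
            rows.append((model.input_name, model.genes[i], model.b[i], "input"))
    pd.DataFrame(rows, columns=["source", "target", "weight", "type"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_model(model: GRNModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def read_model(path) -> GRNModel:
    try:
        return GRNModel.from_dict(json.loads(Path(path).read_text()))
    except (json.JSONDecodeError, KeyError) as exc:
        raise ParseError(f"{path}: malformed model JSON: {exc}") from exc


def write_robustness_report(report: RobustnessReport, path, metadata_path=None,
                            metadata: dict | None = None) -> None:
    out = report.table.copy()
    out["robust"] = out["robust"].astype(int)
    out["high_robust"] = out["high_robust"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if metadata_path is not None:
        payload = {
            "robust_threshold": report.robust_threshold,
            "high_threshold": report.high_threshold,
        }
        payload.update(metadata or {})
        Path(metadata_path).write_text(json.dumps(payload, indent=2))
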
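"""Fixed-dialect table I/O and schema/invariant validation.

All pipeline tables are TSV: header row, UTF-8, ``.`` decimal separator,
``NA`` for missing.  Histograms are long-format CSV (``seed_id, channel,
count``).  Validation reports carry file, row and column locations so a
failing run can be fixed at the source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "ValidationError",
    "ValidationReport",
    "read_table",
    "write_table",
    "validate_ovules",
    "validate_seeds",
    "validate_env",
    "validate_tables",
    "OVULE_COLUMNS",
    "SEED_COLUMNS",
]

NA_TOKEN = "NA"

OVULE_COLUMNS = [
    "population_id", "individual_id", "season",
    "n_mes_only", "n_aes_only", "n_mixed", "n_multi_aes", "n_aborted",
]
SEED_COLUMNS = [
    "population_id", "individual_id", "season",
    "n_sexual", "n_apomictic", "n_biii", "n_unclassified",
]


@dataclass(frozen=True)
class ValidationError:
    file: str
    row: int | None  # 0-based data row; None for file-level problems
    column: str | None
    message: str

    def __str__(self) -> str:
        loc = self.file
        if self.row is not None:
            loc += f":row {self.row}"
        if self.column:
            loc += f":{self.column}"
        return f"{loc}: {self.message}"


@dataclass
class ValidationReport:
    errors: list[ValidationError] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, file: str, row: int | None, column: str | None, message: str) -> None:
        self.errors.append(ValidationError(file, row, column, message))

    def __str__(self) -> str:
        if self.ok:
            return "all tables valid"
        return "\n".join(str(e) for e in self.errors)


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, na_values=[NA_TOKEN], keep_default_na=False)


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, na_rep=NA_TOKEN)


def _check_counts(
    df: pd.DataFrame, cols: Iterable[str], report: ValidationReport, fname: str
) -> None:
    for col in cols:
        if col not in df.columns:
            report.add(fname, None, col, "missing required column")
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[numeric.isna() & df[col].notna()]:
            report.add(fname, int(i), col, f"not a number: {df[col][i]!r}")
        for i in df.index[numeric < 0]:
            report.add(fname, int(i), col, f"negative count: {numeric[i]}")
        frac = numeric.dropna() % 1
        for i in frac.index[frac != 0]:
            report.add(fname, int(i), col, f"non-integer count: {numeric[i]}")


def validate_ovules(df: pd.DataFrame, fname: str = "ovules.tsv") -> ValidationReport:
    report = ValidationReport()
    count_cols = ["n_mes_only", "n_aes_only", "n_mixed", "n_multi_aes", "n_aborted"]
    _check_counts(df, count_cols, report, fname)
    if not report.ok:
        return report
    for i, r in df.iterrows():
        if r["n_multi_aes"] > r["n_aes_only"] + r["n_mixed"]:
            report.add(
                fname, int(i), "n_multi_aes",
                "exceeds number of AES-bearing ovules (n_aes_only + n_mixed)",
            )
        if r["n_mes_only"] + r["n_aes_only"] + r["n_mixed"] + r["n_aborted"] < 1:
            report.add(fname, int(i), None, "row has zero ovules")
    return report


def validate_seeds(df: pd.DataFrame, fname: str = "seeds.tsv") -> ValidationReport:
    report = ValidationReport()
    _check_counts(df, ["n_sexual", "n_apomictic", "n_biii", "n_unclassified"], report, fname)
    return report


def validate_env(df: pd.DataFrame, fname: str = "env.tsv") -> ValidationReport:
    report = ValidationReport()
    if "population_id" not in df.columns:
        report.add(fname, None, "population_id", "missing required column")
        return report
    dupes = df["population_id"][df["population_id"].duplicated()]
    for i in dupes.index:
        report.add(fname, int(i), "population_id", f"duplicated id {df['population_id'][i]!r}")
    if "mdr" in df.columns:
        for i in df.index[pd.to_numeric(df["mdr"], errors="coerce") <= 0]:
            report.add(fname, int(i), "mdr", "mean diurnal range must be positive")
    return report


_VALIDATORS = {
    "ovules": validate_ovules,
    "seeds": validate_seeds,
    "env": validate_env,
}


def validate_tables(paths: dict[str, str | Path]) -> ValidationReport:
    """Validate a set of tables keyed by kind (``ovules``, ``seeds``, ``env``)."""
    report = ValidationReport()
    for kind, path in paths.items():
        if kind not in _VALIDATORS:
            report.add(str(path), None, None, f"unknown table kind {kind!r}")
            continue
        path = Path(path)
        if not path.exists():
            report.add(str(path), None, None, "file not found")
            continue
        try:
            df = read_table(path)
        except Exception as exc:  # malformed delimiter etc.
            report.add(str(path), None, None, f"unreadable: {exc}")
            continue
        sub = _VALIDATORS[kind](df, fname=str(path))
        report.errors.extend(sub.errors)
    return report
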
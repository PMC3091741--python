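"""Reading, validation and writing of the pipeline's tab-delimited tables.

The pipeline consumes three inputs:

* an expression matrix (probes x arrays, non-negative intensities),
* a sample design table mapping each array to a (timepoint, treatment,
  replicate) cell of the 2x2 denervation study, and
* a probe annotation table mapping probe IDs to gene symbols.

All files are UTF-8 TSV; lines starting with ``#`` are comments.  Results are
written back as headered TSV (floats at full precision so a write/read
round-trip is exact).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

VEHICLE = "vehicle"
NANDROLONE = "nandrolone"
TREATMENT_LEVELS = (VEHICLE, NANDROLONE)
TIMEPOINT_LEVELS = (7, 35)

#: float format used for every table we write; 17 significant digits makes the
#: text round-trip bit-exact for IEEE doubles.
FLOAT_FORMAT = "%.17g"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe x array intensity matrix with validated, ordered identifiers."""

    frame: pd.DataFrame  # index: probe IDs, columns: array IDs, dtype float

    def __post_init__(self) -> None:
        f = self.frame
        if f.shape[0] == 0 or f.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        for axis, what in ((f.index, "probe"), (f.columns, "array")):
            dup = axis[axis.duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate {what} ID {dup[0]!r}")
        values = f.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric data")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise ValidationError("expression matrix contains negative values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix with the same labels and replaced values."""
        return ExpressionMatrix(
            pd.DataFrame(values, index=self.frame.index, columns=self.frame.columns)
        )

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        missing = [p for p in probe_ids if p not in self.frame.index]
        if missing:
            raise ValidationError(f"probes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.frame.loc[list(probe_ids)])


@dataclass(frozen=True)
class SampleDesign:
    """Array -> (timepoint, treatment, replicate) assignment for the 2x2 study."""

    table: pd.DataFrame  # columns: array_id, timepoint, treatment, replicate

    def __post_init__(self) -> None:
        t = self.table
        required = ["array_id", "timepoint", "treatment", "replicate"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"design table missing columns {missing}")
        dup = t.loc[t["array_id"].duplicated(), "array_id"]
        if len(dup):
            raise ValidationError(f"array {dup.iloc[0]!r} listed twice in design")
        bad_tr = sorted(set(t["treatment"]) - set(TREATMENT_LEVELS))
        if bad_tr:
            raise ValidationError(
                f"unknown treatment level(s) {bad_tr}; expected {TREATMENT_LEVELS}"
            )
        if (t["replicate"] < 1).any():
            raise ValidationError("replicate indices must be positive")

    @property
    def array_ids(self) -> list[str]:
        return list(self.table["array_id"])

    def arrays_for(self, timepoint: int, treatment: str) -> list[str]:
        t = self.table
        sel = (t["timepoint"] == timepoint) & (t["treatment"] == treatment)
        return list(t.loc[sel, "array_id"])

    def groups(self) -> dict[tuple[int, str], list[str]]:
        out: dict[tuple[int, str], list[str]] = {}
        for (tp, tr), sub in self.table.groupby(["timepoint", "treatment"], sort=True):
            out[(int(tp), str(tr))] = list(sub["array_id"])
        return out

    def check_against(self, matrix: ExpressionMatrix) -> list[str]:
        """Cross-check design vs matrix.

        Arrays present in the matrix but absent from the design are an error;
        design rows without a matrix column are tolerated and returned as
        warnings (the design may describe a superset study).
        """
        design_arrays = set(self.array_ids)
        matrix_arrays = set(matrix.array_ids)
        orphans = sorted(matrix_arrays - design_arrays)
        if orphans:
            raise ValidationError(
                f"matrix array(s) missing from design: {orphans}"
            )
        return [f"design array {a!r} not present in matrix"
                for a in sorted(design_arrays - matrix_arrays)]


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe ID -> gene symbol map; symbols are upper-cased for identity."""

    table: pd.DataFrame = field()  # columns: probe_id, gene_symbol, known_gene

    def __post_init__(self) -> None:
        t = self.table
        for col in ("probe_id", "gene_symbol"):
            if col not in t.columns:
                raise ValidationError(f"annotation table missing column {col!r}")
        dup = t.loc[t["probe_id"].duplicated(), "probe_id"]
        if len(dup):
            raise ValidationError(
                f"probe {dup.iloc[0]!r} annotated more than once"
            )

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "ProbeAnnotation":
        rows = pd.DataFrame(
            {"probe_id": list(mapping), "gene_symbol": list(mapping.values())}
        )
        return cls(_finalize_annotation(rows))

    @property
    def n_known(self) -> int:
        return int(self.table["known_gene"].sum())

    def symbol_of(self) -> pd.Series:
        """Series probe_id -> upper-cased symbol (known genes only)."""
        t = self.table
        known = t[t["known_gene"]]
        return pd.Series(known["gene_symbol"].values, index=known["probe_id"].values)


def _finalize_annotation(rows: pd.DataFrame) -> pd.DataFrame:
    sym = rows["gene_symbol"].fillna("").astype(str).str.strip().str.upper()
    rows = rows.assign(gene_symbol=sym, known_gene=sym != "")
    return rows.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", encoding="utf-8", **kw)


def _first_data_line(path) -> str | None:
    if hasattr(path, "read"):  # file-like: skip the raw header check
        return None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#") and line.strip():
                return line
    return None


def read_expression_matrix(path) -> ExpressionMatrix:
    """Parse a probes x arrays TSV: first row array IDs, first column probe IDs.

    Non-numeric cells raise :class:`ValidationError` naming the offending
    probe/array coordinates; duplicate identifiers raise with the duplicate
    named.
    """
    # pandas silently renames duplicate header fields, so check them raw first
    header = _first_data_line(path)
    if header is not None:
        names = header.rstrip("\n").split("\t")[1:]
        seen: set[str] = set()
        for name in names:
            if name in seen:
                raise ValidationError(f"{path}: duplicate array ID {name!r}")
            seen.add(name)
    raw = _read_tsv(path, index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValidationError(f"{path}: empty expression matrix")
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell {raw.iloc[r, c]!r} at probe "
            f"{raw.index[r]!r}, array {raw.columns[c]!r}"
        )
    # re-parse through float() (correctly-rounded strtod) so that write/read
    # round-trips are bit-exact; pd.to_numeric above only locates bad cells
    exact = np.vectorize(float, otypes=[np.float64])(raw.to_numpy())
    return ExpressionMatrix(
        pd.DataFrame(exact, index=raw.index, columns=raw.columns)
    )


def read_design(path, matrix: ExpressionMatrix | None = None) -> SampleDesign:
    """Read the array design TSV; optionally cross-check against a matrix."""
    t = _read_tsv(path, dtype={"array_id": str, "treatment": str})
    try:
        t["timepoint"] = t["timepoint"].astype(int)
        t["replicate"] = t["replicate"].astype(int)
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"{path}: bad design table: {exc}") from exc
    design = SampleDesign(t)
    if matrix is not None:
        design.check_against(matrix)
    return design


def read_annotation(path) -> ProbeAnnotation:
    """Read the probe annotation TSV (columns probe_id, gene_symbol)."""
    t = _read_tsv(path, dtype=str)
    if "probe_id" not in t.columns or "gene_symbol" not in t.columns:
        raise ValidationError(
            f"{path}: annotation needs columns probe_id, gene_symbol"
        )
    return ProbeAnnotation(_finalize_annotation(t[["probe_id", "gene_symbol"]].copy()))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                        index_label="probe_id")


def write_table(frame: pd.DataFrame, path, index: bool = True,
                index_label: str | None = None) -> None:
    """Write any result table as headered TSV at full float precision."""
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index,
                 index_label=index_label)


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def write_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.table[["probe_id", "gene_symbol"]].to_csv(path, sep="\t", index=False)


def matrix_to_tsv_string(matrix: ExpressionMatrix) -> str:
    buf = io.StringIO()
    write_expression_matrix(matrix, buf)
    return buf.getvalue()
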
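"""Readers and writers for the tabular input formats.

All files are delimited text (CSV/TSV, UTF-8) with a header row and the
identifiers in the first column.  Binary tables accept ``0/1``,
``TRUE/FALSE`` and, when the dialect says so, blank cells as zero.
Assemblage rows are labelled ``<E|S>_<station>_<year>`` by default;
the pattern is configurable because deposited data dialects vary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    EXPOSED,
    SHELTERED,
    AssemblageKey,
    AssemblageSet,
    FormatError,
    PredatorPreyMatrix,
    PreyTraitMatrix,
    TraitScheme,
    ValidationError,
)

__all__ = [
    "TableDialect",
    "read_pp_matrix",
    "write_pp_matrix",
    "read_trait_matrix",
    "write_trait_matrix",
    "read_abundance_table",
    "write_abundance_table",
    "average_replicates",
    "parse_assemblage_label",
    "align_prey",
    "DEFAULT_LABEL_PATTERN",
]

logger = logging.getLogger(__name__)

#: groups: exposure code, station id, year
DEFAULT_LABEL_PATTERN = r"^(?P<exposure>[ES])_(?P<site>[^_]+)_(?P<year>\d{4})$"

_TRUTHY = {"1", "true", "t", "yes"}
_FALSY = {"0", "false", "f", "no"}


@dataclass(frozen=True)
class TableDialect:
    """Parsing options for delimited binary/abundance tables."""

    delimiter: str | None = None  # None = sniff from ',' '\t' ';'
    blank_is_zero: bool = True
    #: for feeding-link files: are predators stored as rows or columns?
    orientation: str = "predators_as_columns"


def _read_frame(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        head = path.open(encoding="utf-8").readline()
        delimiter = max(",\t;", key=head.count)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _to_binary(df: pd.DataFrame, blank_is_zero: bool, what: str) -> np.ndarray:
    out = np.empty(df.shape, dtype=np.int8)
    for i, (ridx, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            s = str(cell).strip().lower()
            if s == "":
                if not blank_is_zero:
                    raise FormatError(
                        f"{what}: blank cell at row {ridx!r}, column {df.columns[j]!r}"
                    )
                out[i, j] = 0
            elif s in _TRUTHY:
                out[i, j] = 1
            elif s in _FALSY:
                out[i, j] = 0
            else:
                raise FormatError(
                    f"{what}: non-binary cell {cell!r} at row {ridx!r}, "
                    f"column {df.columns[j]!r}"
                )
    return out


def read_pp_matrix(
    path: str | Path, dialect: TableDialect = TableDialect()
) -> PredatorPreyMatrix:
    """Read a binary predator-prey feeding-link table.

    Deposited link tables conventionally store predators as columns and
    prey as rows; ``dialect.orientation`` says which way the file is
    laid out, and the returned matrix is always predators-as-rows.
    """
    df = _read_frame(path, dialect.delimiter)
    links = _to_binary(df, dialect.blank_is_zero, "feeding links")
    if dialect.orientation == "predators_as_columns":
        return PredatorPreyMatrix(tuple(df.columns), tuple(df.index), links.T)
    if dialect.orientation == "predators_as_rows":
        return PredatorPreyMatrix(tuple(df.index), tuple(df.columns), links)
    raise FormatError(f"unknown orientation {dialect.orientation!r}")


def write_pp_matrix(
    pp: PredatorPreyMatrix, path: str | Path, dialect: TableDialect = TableDialect()
) -> None:
    df = pp.to_frame()
    if dialect.orientation == "predators_as_columns":
        df = df.T
    df.to_csv(path, sep=dialect.delimiter or ",")


def read_trait_matrix(
    path: str | Path, scheme: TraitScheme, dialect: TableDialect = TableDialect()
) -> PreyTraitMatrix:
    """Read a binary prey-by-category table and align columns to the scheme."""
    df = _read_frame(path, dialect.delimiter)
    norm = {re.sub(r"\s+", " ", c).strip(): c for c in df.columns}
    wanted = list(scheme.category_index)
    unknown = sorted(set(norm) - set(wanted))
    missing = sorted(set(wanted) - set(norm))
    if unknown or missing:
        raise FormatError(
            f"trait table columns do not match the scheme; "
            f"unmatched file columns: {unknown}; missing categories: {missing}"
        )
    df = df[[norm[c] for c in wanted]]
    values = _to_binary(df, dialect.blank_is_zero, "trait values")
    return PreyTraitMatrix(tuple(df.index), scheme, values)


def write_trait_matrix(
    tm: PreyTraitMatrix, path: str | Path, dialect: TableDialect = TableDialect()
) -> None:
    tm.to_frame().to_csv(path, sep=dialect.delimiter or ",")


def parse_assemblage_label(label: str, pattern: str = DEFAULT_LABEL_PATTERN) -> AssemblageKey:
    """Parse a site label like ``E_03_2000`` into an assemblage key."""
    m = re.match(pattern, label.strip())
    if m is None:
        raise FormatError(f"assemblage label {label!r} does not match pattern {pattern!r}")
    exposure = EXPOSED if m.group("exposure").upper() == "E" else SHELTERED
    return AssemblageKey(site=m.group("site"), year=int(m.group("year")), exposure=exposure)


def read_abundance_table(
    path: str | Path,
    label_pattern: str = DEFAULT_LABEL_PATTERN,
    dialect: TableDialect = TableDialect(),
    allow_empty: bool = False,
) -> AssemblageSet:
    """Read a sites-by-prey abundance table with parseable row labels."""
    df = _read_frame(path, dialect.delimiter)
    keys = tuple(parse_assemblage_label(lbl, label_pattern) for lbl in df.index)
    try:
        ab = df.replace("", "0").astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance cell: {exc}") from exc
    if (ab < 0).any():
        r, c = np.argwhere(ab < 0)[0]
        raise FormatError(
            f"negative abundance {ab[r, c]} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return AssemblageSet(keys, tuple(df.columns), ab, allow_empty=allow_empty)


def write_abundance_table(ab: AssemblageSet, path: str | Path) -> None:
    ab.to_frame().to_csv(path)


def average_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Average replicate rows sharing an index label (e.g. 5 grab samples)."""
    return df.astype(float).groupby(level=0, sort=False).mean()


def align_prey(
    pp: PredatorPreyMatrix,
    tm: PreyTraitMatrix,
    ab: AssemblageSet,
    policy: str = "strict",
) -> tuple[PredatorPreyMatrix, PreyTraitMatrix, AssemblageSet, list[str]]:
    """Reconcile the prey lists of the three input tables.

    ``strict`` demands that the trait matrix cover every prey appearing
    in the link and abundance tables; ``intersect`` restricts all three
    to the common prey and reports what was dropped.

    Returns the aligned triple plus the sorted list of dropped prey
    identifiers (empty under ``strict``).
    """
    if policy not in ("strict", "intersect"):
        raise ValueError(f"unknown alignment policy {policy!r}")
    sets = {"links": set(pp.prey), "traits": set(tm.prey), "abundance": set(ab.prey)}
    if policy == "strict":
        uncovered = sorted((sets["links"] | sets["abundance"]) - sets["traits"])
        if uncovered:
            raise ValidationError(
                f"prey without trait classification under strict alignment: {uncovered}"
            )
        common = sets["traits"] & sets["links"] & sets["abundance"]
        if sets["links"] != sets["abundance"] or sets["links"] != sets["traits"]:
            raise ValidationError(
                "prey lists differ between tables under strict alignment; "
                "use policy='intersect' to restrict to the "
                f"{len(common)} common prey"
            )
        return pp, tm, ab, []
    common = sets["links"] & sets["traits"] & sets["abundance"]
    if not common:
        raise ValidationError("no prey shared by all three tables")
    dropped = sorted((sets["links"] | sets["traits"] | sets["abundance"]) - common)
    if dropped:
        logger.info("align_prey dropped %d prey: %s", len(dropped), dropped)
    keep = [p for p in tm.prey if p in common]
    return (
        pp.restrict_prey(keep),
        tm.restrict_prey(keep),
        ab.restrict_prey(keep),
        dropped,
    )
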
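"""Wide-format subject-by-variable data handling.

One row per subject, one column per manifest variable, columns ordered by
fixed situation, then occasion, then method, then indicator. Missing cells are
allowed and tracked in a boolean mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSpec, manifest_layout

__all__ = [
    "WideDataset",
    "load_wide_csv",
    "write_wide_csv",
    "validate_dataset",
    "ValidationReport",
    "DEFAULT_NA_TOKENS",
]

DEFAULT_NA_TOKENS = frozenset({"NA", "", "NaN", "nan"})


class LayoutError(ValueError):
    """Column layout does not match the declared design."""


class DataParseError(ValueError):
    """A cell could not be interpreted as numeric or missing."""


@dataclass
class WideDataset:
    """Numeric wide-format data with a missingness mask.

    ``values`` is an ``n_subjects x p`` float array with NaN at missing cells;
    ``missing_mask`` is True where missing. ``column_map`` maps 1-based
    ``(i, m, t, s)`` tuples to column positions.
    """

    values: np.ndarray
    design: DesignSpec
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise LayoutError("values must be a 2-d array")
        if self.values.shape[1] != self.design.n_manifest:
            raise LayoutError(
                f"data has {self.values.shape[1]} columns but the design "
                f"implies {self.design.n_manifest}"
            )
        if not self.column_names:
            self.column_names = self.design.variable_names()
        if len(self.column_names) != self.values.shape[1]:
            raise LayoutError("column_names length does not match data")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def column_map(self) -> dict[tuple[int, int, int, int], int]:
        return {imts: j for j, imts in enumerate(manifest_layout(self.design))}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)

    def complete_cases(self) -> np.ndarray:
        """Rows with no missing cell."""
        return self.values[~self.missing_mask.any(axis=1)]


def load_wide_csv(
    path: str | Path,
    design: DesignSpec,
    na_tokens: frozenset[str] | set[str] = DEFAULT_NA_TOKENS,
) -> WideDataset:
    """Read a headered CSV of wide-format data against a design.

    User headers are preserved and mapped positionally; the column count must
    equal ``design.n_manifest``. Cells matching ``na_tokens`` (after
    stripping) become missing; any other non-numeric cell raises
    :class:`DataParseError` naming the row and column.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.shape[1] != design.n_manifest:
        raise LayoutError(
            f"{path.name}: found {frame.shape[1]} columns, expected "
            f"{design.n_manifest} for design "
            f"(I={design.n_indicators}, M={design.n_methods}, "
            f"T={design.n_occasions}, S={design.n_situations})"
        )
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for j, col in enumerate(frame.columns):
        for r in range(frame.shape[0]):
            cell = raw[r, j].strip()
            if cell in na_tokens:
                values[r, j] = np.nan
                continue
            try:
                values[r, j] = float(cell)
            except ValueError as exc:
                raise DataParseError(
                    f"{path.name}: non-numeric value {cell!r} at row "
                    f"{r + 2} (1-based, incl. header), column {col!r}"
                ) from exc
    return WideDataset(values, design, column_names=list(frame.columns))


def write_wide_csv(
    dataset: WideDataset, path: str | Path, na_token: str = "NA"
) -> None:
    """Write a dataset to CSV, encoding missing cells as ``na_token``."""
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, na_rep=na_token)


@dataclass
class ValidationReport:
    """Report-only description of data quality issues."""

    n_subjects: int
    missing_rate_per_column: dict[str, float]
    all_missing_columns: list[str]
    zero_variance_columns: list[str]
    empty_subjects: list[int]

    @property
    def issues(self) -> list[str]:
        out: list[str] = []
        for c in self.all_missing_columns:
            out.append(f"column {c!r} has no observed values")
        for c in self.zero_variance_columns:
            out.append(f"column {c!r} has zero variance")
        if self.empty_subjects:
            out.append(
                f"{len(self.empty_subjects)} subject(s) with no observations: "
                f"rows {self.empty_subjects[:10]}"
            )
        return out


def validate_dataset(dataset: WideDataset, design: DesignSpec) -> ValidationReport:
    """Check a dataset against its design and summarise problems.

    Flags all-missing columns, zero-variance columns (among observed values)
    and subjects with no observed cells; reports per-column missing rates.
    """
    if dataset.values.shape[1] != design.n_manifest:
        raise LayoutError(
            f"dataset has {dataset.values.shape[1]} columns, design implies "
            f"{design.n_manifest}"
        )
    mask = dataset.missing_mask
    rates = mask.mean(axis=0)
    all_missing = mask.all(axis=0)
    zero_var: list[str] = []
    for j, name in enumerate(dataset.column_names):
        if all_missing[j]:
            continue
        observed = dataset.values[~mask[:, j], j]
        if observed.size and np.nanstd(observed) == 0.0:
            zero_var.append(name)
    empty_rows = np.nonzero(mask.all(axis=1))[0].tolist()
    return ValidationReport(
        n_subjects=dataset.n_subjects,
        missing_rate_per_column={
            name: float(rates[j]) for j, name in enumerate(dataset.column_names)
        },
        all_missing_columns=[
            dataset.column_names[j] for j in np.nonzero(all_missing)[0]
        ],
        zero_variance_columns=zero_var,
        empty_subjects=empty_rows,
    )
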
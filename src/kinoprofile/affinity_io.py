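"""Target x inhibitor affinity matrices and the censored binding-energy transform.

Affinities are dissociation constants (Kd) or estimated IC50 values in nM,
arranged as a matrix of *t* targets (rows) by *n* inhibitors (columns).
Single-point profiling assays report values above their upper measurement
limit (typically 10 µM) only as censored ("> limit") observations; those
cells carry a censor flag instead of a number.

The binding-energy transform maps each affinity x (nM) to log10(x), which is
proportional to the binding free energy, and fixes every censored cell at a
uniform ceiling (default 5.0, i.e. 100 µM) so that censored interactions
enter downstream correlation and PCA analyses as uniformly weak binders.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AffinityMatrix",
    "BindingEnergyMatrix",
    "PotencyThreshold",
    "read_affinity_table",
    "write_affinity_table",
    "to_binding_energy",
    "potent_set",
]

#: accepted censoring token, e.g. ">10000" or "> 10000.0"
CENSOR_TOKEN_RE = re.compile(r"^>\s*(\d+(?:\.\d+)?)$")


class AffinityParseError(ValueError):
    """Raised when an affinity table cell cannot be interpreted."""


@dataclass
class AffinityMatrix:
    """Affinities in nM for t targets x n inhibitors.

    ``values`` holds NaN where a cell is absent or censored; ``censored``
    flags cells reported above the assay limit.  Both frames share the same
    (target, inhibitor) axes.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    limit_nM: float = 10000.0

    def __post_init__(self) -> None:
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("affinity matrix must have at least 1 target and 1 inhibitor")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate target ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate inhibitor ids")
        if not (self.values.index.equals(self.censored.index)
                and self.values.columns.equals(self.censored.columns)):
            raise ValueError("values and censored must share axes")
        if self.limit_nM <= 0:
            raise ValueError("limit_nM must be positive")
        vals = self.values.to_numpy(dtype=float)
        cens = self.censored.to_numpy(dtype=bool)
        measured = ~cens & np.isfinite(vals)
        if (vals[measured] <= 0).any():
            raise ValueError("non-censored affinities must be positive")

    @property
    def target_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def inhibitor_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def present(self) -> pd.DataFrame:
        """Boolean mask of cells with an observation (measured or censored)."""
        return self.values.notna() | self.censored

    def equals(self, other: "AffinityMatrix") -> bool:
        same_vals = self.values.fillna(-1.0).equals(other.values.fillna(-1.0))
        return (same_vals and self.censored.equals(other.censored)
                and self.limit_nM == other.limit_nM)


@dataclass
class BindingEnergyMatrix:
    """log10(nM) binding-energy equivalents with censored cells at ``ceiling``."""

    values: pd.DataFrame
    ceiling: float = 5.0
    censored: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals[~np.isnan(vals)]).all():
            raise ValueError("binding energies must be finite")
        cens = self.censored.to_numpy(dtype=bool)
        if cens.any() and not np.allclose(vals[cens], self.ceiling):
            raise ValueError("censored-origin values must equal the ceiling")

    @property
    def target_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def inhibitor_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class PotencyThreshold:
    """Strict potency cut-off: an inhibitor is potent below ``threshold_nM``."""

    threshold_nM: float = 150.0

    def __post_init__(self) -> None:
        if self.threshold_nM <= 0:
            raise ValueError("threshold_nM must be positive")


def _parse_cell(raw, row_label, col_label, limits: set[float]):
    """Return (value, censored) for one table cell; collect censor limits."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return np.nan, False
    text = str(raw).strip()
    if text == "" or text.lower() in {"nan", "na"}:
        return np.nan, False
    m = CENSOR_TOKEN_RE.match(text)
    if m:
        limits.add(float(m.group(1)))
        return np.nan, True
    try:
        value = float(text)
    except ValueError:
        raise AffinityParseError(
            f"malformed affinity value {text!r} at target {row_label!r}, "
            f"inhibitor {col_label!r}"
        ) from None
    if value <= 0:
        raise AffinityParseError(
            f"non-positive affinity {value} at target {row_label!r}, "
            f"inhibitor {col_label!r}"
        )
    return value, False


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_affinity_table(path, format: str = "wide") -> AffinityMatrix:
    """Read a wide or long affinity table (CSV/TSV) into an :class:`AffinityMatrix`.

    Wide: header row of inhibitor ids, first column target ids.  Long: three
    columns (target, inhibitor, value).  Cells are positive numbers, censor
    tokens like ``>10000``, or empty (absent).
    """
    path = Path(path)
    sep = _sep_for(path)
    limits: set[float] = set()
    if format == "wide":
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
        targets = [str(t) for t in raw.index]
        inhibitors = [str(c) for c in raw.columns]
        if len(set(targets)) != len(targets):
            raise AffinityParseError("duplicate target ids in wide table")
        values = pd.DataFrame(np.nan, index=targets, columns=inhibitors)
        censored = pd.DataFrame(False, index=targets, columns=inhibitors)
        for t, (_, row) in zip(targets, raw.iterrows()):
            for i, raw_cell in zip(inhibitors, row):
                v, c = _parse_cell(raw_cell, t, i, limits)
                values.at[t, i] = v
                censored.at[t, i] = c
    elif format == "long":
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        if raw.shape[1] < 3:
            raise AffinityParseError("long table needs (target, inhibitor, value) columns")
        tcol, icol, vcol = raw.columns[:3]
        pairs = list(zip(raw[tcol], raw[icol]))
        dup = pd.Series(pairs).duplicated()
        if dup.any():
            raise AffinityParseError(f"duplicate (target, inhibitor) pair {pairs[dup.idxmax()]}")
        targets = list(dict.fromkeys(raw[tcol]))
        inhibitors = list(dict.fromkeys(raw[icol]))
        values = pd.DataFrame(np.nan, index=targets, columns=inhibitors)
        censored = pd.DataFrame(False, index=targets, columns=inhibitors)
        for t, i, raw_cell in zip(raw[tcol], raw[icol], raw[vcol]):
            v, c = _parse_cell(raw_cell, t, i, limits)
            values.at[t, i] = v
            censored.at[t, i] = c
    else:
        raise ValueError(f"unknown format {format!r}; use 'wide' or 'long'")
    if len(limits) > 1:
        raise AffinityParseError(f"inconsistent censor limits in table: {sorted(limits)}")
    limit = limits.pop() if limits else 10000.0
    return AffinityMatrix(values=values, censored=censored, limit_nM=limit)


def write_affinity_table(m: AffinityMatrix, path, format: str = "wide") -> None:
    """Write an affinity matrix back to CSV/TSV in the dialect of :func:`read_affinity_table`."""
    path = Path(path)
    sep = _sep_for(path)
    token = f">{m.limit_nM:g}"

    def fmt(t, i):
        if m.censored.at[t, i]:
            return token
        v = m.values.at[t, i]
        return "" if pd.isna(v) else repr(float(v))  # shortest round-trip repr

    if format == "wide":
        out = pd.DataFrame(
            [[fmt(t, i) for i in m.inhibitor_ids] for t in m.target_ids],
            index=m.target_ids, columns=m.inhibitor_ids,
        )
        out.index.name = "target"
        out.to_csv(path, sep=sep)
    elif format == "long":
        rows = [
            (t, i, fmt(t, i))
            for t in m.target_ids for i in m.inhibitor_ids
            if m.censored.at[t, i] or not pd.isna(m.values.at[t, i])
        ]
        pd.DataFrame(rows, columns=["target", "inhibitor", "value"]).to_csv(
            path, sep=sep, index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def to_binding_energy(m: AffinityMatrix, ceiling: float = 5.0) -> BindingEnergyMatrix:
    """Map affinities to log10(nM) binding-energy equivalents.

    Measured x nM -> log10(x); censored cells -> ``ceiling`` uniformly
    (default 5.0 = 100 µM); absent cells stay absent.
    """
    if ceiling < math.log10(m.limit_nM):
        raise ValueError(
            f"ceiling {ceiling} is below log10(limit) = {math.log10(m.limit_nM):.3f}"
        )
    vals = m.values.to_numpy(dtype=float)
    cens = m.censored.to_numpy(dtype=bool)
    out = np.full(vals.shape, np.nan)
    measured = ~cens & np.isfinite(vals)
    out[measured] = np.log10(vals[measured])
    out[cens] = ceiling
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return BindingEnergyMatrix(values=values, ceiling=ceiling, censored=m.censored.copy())


def potent_set(m: AffinityMatrix, target: str, thr: PotencyThreshold | None = None) -> set[str]:
    """Inhibitors with a measured affinity strictly below the potency threshold.

    Censored and absent cells are never potent; the boundary value itself
    (e.g. exactly 150 nM) is not potent.
    """
    thr = thr or PotencyThreshold()
    if target not in m.values.index:
        raise KeyError(f"unknown target {target!r}")
    row = m.values.loc[target]
    cens = m.censored.loc[target]
    mask = row.notna() & ~cens & (row < thr.threshold_nM)
    return set(row.index[mask])
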
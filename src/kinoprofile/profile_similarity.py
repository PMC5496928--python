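"""Pearson correlation of censored binding-energy profiles; kinome disk plots.

Target similarity is the Pearson correlation coefficient between two
targets' vectors of log10(nM) binding-energy equivalents across the
inhibitor panel, with censored cells participating at the uniform ceiling.
Profiles are rendered on a kinome layout as disks whose hue and radius
encode the correlation with a chosen reference kinase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import to_rgb

from .affinity_io import BindingEnergyMatrix

__all__ = [
    "CorrelationProfile",
    "KinomeLayout",
    "read_layout",
    "profile_correlation",
    "correlation_matrix",
    "interpolate_disk_color",
    "disk_radius",
    "kinome_disk_plot",
]

logger = logging.getLogger(__name__)

MIN_SHARED_INHIBITORS = 3

#: disk hue anchors: correlation -> color (100% red, 80% magenta, 50% blue, 20% green)
COLOR_ANCHORS: dict[float, str] = {1.0: "red", 0.8: "magenta", 0.5: "blue", 0.2: "green"}


@dataclass
class CorrelationProfile:
    """Pearson correlation of every target's profile with a reference target.

    ``r`` is NaN where fewer than 3 inhibitors are shared or a profile has
    zero variance over the shared set; ``n_pairs`` counts shared inhibitors.
    """

    reference: str
    r: pd.Series
    n_pairs: pd.Series

    def __post_init__(self) -> None:
        defined = self.r.dropna()
        if (defined.abs() > 1 + 1e-12).any():
            raise ValueError("|r| must not exceed 1")


@dataclass
class KinomeLayout:
    """Plot coordinates (x, y, arbitrary units) and group label per kinase."""

    table: pd.DataFrame  # index: kinase label; columns x, y, group

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate kinase labels in layout")
        for col in ("x", "y"):
            if col not in self.table.columns:
                raise ValueError(f"layout missing column {col!r}")


def read_layout(path) -> KinomeLayout:
    """Read a layout CSV with columns (kinase, x, y, group)."""
    table = pd.read_csv(path)
    table = table.set_index(table.columns[0])
    return KinomeLayout(table=table)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Pearson r; NaN when either vector has zero variance."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def profile_correlation(e: BindingEnergyMatrix, reference: str) -> CorrelationProfile:
    """Correlate every target's binding-energy profile with the reference's.

    Each pair uses pairwise-complete inhibitors (present in both rows);
    pairs with fewer than 3 shared inhibitors, or zero variance over the
    shared set, are undefined (NaN).
    """
    if reference not in e.values.index:
        raise KeyError(f"unknown reference target {reference!r}")
    ref = e.values.loc[reference].to_numpy(dtype=float)
    r = {}
    n_pairs = {}
    for target in e.target_ids:
        row = e.values.loc[target].to_numpy(dtype=float)
        shared = np.isfinite(ref) & np.isfinite(row)
        n_pairs[target] = int(shared.sum())
        if shared.sum() < MIN_SHARED_INHIBITORS:
            r[target] = np.nan
        else:
            r[target] = _pearson(ref[shared], row[shared])
    return CorrelationProfile(
        reference=reference,
        r=pd.Series(r).reindex(e.target_ids),
        n_pairs=pd.Series(n_pairs).reindex(e.target_ids),
    )


def correlation_matrix(e: BindingEnergyMatrix) -> pd.DataFrame:
    """Symmetric t x t Pearson correlation matrix of binding-energy profiles."""
    targets = e.target_ids
    out = pd.DataFrame(np.nan, index=targets, columns=targets)
    arr = e.values.to_numpy(dtype=float)
    for i, a_id in enumerate(targets):
        for j in range(i, len(targets)):
            shared = np.isfinite(arr[i]) & np.isfinite(arr[j])
            if shared.sum() < MIN_SHARED_INHIBITORS:
                val = np.nan
            else:
                val = _pearson(arr[i][shared], arr[j][shared])
            out.iat[i, j] = val
            out.iat[j, i] = val
    return out


def interpolate_disk_color(r: float) -> tuple[float, float, float]:
    """RGB hue for a correlation value, linear between the legend anchors.

    Anchors: r = 1.0 red, 0.8 magenta, 0.5 blue, 0.2 green; values below
    0.2 clamp to green.
    """
    anchors = sorted(COLOR_ANCHORS.items())  # ascending r
    lo_r, lo_c = anchors[0]
    if r <= lo_r:
        return to_rgb(lo_c)
    for (r0, c0), (r1, c1) in zip(anchors, anchors[1:]):
        if r <= r1:
            f = (r - r0) / (r1 - r0)
            rgb0, rgb1 = np.array(to_rgb(c0)), np.array(to_rgb(c1))
            return tuple((1 - f) * rgb0 + f * rgb1)
    return to_rgb(anchors[-1][1])


def disk_radius(r: float, max_radius: float = 1.0, min_radius: float = 0.15) -> float:
    """Disk radius monotone in r: minimal at r <= 0.2, linear up to r = 1."""
    lo = min(COLOR_ANCHORS)
    if not np.isfinite(r) or r <= lo:
        return min_radius
    f = min((r - lo) / (1.0 - lo), 1.0)
    return min_radius + f * (max_radius - min_radius)


def kinome_disk_plot(
    p: CorrelationProfile,
    layout: KinomeLayout,
    out_path,
    max_radius: float = 140.0,
    min_radius: float = 15.0,
):
    """Render a correlation profile as disks on the kinome layout.

    One disk per kinase with a defined correlation and a layout position;
    kinases missing from the layout are skipped with a warning.
    """
    import matplotlib.pyplot as plt

    if layout.table.empty:
        raise ValueError("empty kinome layout")
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.scatter(layout.table["x"], layout.table["y"], s=2, c="0.8", zorder=1)
    for kinase, r in p.r.items():
        if kinase not in layout.table.index:
            logger.warning("kinase %s not in layout; skipped", kinase)
            continue
        if not np.isfinite(r):
            continue
        row = layout.table.loc[kinase]
        ax.scatter(
            row["x"], row["y"],
            s=disk_radius(r, max_radius, min_radius),
            color=interpolate_disk_color(r),
            edgecolors="k", linewidths=0.3, zorder=2,
        )
    ax.set_title(f"Profile correlation with {p.reference}")
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return Path(out_path)
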
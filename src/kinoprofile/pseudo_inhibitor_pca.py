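"""Pseudo-inhibitor principal-component analysis of binding-energy matrices.

The t x n binding-energy matrix places each target at a point in the
n-dimensional space of inhibitors.  A Karhunen-Loeve / principal-component
transform rotates that space into orthonormal "pseudo-inhibitors" — weighted
combinations of real inhibitors — ordered by the inhibition variance they
carry.  Targets with shared selectivity cluster in the leading components,
and the loading plot identifies which real inhibitors drive a component.

The decomposition is computed by singular value decomposition of the
column-standardized matrix (targets as observations, inhibitors as
variables), which is numerically stabler than an explicit covariance
eigen-solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .affinity_io import BindingEnergyMatrix

__all__ = [
    "PCAResult",
    "GatekeeperTable",
    "pca_pseudo_inhibitors",
    "component_separation",
    "score_plot",
    "loading_plot",
]

logger = logging.getLogger(__name__)

AMINO_ONE_LETTER = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PCAResult:
    """Scores (targets in pseudo-inhibitor space) and orthonormal loadings.

    ``scores`` is t x k, ``loadings`` n x k with orthonormal columns,
    ``explained_variance`` the non-increasing component variances.
    ``column_means``/``column_scales`` are the per-inhibitor standardization
    constants applied before decomposition.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    column_means: pd.Series
    column_scales: pd.Series
    dropped_inhibitors: list[str]

    def __post_init__(self) -> None:
        L = self.loadings.to_numpy()
        if not np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8):
            raise ValueError("loadings columns must be orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-10):
            raise ValueError("explained_variance must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum()


@dataclass
class GatekeeperTable:
    """Gatekeeper residue one-letter code per kinase (annotation for score plots)."""

    codes: dict[str, str]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.codes.items() if v not in AMINO_ONE_LETTER}
        if bad:
            raise ValueError(f"invalid amino-acid codes: {bad}")

    def color(self, kinase: str) -> str:
        # methionine gatekeepers red, others gray (unknown: default gray)
        return "red" if self.codes.get(kinase) == "M" else "gray"


def pca_pseudo_inhibitors(
    e: BindingEnergyMatrix, standardize: bool = True, k: int | None = None
) -> PCAResult:
    """PCA of the binding-energy matrix with inhibitors as variables.

    Columns are centered and, if ``standardize``, scaled to unit variance
    (correlation-matrix PCA, the default).  Zero-variance columns are
    dropped with a warning.  Loadings carry a deterministic sign: each
    column is oriented so its largest-magnitude coefficient is positive.
    ``k`` defaults to min(t, n) - 1.
    """
    X = e.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("binding-energy matrix has absent cells; complete or drop first")
    t, n = X.shape
    if t < 2 or n < 2:
        raise ValueError("need at least 2 targets and 2 inhibitors")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    keep = scales > 0
    dropped = [c for c, k_ in zip(e.inhibitor_ids, keep) if not k_]
    if not keep.any():
        raise ValueError("all inhibitor columns are constant")
    if dropped:
        logger.warning("dropping %d zero-variance inhibitor columns", len(dropped))
    cols = [c for c, k_ in zip(e.inhibitor_ids, keep) if k_]
    Xs = X[:, keep] - means[keep]
    if standardize:
        Xs = Xs / scales[keep]
    n_keep = Xs.shape[1]
    k_max = min(t, n_keep) - 1 if min(t, n_keep) > 1 else 1
    k = k_max if k is None else min(k, min(t, n_keep))
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    loadings = Vt[:k].T  # n_keep x k
    # sign convention: largest-|coefficient| entry of each loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Xs @ loadings
    explained = (S[:k] ** 2) / (t - 1)
    comp_ids = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=e.target_ids, columns=comp_ids),
        loadings=pd.DataFrame(loadings, index=cols, columns=comp_ids),
        explained_variance=explained,
        column_means=pd.Series(means[keep], index=cols),
        column_scales=pd.Series(scales[keep] if standardize else np.ones(n_keep), index=cols),
        dropped_inhibitors=dropped,
    )


def component_separation(p: PCAResult, member_mask: pd.Series) -> pd.Series:
    """Separation ratio of a target group on each component.

    For each component: |mean score of the group - mean of the rest| divided
    by the larger of the two within-group standard deviations.  Used to ask
    whether some leading component isolates a planted (or biological) family
    the way a selectivity-orthogonal kinase group separates from the rest.
    """
    mask = member_mask.reindex(p.scores.index).fillna(False).astype(bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("member_mask must split targets into two nonempty groups")
    inside = p.scores[mask.to_numpy()]
    outside = p.scores[~mask.to_numpy()]
    gap = (inside.mean() - outside.mean()).abs()
    spread = pd.concat([inside.std(ddof=0), outside.std(ddof=0)], axis=1).max(axis=1)
    return gap / spread.replace(0.0, np.finfo(float).tiny)


def _check_dims(p: PCAResult, dims) -> list[str]:
    comps = []
    for d in dims:
        if not 1 <= d <= p.n_components:
            raise IndexError(f"component {d} out of range (1..{p.n_components})")
        comps.append(f"PC{d}")
    return comps


def score_plot(
    p: PCAResult,
    out_path,
    dims: tuple[int, int] = (1, 2),
    annotation=None,
    label_points: bool = True,
):
    """Scatter the target scores on two components, colored by annotation.

    ``annotation`` may be a :class:`GatekeeperTable` (methionine gatekeepers
    red, others gray) or a mapping of target -> group label; targets without
    an annotation render in the default color with a warning.
    """
    import matplotlib.pyplot as plt

    cx, cy = _check_dims(p, dims)
    ratio = p.explained_variance_ratio
    fig, ax = plt.subplots(figsize=(6, 5))
    if isinstance(annotation, GatekeeperTable):
        colors = [annotation.color(t) for t in p.scores.index]
        ax.scatter(p.scores[cx], p.scores[cy], c=colors, edgecolors="k", linewidths=0.3)
    elif annotation is not None:
        groups = {}
        for t in p.scores.index:
            g = annotation.get(t)
            if g is None:
                logger.warning("no annotation for target %s; default color", t)
            groups.setdefault(g, []).append(t)
        cmap = plt.get_cmap("tab10")
        for gi, (g, members) in enumerate(sorted(groups.items(), key=lambda kv: str(kv[0]))):
            sub = p.scores.loc[members]
            color = "0.6" if g is None else cmap(gi % 10)
            ax.scatter(sub[cx], sub[cy], color=color, label=str(g), edgecolors="k",
                       linewidths=0.3)
        ax.legend(fontsize=8)
    else:
        ax.scatter(p.scores[cx], p.scores[cy], edgecolors="k", linewidths=0.3)
    if label_points:
        for t in p.scores.index:
            ax.annotate(str(t), (p.scores.at[t, cx], p.scores.at[t, cy]),
                        fontsize=6, xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel(f"{cx} ({100 * ratio[dims[0] - 1]:.1f}% variance)")
    ax.set_ylabel(f"{cy} ({100 * ratio[dims[1] - 1]:.1f}% variance)")
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def loading_plot(p: PCAResult, out_path, dims: tuple[int, int] = (2, 3)) -> pd.DataFrame:
    """Scatter inhibitor coefficients on two components; return the table.

    The table lists each retained inhibitor's coefficients on the chosen
    components and its quadrant (signs of the two coefficients), which is
    how selectivity-driving inhibitors are read off the plot.
    """
    import matplotlib.pyplot as plt

    cx, cy = _check_dims(p, dims)
    table = p.loadings[[cx, cy]].copy()
    table["quadrant"] = [
        f"{'+' if a >= 0 else '-'}{'+' if b >= 0 else '-'}"
        for a, b in zip(table[cx], table[cy])
    ]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.scatter(table[cx], table[cy], s=18, edgecolors="k", linewidths=0.3)
    for i in table.index:
        ax.annotate(str(i), (table.at[i, cx], table.at[i, cy]), fontsize=6,
                    xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel(f"{cx} loading")
    ax.set_ylabel(f"{cy} loading")
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return table
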
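"""PLS regression of kinase activation state on geometric descriptors.

A kinase domain's catalytically competent ("active", DFG-in, C-helix-in)
versus incompetent ("inactive") state is encoded 1/0 and regressed on a
table of geometric descriptors (distances in Å, angles and dihedrals in
degrees) by single-response partial least squares (PLS1, NIPALS).
Descriptors are centered and scaled to unit variance; the response is
centered.  Components are latent directions of descriptor space maximizing
covariance with the activity state.

Model quality is reported as cumulative R² (goodness of fit,
1 − SS_res/SS_tot) and cumulative Q² (predictive ability, 1 − PRESS/SS_tot,
with PRESS pooled over stratified k-fold cross-validation, 7 folds by
default).  Components are added while the cumulative Q² improves by more
than a configurable gain threshold, which guards against overfitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorTable",
    "PLSModel",
    "read_descriptor_table",
    "write_descriptor_table",
    "pls_fit",
    "pls_predict",
    "pls_score_plot",
]

logger = logging.getLogger(__name__)

LABEL_COLUMN = "activity_state"


@dataclass
class DescriptorTable:
    """Structures x descriptors with a binary activity-state label per structure."""

    X: pd.DataFrame  # m x p real descriptors
    y: pd.Series  # 1 = active, 0 = inactive

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("descriptor rows and labels must share structure ids")
        if self.y.isna().any():
            raise ValueError("labels must not be absent")
        if not set(self.y.unique()) <= {0, 1}:
            raise ValueError("labels must be encoded 0 (inactive) / 1 (active)")
        if self.X.shape[1] < 1 or self.X.shape[0] < 2:
            raise ValueError("need at least 2 structures and 1 descriptor")

    @property
    def structure_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def descriptor_ids(self) -> list[str]:
        return list(self.X.columns)


def read_descriptor_table(path, label_col: str = LABEL_COLUMN) -> DescriptorTable:
    df = pd.read_csv(path, index_col=0)
    if label_col not in df.columns:
        raise ValueError(f"descriptor table missing label column {label_col!r}")
    y = df[label_col].astype(int)
    X = df.drop(columns=[label_col]).astype(float)
    return DescriptorTable(X=X, y=y)


def write_descriptor_table(d: DescriptorTable, path, label_col: str = LABEL_COLUMN) -> None:
    out = d.X.copy()
    out[label_col] = d.y
    out.index.name = "structure"
    out.to_csv(path)


@dataclass
class PLSModel:
    """Fitted PLS1 model with cross-validated component count."""

    n_components: int
    x_weights: np.ndarray  # p x a
    x_loadings: np.ndarray  # p x a
    y_loadings: np.ndarray  # a
    coef_: np.ndarray  # p, on the standardized scale
    r2_cum: list[float]
    q2_cum: list[float]
    x_variance_ratio: list[float]  # fraction of (scaled) X variance per component
    x_mean: pd.Series
    x_scale: pd.Series
    y_mean: float
    descriptor_ids: list[str] = field(default_factory=list)
    train_scores: pd.DataFrame | None = None
    seed: int = 0
    folds: int = 7

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if np.any(np.diff(self.r2_cum) < -1e-10):
            raise ValueError("cumulative R2 must be non-decreasing")
        if any(q > 1 + 1e-12 for q in self.q2_cum):
            raise ValueError("Q2 cannot exceed 1")


def _nipals_pls1(Xs: np.ndarray, ys: np.ndarray, a_max: int):
    """NIPALS PLS1 on pre-scaled data; returns weights, loadings, y-loadings, scores."""
    X = Xs.copy()
    y = ys.copy()
    p = X.shape[1]
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    q = np.zeros(a_max)
    T = np.zeros((X.shape[0], a_max))
    for a in range(a_max):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            return W[:, :a], P[:, :a], q[:a], T[:, :a]
        w /= norm
        t = X @ w
        tt = t @ t
        if tt < 1e-14:
            return W[:, :a], P[:, :a], q[:a], T[:, :a]
        pl = X.T @ t / tt
        ql = y @ t / tt
        X = X - np.outer(t, pl)
        y = y - ql * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pl, ql, t
    return W, P, q, T


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, a: int) -> np.ndarray:
    """Regression coefficients for the first ``a`` components (standardized scale)."""
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


def _stratified_folds(ids: list, y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold index per sample, stratified by class.

    Keyed to sorted structure ids (shuffled with the seed, dealt round-robin)
    so the assignment is invariant to the row order of the input table.
    """
    rng = np.random.default_rng(seed)
    fold_by_id: dict = {}
    for cls in np.unique(y):
        cls_ids = sorted(str(i) for i, yy in zip(ids, y) if yy == cls)
        perm = rng.permutation(len(cls_ids))
        for k, j in enumerate(perm):
            fold_by_id[cls_ids[j]] = k % folds
    return np.array([fold_by_id[str(i)] for i in ids], dtype=int)


def pls_fit(
    d: DescriptorTable,
    folds: int = 7,
    max_components: int = 10,
    q2_gain: float = 0.01,
    seed: int = 0,
) -> PLSModel:
    """Fit PLS1 with cross-validated selection of the component count.

    Descriptors are centered and unit-variance scaled (zero-variance columns
    dropped with a warning); the 0/1 response is centered.  Q² per cumulative
    component count comes from stratified ``folds``-fold CV with pooled
    PRESS; components are added while the Q² gain exceeds ``q2_gain``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if d.X.shape[0] <= folds:
        raise ValueError("need more structures than folds")
    y_raw = d.y.to_numpy(dtype=float)
    if len(np.unique(y_raw)) < 2:
        raise ValueError("response is constant; both classes required")

    scales_all = d.X.std(axis=0, ddof=1)
    keep = scales_all > 0
    if (~keep).any():
        logger.warning("dropping %d zero-variance descriptors", int((~keep).sum()))
    X_df = d.X.loc[:, keep]
    descriptor_ids = list(X_df.columns)
    X = X_df.to_numpy(dtype=float)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    Xs = (X - x_mean) / x_scale
    y_mean = y_raw.mean()
    ys = y_raw - y_mean

    a_max = min(max_components, Xs.shape[1], Xs.shape[0] - 1)
    W, P, q, T = _nipals_pls1(Xs, ys, a_max)
    a_max = W.shape[1]
    ss_tot = float(ys @ ys)
    ss_x_tot = float((Xs * Xs).sum())

    r2_cum, x_var = [], []
    for a in range(1, a_max + 1):
        resid = ys - T[:, :a] @ q[:a]
        r2_cum.append(1.0 - float(resid @ resid) / ss_tot)
        t = T[:, a - 1]
        x_var.append(float((t @ t) * (P[:, a - 1] @ P[:, a - 1])) / ss_x_tot)

    # pooled-PRESS Q2 per cumulative component count
    fold_of = _stratified_folds(d.structure_ids, y_raw, folds, seed)
    press = np.zeros(a_max)
    for f in range(folds):
        test = fold_of == f
        train = ~test
        Xtr = X[train]
        mtr, str_ = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        str_[str_ == 0] = 1.0
        Xtr_s = (Xtr - mtr) / str_
        ytr = y_raw[train]
        ytr_s = ytr - ytr.mean()
        Wf, Pf, qf, _ = _nipals_pls1(Xtr_s, ytr_s, a_max)
        Xte_s = (X[test] - mtr) / str_
        for a in range(1, a_max + 1):
            aa = min(a, Wf.shape[1])
            if aa == 0:
                pred = np.full(test.sum(), ytr.mean())
            else:
                b = _coefficients(Wf, Pf, qf, aa)
                pred = Xte_s @ b + ytr.mean()
            press[a - 1] += float(((y_raw[test] - pred) ** 2).sum())
    q2_cum = list(1.0 - press / ss_tot)

    # add components while cumulative Q2 improves by more than q2_gain
    n_components = 1
    for a in range(2, a_max + 1):
        if q2_cum[a - 1] - q2_cum[a - 2] > q2_gain:
            n_components = a
        else:
            break

    coef = _coefficients(W, P, q, n_components)
    comp_ids = [f"LV{i + 1}" for i in range(n_components)]
    return PLSModel(
        n_components=n_components,
        x_weights=W[:, :n_components],
        x_loadings=P[:, :n_components],
        y_loadings=q[:n_components],
        coef_=coef,
        r2_cum=r2_cum[:n_components],
        q2_cum=q2_cum[:n_components],
        x_variance_ratio=x_var[:n_components],
        x_mean=pd.Series(x_mean, index=descriptor_ids),
        x_scale=pd.Series(x_scale, index=descriptor_ids),
        y_mean=float(y_mean),
        descriptor_ids=descriptor_ids,
        train_scores=pd.DataFrame(T[:, :n_components], index=d.X.index, columns=comp_ids),
        seed=seed,
        folds=folds,
    )


def pls_predict(model: PLSModel, d: DescriptorTable) -> pd.DataFrame:
    """Predict continuous activity-state and the class call at 0.5.

    Descriptor ids must match the training table (columns may be in any
    order); returns a frame with ``y_pred`` and boolean ``active``.
    """
    missing = set(model.descriptor_ids) - set(d.X.columns)
    if missing:
        raise ValueError(f"descriptor mismatch; missing {sorted(missing)[:5]}...")
    X = d.X[model.descriptor_ids].to_numpy(dtype=float)
    Xs = (X - model.x_mean.to_numpy()) / model.x_scale.to_numpy()
    y_pred = Xs @ model.coef_ + model.y_mean
    return pd.DataFrame(
        {"y_pred": y_pred, "active": y_pred >= 0.5}, index=d.X.index
    )


def pls_score_plot(model: PLSModel, out_path, dims: tuple[int, int] = (1, 2),
                   groups=None):
    """Scatter per-structure latent scores on two components, colored by group."""
    import matplotlib.pyplot as plt

    for dim in dims:
        if not 1 <= dim <= model.n_components:
            raise IndexError(f"component {dim} out of range (1..{model.n_components})")
    cx, cy = f"LV{dims[0]}", f"LV{dims[1]}"
    scores = model.train_scores
    fig, ax = plt.subplots(figsize=(6, 5))
    if groups is not None:
        groups = pd.Series(groups).reindex(scores.index)
        cmap = plt.get_cmap("tab10")
        for gi, g in enumerate(sorted(groups.dropna().unique())):
            sub = scores[groups == g]
            ax.scatter(sub[cx], sub[cy], color=cmap(gi % 10), label=str(g),
                       edgecolors="k", linewidths=0.3)
        ax.legend(fontsize=8)
    else:
        ax.scatter(scores[cx], scores[cy], edgecolors="k", linewidths=0.3)
    ax.set_xlabel(f"{cx} ({100 * model.x_variance_ratio[dims[0] - 1]:.1f}% of X variance)")
    ax.set_ylabel(f"{cy} ({100 * model.x_variance_ratio[dims[1] - 1]:.1f}% of X variance)")
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
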
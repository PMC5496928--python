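"""Activity-homology (AH) similarity of kinase drug targets.

AH(A, B) is the percentage of the potent inhibitors of a reference kinase A
that are also potent for a comparison kinase B — the prior probability that
a compound active on A is active on B.  Each kinase owns its own potent set,
so the matrix is asymmetric: AH(A, B) and AH(B, A) generally differ.

Rows with an empty potent set have no defined AH (0/0 carries no
probabilistic meaning); they are reported as undefined (NaN) and excluded
from clustering with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .affinity_io import AffinityMatrix, PotencyThreshold, potent_set

__all__ = ["AHMatrix", "activity_homology", "ah_reference_curves", "ah_clustermap",
           "ClustermapResult"]

logger = logging.getLogger(__name__)


@dataclass
class AHMatrix:
    """Asymmetric t x t activity-homology percentages.

    Row = reference kinase A, column = comparison kinase B; entries in
    [0, 100] or NaN where the reference has no potent inhibitors.
    ``potent_counts`` gives |P_A| per row.
    """

    values: pd.DataFrame
    potent_counts: pd.Series

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        defined = ~np.isnan(vals)
        if ((vals[defined] < 0) | (vals[defined] > 100)).any():
            raise ValueError("AH percentages must lie in [0, 100]")

    @property
    def target_ids(self) -> list[str]:
        return list(self.values.index)

    def defined_rows(self) -> list[str]:
        return [t for t in self.target_ids if self.potent_counts[t] > 0]


def activity_homology(m: AffinityMatrix, thr: PotencyThreshold | None = None) -> AHMatrix:
    """Compute AH(A, B) = 100 * |P_A ∩ P_B| / |P_A| for all target pairs."""
    thr = thr or PotencyThreshold()
    targets = m.target_ids
    potent = np.array(
        [[i in potent_set(m, t, thr) for i in m.inhibitor_ids] for t in targets],
        dtype=bool,
    )
    counts = potent.sum(axis=1)
    shared = potent.astype(int) @ potent.astype(int).T  # |P_A ∩ P_B|
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = 100.0 * shared / counts[:, None]
    ah[counts == 0, :] = np.nan
    values = pd.DataFrame(ah, index=targets, columns=targets)
    return AHMatrix(values=values, potent_counts=pd.Series(counts, index=targets))


def ah_reference_curves(
    ah: AHMatrix, references: list[str], ordering_reference: str
) -> pd.DataFrame:
    """AH curves of selected reference kinases over the rank-ordered test set.

    Targets (x-axis) are sorted by descending AH with ``ordering_reference``;
    ties break lexicographically by target id.  Returns a table with columns
    ``rank``, ``target`` and one AH column per reference.
    """
    for label in [*references, ordering_reference]:
        if label not in ah.values.index:
            raise KeyError(f"unknown target {label!r}")
    order_row = ah.values.loc[ordering_reference]
    if order_row.isna().all():
        raise ValueError(f"ordering reference {ordering_reference!r} has undefined AH")
    order = sorted(ah.target_ids, key=lambda t: (-(order_row[t]), t))
    out = pd.DataFrame({"rank": np.arange(1, len(order) + 1), "target": order})
    for ref in references:
        out[ref] = ah.values.loc[ref, order].to_numpy()
    return out


@dataclass
class ClustermapResult:
    """Row/column-reordered AH matrix with the linkages that produced it."""

    ordered: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    dropped: list[str] = field(default_factory=list)
    _leaf_source: list[str] = field(default_factory=list)

    def cut_rows(self, n_clusters: int) -> pd.Series:
        """Flat row clusters from cutting the row dendrogram into ``n_clusters``."""
        labels = sch.fcluster(self.row_linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=list(self._leaf_source))


def ah_clustermap(
    ah: AHMatrix,
    linkage: str = "average",
    metric: str = "euclidean",
    out_path=None,
) -> ClustermapResult:
    """Hierarchically cluster the AH matrix rows and columns; render a heat map.

    Undefined rows (no potent inhibitors) are dropped with a warning before
    clustering.  Leaf orders are deterministic (scipy's merge order; ties
    resolved by lowest pair index).
    """
    keep = ah.defined_rows()
    dropped = [t for t in ah.target_ids if t not in keep]
    if dropped:
        logger.warning("dropping %d undefined AH rows: %s", len(dropped), dropped)
    if len(keep) < 2:
        raise ValueError("clustering requires at least 2 targets with defined AH")
    sub = ah.values.loc[keep, keep]
    row_link = sch.linkage(pdist(sub.to_numpy(), metric=metric), method=linkage)
    col_link = sch.linkage(pdist(sub.to_numpy().T, metric=metric), method=linkage)
    row_order = [keep[i] for i in sch.leaves_list(row_link)]
    col_order = [keep[i] for i in sch.leaves_list(col_link)]
    ordered = sub.loc[row_order, col_order]
    if out_path is not None:
        import seaborn as sns

        g = sns.clustermap(
            sub, row_linkage=row_link, col_linkage=col_link,
            cmap="viridis", vmin=0, vmax=100,
            cbar_kws={"label": "AH (%)"},
        )
        g.savefig(out_path)
        import matplotlib.pyplot as plt

        plt.close(g.figure)
    result = ClustermapResult(
        ordered=ordered, row_order=row_order, col_order=col_order,
        row_linkage=row_link, col_linkage=col_link, dropped=dropped,
    )
    result._leaf_source = keep
    return result
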
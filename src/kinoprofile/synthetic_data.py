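"""Synthetic inputs with the statistical structure of kinase profiling data.

Three generators produce the inputs every analysis stage consumes, with
known ground truth so recovery can be tested end to end:

* :func:`simulate_affinity_matrix` — a target x inhibitor log10-Kd matrix
  built from additive Gaussian effects on the log-affinity scale (binding
  free energies are additive in log Kd): a grand mean, a family shift per
  target family, a per-inhibitor promiscuity term, a family-by-inhibitor
  interaction that gives members of a family correlated inhibition
  profiles, and measurement noise.  One family can be made an "outlier":
  it receives a dedicated subset of inhibitors boosted in potency for it
  alone and, optionally, has its interaction terms with all other
  inhibitors zeroed — making its selectivity orthogonal to the rest of the
  panel, the way covalent-trap binding is orthogonal to pocket-shape
  complementarity.  Values above the censoring limit are emitted censored.

* :func:`simulate_descriptors` — a two-class geometric descriptor table:
  most descriptors are standard normal for both classes, a chosen few are
  shifted between classes by a stated number of standard deviations.

* :func:`simulate_superposition_set` — coordinate ensembles: a reference
  point set plus members displaced by known rigid transforms and isotropic
  Gaussian noise, with optional planted aromatic-ring sites for centroid
  clustering.

All randomness flows from a single integer seed per call; equal seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .affinity_io import AffinityMatrix
from .activity_state_pls import DescriptorTable
from .structure_superpose import (
    Atom,
    KinaseMonomer,
    Residue,
    RigidTransform,
    RING_ATOMS,
)

__all__ = [
    "OutlierFamilyConfig",
    "SimulationConfig",
    "GroundTruth",
    "simulate_affinity_matrix",
    "simulate_descriptors",
    "simulate_superposition_set",
    "toy_kinome_layout",
]


@dataclass(frozen=True)
class OutlierFamilyConfig:
    """Knobs for the selectivity-orthogonal family.

    ``dedicated_inhibitor_count`` inhibitors are boosted in potency by
    ``potency_boost`` log10 units for this family only; with ``decoupling``
    the family's interaction terms with every other inhibitor are zeroed.
    """

    enabled: bool = True
    dedicated_inhibitor_count: int = 8
    potency_boost: float = 2.0
    decoupling: bool = True


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic affinity matrix.

    All scales are log10-nM.  Defaults: 4 families x 5 targets against 60
    inhibitors around a 1 µM grand mean (log10 = 3.0); family-by-inhibitor
    interaction (sd 0.8) dominates the family shift (sd 0.3) so similarity
    is carried by shared inhibitor preferences, as in real panels; noise sd
    0.3 (~2-fold assay error); censoring at 10 µM.  The last family is the
    outlier when enabled.
    """

    n_families: int = 4
    targets_per_family: int = 5
    n_inhibitors: int = 60
    grand_mean: float = 3.0
    family_effect_sd: float = 0.3
    inhibitor_effect_sd: float = 0.5
    interaction_sd: float = 0.8
    noise_sd: float = 0.3
    outlier_family: OutlierFamilyConfig = field(default_factory=OutlierFamilyConfig)
    censor_limit_nM: float = 10000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("family_effect_sd", "inhibitor_effect_sd", "interaction_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_families", "targets_per_family", "n_inhibitors"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.censor_limit_nM <= 0:
            raise ValueError("censor_limit_nM must be positive")
        if (self.outlier_family.enabled
                and self.outlier_family.dedicated_inhibitor_count > self.n_inhibitors):
            raise ValueError("dedicated inhibitors exceed the panel size")


@dataclass
class GroundTruth:
    """Planted structure behind a simulated matrix."""

    family: pd.Series  # target -> family label
    outlier_family: str | None
    dedicated_inhibitors: list[str]
    effects: dict[str, np.ndarray]

    def family_mask(self, label: str) -> pd.Series:
        return self.family == label


def simulate_affinity_matrix(
    c: SimulationConfig | None = None,
) -> tuple[AffinityMatrix, GroundTruth]:
    """Draw a censored affinity matrix from the additive log10-Kd model.

    log10 Kd(i, j) = grand_mean + a_f(i) + b_j + c_{f(i), j} + eps_ij, with
    the outlier-family modifications described in the module docstring;
    cells above the censoring limit are emitted as censored.
    """
    c = c or SimulationConfig()
    rng = np.random.default_rng(c.seed)
    t = c.n_families * c.targets_per_family
    families = [f"F{k + 1}" for k in range(c.n_families)]
    target_ids = [
        f"{fam}_T{j + 1}" for fam in families for j in range(c.targets_per_family)
    ]
    inhibitor_ids = [f"inh{j + 1:03d}" for j in range(c.n_inhibitors)]
    fam_of = np.repeat(np.arange(c.n_families), c.targets_per_family)

    a = rng.normal(0.0, c.family_effect_sd, size=c.n_families)
    b = rng.normal(0.0, c.inhibitor_effect_sd, size=c.n_inhibitors)
    inter = rng.normal(0.0, c.interaction_sd, size=(c.n_families, c.n_inhibitors))
    eps = rng.normal(0.0, c.noise_sd, size=(t, c.n_inhibitors))

    out = c.outlier_family
    outlier_label = None
    dedicated: list[str] = []
    if out.enabled and c.n_families >= 2:
        k_out = c.n_families - 1
        outlier_label = families[k_out]
        n_ded = out.dedicated_inhibitor_count
        ded_idx = np.arange(c.n_inhibitors - n_ded, c.n_inhibitors)
        dedicated = [inhibitor_ids[j] for j in ded_idx]
        if out.decoupling:
            inter[k_out, :] = 0.0
        inter[k_out, ded_idx] -= out.potency_boost

    log10_kd = (
        c.grand_mean
        + a[fam_of][:, None]
        + b[None, :]
        + inter[fam_of, :]
        + eps
    )
    nM = 10.0 ** log10_kd
    censored = nM > c.censor_limit_nM
    values = pd.DataFrame(
        np.where(censored, np.nan, nM), index=target_ids, columns=inhibitor_ids
    )
    matrix = AffinityMatrix(
        values=values,
        censored=pd.DataFrame(censored, index=target_ids, columns=inhibitor_ids),
        limit_nM=c.censor_limit_nM,
    )
    truth = GroundTruth(
        family=pd.Series([families[k] for k in fam_of], index=target_ids),
        outlier_family=outlier_label,
        dedicated_inhibitors=dedicated,
        effects={"family": a, "inhibitor": b, "interaction": inter, "noise": eps},
    )
    return matrix, truth


def simulate_descriptors(
    m_per_class: int = 60,
    p: int = 233,
    n_informative: int = 10,
    shift_sd: float = 2.0,
    seed: int = 0,
) -> DescriptorTable:
    """Two-class geometric descriptor table with a planted mean shift.

    ``n_informative`` descriptors separate the classes by ``shift_sd``
    standard deviations; the rest are standard normal for both.  Labels are
    balanced, 1 = active, 0 = inactive.
    """
    if n_informative > p:
        raise ValueError("n_informative exceeds p")
    if m_per_class < 1 or p < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    m = 2 * m_per_class
    X = rng.normal(size=(m, p))
    y = np.array([0] * m_per_class + [1] * m_per_class)
    X[y == 1, :n_informative] += shift_sd
    structure_ids = [f"struct{i + 1:03d}" for i in range(m)]
    descriptor_ids = [f"geo{j + 1:03d}" for j in range(p)]
    return DescriptorTable(
        X=pd.DataFrame(X, index=structure_ids, columns=descriptor_ids),
        y=pd.Series(y, index=structure_ids),
    )


def _hexagon(center: np.ndarray, radius: float = 1.39) -> np.ndarray:
    """Ideal planar six-membered ring (benzene C-C 1.39 Å) around a center."""
    angles = np.arange(6) * np.pi / 3
    ring = np.stack([np.cos(angles), np.sin(angles), np.zeros(6)], axis=1) * radius
    return ring + center


def simulate_superposition_set(
    n_structures: int = 5,
    n_atoms: int = 50,
    transforms: list[RigidTransform] | None = None,
    noise_sd: float = 0.1,
    planted_centroid_sites: list[np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[KinaseMonomer, list[KinaseMonomer], dict]:
    """Coordinate ensemble for superposition tests.

    A reference Cα trace of ``n_atoms`` residues is drawn once; each member
    is the reference under a known rigid transform (random proper rotations
    and translations when ``transforms`` is None) plus isotropic Gaussian
    noise of ``noise_sd`` Å per coordinate.  Optional planted sites add one
    phenylalanine ring per site per structure, its ring center jittered by
    the same noise — fodder for centroid clustering.

    Returns (reference monomer, member monomers, ground truth dict with the
    transforms and noise level).
    """
    rng = np.random.default_rng(seed)
    ref_coords = rng.normal(scale=8.0, size=(n_atoms, 3))
    if transforms is None:
        transforms = []
        for _ in range(n_structures):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-20, 20, size=3)
            transforms.append(RigidTransform(R, t))
    if len(transforms) != n_structures:
        raise ValueError("need one transform per structure")
    sites = [np.asarray(s, dtype=float) for s in (planted_centroid_sites or [])]

    def build(coords: np.ndarray, ring_centers: list[np.ndarray], tag: str) -> KinaseMonomer:
        residues = [
            Residue(seqid=i + 1, icode="", name="ALA",
                    atoms=[Atom("CA", "C", coords[i].copy())])
            for i in range(len(coords))
        ]
        for k, center in enumerate(ring_centers):
            ring = _hexagon(center)
            atoms = [
                Atom(name, "C", ring[j].copy())
                for j, name in enumerate(RING_ATOMS["PHE"])
            ]
            residues.append(
                Residue(seqid=1000 + k, icode="", name="PHE", atoms=atoms)
            )
        return KinaseMonomer(source_id=tag, residues=residues)

    reference = build(ref_coords, sites, "SYNREF_A")
    members = []
    for s, tr in enumerate(transforms):
        coords = tr.apply(ref_coords) + rng.normal(scale=noise_sd, size=(n_atoms, 3))
        centers = [
            tr.apply(site[None, :])[0] + rng.normal(scale=noise_sd, size=3)
            for site in sites
        ]
        members.append(build(coords, centers, f"SYN{s + 1:02d}_A"))
    truth = {"transforms": transforms, "noise_sd": noise_sd, "sites": sites}
    return reference, members, truth


def toy_kinome_layout(target_ids: list[str], family: pd.Series, seed: int = 0) -> pd.DataFrame:
    """A toy (kinase, x, y, group) layout: families placed on a ring, members jittered."""
    rng = np.random.default_rng(seed)
    families = list(dict.fromkeys(family))
    centers = {
        fam: 10.0 * np.array([np.cos(2 * np.pi * k / len(families)),
                              np.sin(2 * np.pi * k / len(families))])
        for k, fam in enumerate(families)
    }
    rows = []
    for t in target_ids:
        fam = family[t]
        x, y = centers[fam] + rng.normal(scale=1.5, size=2)
        rows.append({"kinase": t, "x": x, "y": y, "group": fam})
    return pd.DataFrame(rows)
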
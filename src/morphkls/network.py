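"""Single-subject morphological networks from regional value distributions.

Each brain region contributes a bag of positive grey-matter voxel values.
A Gaussian kernel density estimate of every region's value distribution is
evaluated on one common grid per subject and renormalised to a discrete
probability mass vector.  The edge weight between two regions is the
KL-divergence-based similarity

    KLS(P, Q) = exp(-D_KL(P, Q)),

where D_KL(P, Q) is the *symmetric* divergence
sum_i [P_i log(P_i/Q_i) + Q_i log(Q_i/P_i)].  KLS lies in (0, 1] and equals
1 exactly when the two distributions coincide, giving a 90 x 90 weighted
undirected similarity matrix per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

N_REGIONS = 90
DEFAULT_GRID_POINTS = 2**7
#: floor applied to discrete masses before taking logs
MASS_FLOOR = 1e-10


class DegenerateSampleError(ValueError):
    """Raised when a region's voxel values admit no density estimate."""


class GridMismatchError(ValueError):
    """Raised when two density profiles do not share a grid."""


@dataclass
class RegionalVoxelSet:
    """Per-subject bags of voxel values, one bag per atlas region."""

    subject_id: str
    region_values: list[np.ndarray]
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.region_values) != N_REGIONS:
            raise ValueError(
                f"expected {N_REGIONS} regions, got {len(self.region_values)}"
            )
        if not self.region_labels:
            self.region_labels = [f"R{i + 1:02d}" for i in range(N_REGIONS)]
        if len(self.region_labels) != N_REGIONS:
            raise ValueError("region_labels must have one entry per region")
        self.region_values = [np.asarray(v, dtype=float) for v in self.region_values]
        for lab, vals in zip(self.region_labels, self.region_values):
            if vals.size == 0:
                raise ValueError(f"region {lab}: empty voxel bag")
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise ValueError(f"region {lab}: values must be finite and >= 0")


@dataclass
class DensityProfile:
    """A discrete probability mass vector on a common value-axis grid."""

    region_label: str
    grid: np.ndarray
    probabilities: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.grid.shape != self.probabilities.shape:
            raise ValueError("grid and probabilities must have the same length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


@dataclass
class MorphNetwork:
    """One subject's symmetric KLS similarity matrix with node labels."""

    subject_id: str
    weights: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_labels)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square and match node_labels")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def upper_triangle(self) -> np.ndarray:
        """Edge weights of the strict upper triangle, row-major order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]

    def to_tsv(self, path) -> None:
        """Write the weight matrix as TSV with node labels as header."""
        header = "\t".join(self.node_labels)
        np.savetxt(path, self.weights, delimiter="\t", header=header,
                   comments="", fmt="%.12g")

    @classmethod
    def from_tsv(cls, path, subject_id: str) -> "MorphNetwork":
        with open(path) as fh:
            labels = fh.readline().rstrip("\n").split("\t")
        w = np.loadtxt(path, delimiter="\t", skiprows=1)
        return cls(subject_id, w, labels)


def extract_regional_values(
    gm_img: "nib.spatialimages.SpatialImage | str",
    atlas_img: "nib.spatialimages.SpatialImage | str",
    subject_id: str = "subject",
    region_labels: list[str] | None = None,
) -> RegionalVoxelSet:
    """Collect the grey-matter map values within each atlas parcel.

    Parameters
    ----------
    gm_img, atlas_img
        NIfTI images (or paths) on the same voxel grid; the atlas holds
        integer labels 1..90.
    """
    if isinstance(gm_img, str):
        gm_img = nib.load(gm_img)
    if isinstance(atlas_img, str):
        atlas_img = nib.load(atlas_img)
    gm = np.asarray(gm_img.dataobj, dtype=float)
    atlas = np.asarray(atlas_img.dataobj)
    atlas = np.rint(atlas).astype(int)
    if gm.shape != atlas.shape:
        raise ValueError(f"shape mismatch: map {gm.shape} vs atlas {atlas.shape}")
    bags = []
    for k in range(1, N_REGIONS + 1):
        vals = gm[atlas == k]
        if vals.size == 0:
            raise ValueError(f"atlas label {k} missing from atlas volume")
        bags.append(vals)
    return RegionalVoxelSet(subject_id, bags, region_labels or [])


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a Gaussian kernel."""
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        raise DegenerateSampleError("all values identical: zero bandwidth")
    return 0.9 * spread * n ** (-1 / 5)


def make_common_grid(
    region_values: list[np.ndarray], n_points: int = DEFAULT_GRID_POINTS
) -> np.ndarray:
    """One evaluation grid spanning a subject's pooled values.

    The span is extended by three times the largest regional bandwidth so
    that every region's kernel mass is covered by the shared support.
    """
    lo = min(float(v.min()) for v in region_values)
    hi = max(float(v.max()) for v in region_values)
    h = max(silverman_bandwidth(v) for v in region_values)
    return np.linspace(lo - 3 * h, hi + 3 * h, n_points)


def estimate_density(
    values: np.ndarray,
    grid: np.ndarray,
    region_label: str = "",
    bandwidth: float | None = None,
) -> DensityProfile:
    """Gaussian KDE on ``grid``, renormalised to a probability mass vector.

    Raises
    ------
    DegenerateSampleError
        If the sample has fewer than two distinct values (bandwidth 0).
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise DegenerateSampleError(
            f"region {region_label!r}: need >= 2 distinct values for a KDE"
        )
    h = silverman_bandwidth(values) if bandwidth is None else float(bandwidth)
    grid = np.asarray(grid, dtype=float)
    # evaluate the Gaussian kernel mixture on the grid
    z = (grid[:, None] - values[None, :]) / h
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (values.size * h * np.sqrt(2 * np.pi))
    total = dens.sum()
    if total <= 0:
        raise DegenerateSampleError(f"region {region_label!r}: zero density on grid")
    return DensityProfile(region_label, grid, dens / total, h)


def _floored_masses(p: np.ndarray) -> np.ndarray:
    q = np.maximum(p, MASS_FLOOR)
    return q / q.sum()


def _check_grids(p: DensityProfile, q: DensityProfile) -> None:
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
        raise GridMismatchError("density profiles are on different grids")


def kl_divergence(p: DensityProfile, q: DensityProfile) -> float:
    """Standard (asymmetric) KL divergence sum_i P_i log(P_i / Q_i).

    Masses are floored at ``MASS_FLOOR`` and renormalised before the logs,
    so the result is finite even for disjoint supports.
    """
    _check_grids(p, q)
    pm, qm = _floored_masses(p.probabilities), _floored_masses(q.probabilities)
    return float(np.sum(pm * (np.log(pm) - np.log(qm))))


def symmetric_kl(p: DensityProfile, q: DensityProfile) -> float:
    """Symmetric divergence: D_KL(P||Q) + D_KL(Q||P)."""
    return kl_divergence(p, q) + kl_divergence(q, p)


def kls(p: DensityProfile, q: DensityProfile) -> float:
    """KL-based similarity exp(-symmetric KL); 1 iff identical profiles."""
    return float(np.exp(-symmetric_kl(p, q)))


def _kls_matrix(masses: np.ndarray) -> np.ndarray:
    """Pairwise KLS for a stack of probability mass rows (regions x grid)."""
    pm = np.maximum(masses, MASS_FLOOR)
    pm /= pm.sum(axis=1, keepdims=True)
    logp = np.log(pm)
    self_term = np.sum(pm * logp, axis=1)  # sum_i P log P per region
    cross = pm @ logp.T  # cross[j, k] = sum_i P_j log P_k
    kl = self_term[:, None] - cross  # KL(P_j || P_k)
    sym = kl + kl.T
    w = np.exp(-sym)
    np.fill_diagonal(w, 0.0)
    return np.clip(w, 0.0, 1.0)


def build_network(
    subject: RegionalVoxelSet, n_grid: int = DEFAULT_GRID_POINTS
) -> MorphNetwork:
    """Construct the subject's 90 x 90 weighted undirected KLS network.

    All regional densities are evaluated on one shared grid so that every
    pair of profiles has common support; the diagonal is set to zero by
    convention.
    """
    try:
        grid = make_common_grid(subject.region_values, n_grid)
    except DegenerateSampleError as err:
        raise DegenerateSampleError(f"subject {subject.subject_id}: {err}") from err
    masses = np.empty((N_REGIONS, n_grid))
    for j, (lab, vals) in enumerate(
        zip(subject.region_labels, subject.region_values)
    ):
        masses[j] = estimate_density(vals, grid, lab).probabilities
    return MorphNetwork(subject.subject_id, _kls_matrix(masses), list(subject.region_labels))
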
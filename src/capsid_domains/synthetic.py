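"""Planted-structure toy assemblies for desk-scale validation.

Real capsids are large and must be downloaded; these generators build small
point assemblies with a known ("planted") quasi-rigid organisation — stiff
springs inside blocks, soft springs between them — so that every stage of
the pipeline (mode computation, strain minimization, order parameters) can
be exercised and checked against ground truth.  Toys use main-chain-only
networks (single-centroid backend) so their spectra are directly
analyzable; "proteins" are the planted blocks, enabling integrity and
interlocking tests without sequence data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .capsid_io import CHAIN_ALPHABET, CapsidStructure
from .enm import ElasticNetwork

#: default ratio of intra-block to inter-block spring strength
DEFAULT_CONTRAST = 100.0
#: fractional positional jitter relative to inter-point spacing
JITTER_FRACTION = 0.05


@dataclass
class ToyAssembly:
    """A synthetic assembly with its planted block structure."""

    structure: CapsidStructure
    network: ElasticNetwork
    planted_labels: np.ndarray
    stiffness_contrast: float
    trimer_labels: np.ndarray | None = None  # unit -> planted super-block

    @property
    def planted_q(self) -> int:
        return int(self.planted_labels.max()) + 1


def _structure_from_points(points: np.ndarray, block_labels: np.ndarray) -> CapsidStructure:
    """Pseudo-residue structure: one chain/protein per planted block."""
    points = np.asarray(points, dtype=float)
    block_labels = np.asarray(block_labels, dtype=int)
    n = len(points)
    chain_ids = [CHAIN_ALPHABET[b % len(CHAIN_ALPHABET)] for b in block_labels]
    resnum = np.zeros(n, dtype=int)
    for b in np.unique(block_labels):
        idx = np.flatnonzero(block_labels == b)
        resnum[idx] = np.arange(1, len(idx) + 1)
    return CapsidStructure(
        chain_ids=chain_ids,
        protein_ids=chain_ids.copy(),
        res_numbers=[str(r) for r in resnum],
        res_names=["ALA"] * n,
        main_coords=points,
        side_coords=np.full((n, 3), np.nan),
    )


def _network(points, pairs, strengths) -> ElasticNetwork:
    return ElasticNetwork(
        coords=np.asarray(points, float),
        pairs=np.asarray(pairs, int),
        strengths=np.asarray(strengths, float),
        n_mainchain=len(points),
        cutoff=np.inf,
    )


def _intra_pairs(indices: np.ndarray):
    idx = np.asarray(indices, int)
    a, b = np.triu_indices(len(idx), k=1)
    return np.column_stack([idx[a], idx[b]])


def _closest_cross_pairs(points, idx_a, idx_b, m: int):
    """The m closest point pairs between two blocks."""
    d = np.linalg.norm(points[idx_a][:, None] - points[idx_b][None, :], axis=2)
    flat = np.argsort(d, axis=None, kind="stable")[:m]
    ia, ib = np.unravel_index(flat, d.shape)
    return np.column_stack([np.asarray(idx_a)[ia], np.asarray(idx_b)[ib]])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_hinge_toy(contrast: float = DEFAULT_CONTRAST) -> ToyAssembly:
    """Two rigid triangles joined by a single soft hinge coupling.

    Six points: each triangle carries stiff springs on its three edges; one
    soft spring connects the two facing vertices.  The planted partition is
    the two triangles.  Note the single coupling leaves relative motions
    that do not stretch it at zero energy, so this toy has more than six
    null modes by construction; its one soft nonzero mode is the hinge
    stretch, along which intra-triangle distances are constant.
    """
    h = 5.0 * np.sqrt(3) / 2
    tri_a = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [2.5, h, 0.0]])
    tri_b = np.array([[9.0, 0.0, 0.0], [14.0, 0.0, 0.0], [11.5, h, 0.0]])
    points = np.vstack([tri_a, tri_b])
    pairs = np.vstack([_intra_pairs([0, 1, 2]), _intra_pairs([3, 4, 5]), [[1, 3]]])
    strengths = np.array([contrast] * 6 + [1.0])
    labels = np.array([0, 0, 0, 1, 1, 1])
    return ToyAssembly(
        structure=_structure_from_points(points, labels),
        network=_network(points, pairs, strengths),
        planted_labels=labels,
        stiffness_contrast=contrast,
    )


def make_ring_assembly(
    K: int,
    n: int,
    contrast: float = DEFAULT_CONTRAST,
    seed: int = 0,
    springs_per_contact: int = 9,
) -> ToyAssembly:
    """K jittered point clusters on a circle; stiff springs within clusters,
    soft springs between adjacent ones.  Reproducible from ``seed``."""
    if K < 2 or n < 3:
        raise ValueError("need K >= 2 blocks of n >= 3 points")
    rng = np.random.default_rng(seed)
    spacing = 8.0
    radius = K * spacing / (2 * np.pi)
    block_r = 2.5
    points = []
    labels = []
    for k in range(K):
        theta = 2 * np.pi * k / K
        center = radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        cluster = center + rng.uniform(-block_r, block_r, size=(n, 3))
        cluster += rng.normal(scale=JITTER_FRACTION * spacing, size=(n, 3))
        points.append(cluster)
        labels.extend([k] * n)
    points = np.vstack(points)
    labels = np.asarray(labels)

    pairs, strengths = [], []
    for k in range(K):
        idx = np.flatnonzero(labels == k)
        p = _intra_pairs(idx)
        pairs.append(p)
        strengths.append(np.full(len(p), contrast))
    for k in range(K):
        idx_a = np.flatnonzero(labels == k)
        idx_b = np.flatnonzero(labels == (k + 1) % K)
        p = _closest_cross_pairs(points, idx_a, idx_b, springs_per_contact)
        pairs.append(p)
        strengths.append(np.ones(len(p)))
    return ToyAssembly(
        structure=_structure_from_points(points, labels),
        network=_network(points, np.vstack(pairs), np.concatenate(strengths)),
        planted_labels=labels,
        stiffness_contrast=contrast,
    )


def icosahedral_rotations() -> np.ndarray:
    """The 60 proper rotation matrices of the icosahedral group, in a fixed
    deterministic order."""
    group = Rotation.create_group("I")
    mats = group.as_matrix()
    # sort lexicographically on rounded entries for a stable order
    order = np.lexsort(np.round(mats.reshape(60, 9), 9).T[::-1])
    return mats[order]


def _threefold_axes(rotations: np.ndarray) -> np.ndarray:
    """The 20 face-center directions (axes of the 120-degree rotations)."""
    dirs = []
    for R in rotations:
        rv = Rotation.from_matrix(R).as_rotvec()
        ang = np.linalg.norm(rv)
        if abs(ang - 2 * np.pi / 3) < 1e-6:
            dirs.append(rv / ang)
    dirs = np.asarray(dirs)
    uniq = []
    for d in dirs:
        if not any(np.allclose(d, u, atol=1e-6) for u in uniq):
            uniq.append(d)
    assert len(uniq) == 20
    return np.asarray(uniq)


def make_icosahedral_toy(
    points_per_unit: int,
    contrast: float = DEFAULT_CONTRAST,
    seed: int = 0,
    radius: float = 30.0,
    fuse_trimers: bool = False,
    trimer_contrast: float | None = None,
    springs_per_contact: int = 6,
) -> ToyAssembly:
    """One random asymmetric cluster replicated by the 60 icosahedral
    rotations on a sphere; stiff intra-unit springs, soft springs between
    nearest-neighbour units.

    With ``fuse_trimers`` the cross-unit springs inside each triple of units
    around a three-fold axis are made stiff (``trimer_contrast``, default
    equal to ``contrast``), planting 20 trimeric super-blocks — the
    organisation seen in small T=1 plant satellite viruses.
    """
    if points_per_unit < 3:
        raise ValueError("need at least 3 points per unit")
    rng = np.random.default_rng(seed)
    rotations = icosahedral_rotations()
    faces = _threefold_axes(rotations)

    # base unit centroid: tilted off a face center so the three copies
    # around that axis are distinct and form a natural trimer
    f0 = faces[0]
    ortho = np.cross(f0, [0.0, 0.0, 1.0])
    if np.linalg.norm(ortho) < 1e-6:
        ortho = np.cross(f0, [0.0, 1.0, 0.0])
    ortho /= np.linalg.norm(ortho)
    tilt = 0.30  # radians off the three-fold axis
    base_dir = np.cos(tilt) * f0 + np.sin(tilt) * ortho
    base_center = radius * base_dir
    unit_r = 3.0
    base = base_center + rng.uniform(-unit_r, unit_r, size=(points_per_unit, 3))

    points = np.vstack([base @ R.T for R in rotations])
    labels = np.repeat(np.arange(60), points_per_unit)
    centroids = np.array([points[labels == u].mean(axis=0) for u in range(60)])

    # trimer membership: nearest face-center direction
    cdirs = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    trimer_of = np.argmax(cdirs @ faces.T, axis=1)
    counts = np.bincount(trimer_of, minlength=20)
    assert np.all(counts == 3), "unit tilt does not yield 3 units per face"

    pairs, strengths = [], []
    for u in range(60):
        p = _intra_pairs(np.flatnonzero(labels == u))
        pairs.append(p)
        strengths.append(np.full(len(p), contrast))

    # nearest-neighbour unit contacts
    cdist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    np.fill_diagonal(cdist, np.inf)
    neighbor_cut = 1.5 * cdist.min()
    k_fuse = contrast if trimer_contrast is None else trimer_contrast
    for a in range(60):
        for b in range(a + 1, 60):
            same_trimer = trimer_of[a] == trimer_of[b]
            if cdist[a, b] >= neighbor_cut and not (fuse_trimers and same_trimer):
                continue
            p = _closest_cross_pairs(
                points, np.flatnonzero(labels == a), np.flatnonzero(labels == b),
                springs_per_contact,
            )
            k = k_fuse if (fuse_trimers and same_trimer) else 1.0
            pairs.append(p)
            strengths.append(np.full(len(p), k))

    return ToyAssembly(
        structure=_structure_from_points(points, labels),
        network=_network(points, np.vstack(pairs), np.concatenate(strengths)),
        planted_labels=labels,
        stiffness_contrast=contrast,
        trimer_labels=trimer_of,
    )


# ---------------------------------------------------------------------------
# agreement score
# ---------------------------------------------------------------------------

def match_score(partition, planted_labels: np.ndarray) -> float:
    """Maximum fraction of residues with agreeing labels over all injective
    mappings of found labels onto planted ones (exact optimal assignment)."""
    a = np.asarray(getattr(partition, "labels", partition), dtype=int)
    b = np.asarray(planted_labels, dtype=int)
    if a.shape != b.shape:
        raise ValueError("label vectors must cover the same residues")
    ua, ub = np.unique(a), np.unique(b)
    cont = np.zeros((len(ua), len(ub)))
    for i, la in enumerate(ua):
        mask = a == la
        for j, lb in enumerate(ub):
            cont[i, j] = np.sum(b[mask] == lb)
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / len(a))
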
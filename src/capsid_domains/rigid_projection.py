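"""Rigid/internal decomposition of modes over a domain partition.

Every displacement field splits uniquely into a component lying in the span
of per-domain rigid motions (3 translations + 3 linearized rotations per
domain, fewer for degenerate geometries) and an orthogonal remainder of
intra-domain deformation.  The 1/lambda-weighted share of the rigid
component over the retained modes — the captured-motion fraction — measures
how much of the assembly's mean-square fluctuation is explained by treating
the domains as strictly rigid bodies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capsid_io import CapsidStructure
from .enm import ModeSpectrum

#: singular values below this fraction of the largest are rank-deficient
RANK_TOLERANCE = 1e-10


@dataclass
class RigidBasis:
    """Orthonormal per-domain rigid-motion vectors.

    Stored compactly as (residue indices, basis matrix of shape
    (3*n_d, r<=6)) per domain; conceptually each basis vector is embedded in
    the full 3N space with zeros outside its domain, which makes vectors of
    different domains mutually orthogonal automatically.
    """

    domains: list[tuple[np.ndarray, np.ndarray]]
    n_residues: int

    @property
    def total_rank(self) -> int:
        return sum(b.shape[1] for _, b in self.domains)


def _domain_rigid_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of rigid motions of one point set (3n x r)."""
    n = len(coords)
    c = coords.mean(axis=0)
    xc = coords - c
    cols = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        cols.append(t.reshape(-1))
    for k in range(3):
        axis = np.zeros(3)
        axis[k] = 1.0
        cols.append(np.cross(axis, xc).reshape(-1))  # rotation about centroid
    A = np.column_stack(cols)
    # rank-revealing orthonormalization: collinear domains lose the rotation
    # about their line, singletons keep translations only
    u, s, _ = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(s > RANK_TOLERANCE * s[0]))
    return u[:, :rank]


def build_rigid_basis(structure: CapsidStructure, partition) -> RigidBasis:
    """Per-domain orthonormal rigid-motion bases for a partition (a
    :class:`~capsid_domains.decomposition.Partition` or a label array)."""
    labels = np.asarray(getattr(partition, "labels", partition), dtype=int)
    if len(labels) != structure.n_residues:
        raise ValueError("partition does not cover the structure")
    domains = []
    for d in np.unique(labels):
        idx = np.flatnonzero(labels == d)
        domains.append((idx, _domain_rigid_basis(structure.main_coords[idx])))
    return RigidBasis(domains=domains, n_residues=structure.n_residues)


def rigid_component_sq(mode: np.ndarray, basis: RigidBasis) -> float:
    """Squared norm of the projection of one (N, 3) mode onto the rigid
    subspace.  With unit-norm modes the internal share is 1 minus this."""
    total = 0.0
    for idx, b in basis.domains:
        seg = mode[idx].reshape(-1)
        total += float(np.sum((b.T @ seg) ** 2))
    return total


def captured_fraction(spectrum: ModeSpectrum, basis: RigidBasis) -> float:
    """Fraction of total mean-square fluctuation captured by rigid-like
    domain motion: sum_l (1/lambda_l) |P u_l|^2 / sum_l (1/lambda_l)."""
    if spectrum.n_residues != basis.n_residues:
        raise ValueError("spectrum and basis cover different residue sets")
    w = 1.0 / spectrum.eigenvalues
    rigid = np.array([rigid_component_sq(m, basis) for m in spectrum.modes])
    f = float(np.sum(w * rigid) / np.sum(w))
    if not -1e-9 <= f <= 1 + 1e-9:
        raise AssertionError(f"captured fraction {f} outside [0, 1]")
    return min(max(f, 0.0), 1.0)
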
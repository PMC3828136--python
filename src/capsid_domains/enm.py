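"""Elastic network construction and normal-mode computation.

The capsid's near-native free energy is approximated by a quadratic form
over centroid displacements.  Each pair of interaction centers within the
cutoff contributes a Tirion-style spring penalizing the change of the pair
distance, i.e. the 3x3 Hessian block k * e e^T built from the native unit
separation vector e.  The two-center (beta-Gaussian) variant places a
main-chain centroid (the alpha-carbon) and a side-chain centroid (centroid
of side-chain heavy atoms, absent for glycine) on every residue; side-chain
degrees of freedom are then eliminated analytically by a Schur complement,
so the effective interaction matrix acts on the 3N main-chain coordinates
only.  The low-energy eigenpairs of that matrix are the collective modes
used throughout the decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from scipy.spatial import cKDTree

from .capsid_io import CapsidStructure

logger = logging.getLogger("capsid_domains")

#: default interaction cutoff of the two-center model, Å
DEFAULT_CUTOFF = 7.5
#: cutoff used with decimated (one centroid per two residues) models, Å
DECIMATED_CUTOFF = 15.0
#: eigenvalues below this fraction of the stiffness scale (the largest
#: Hessian diagonal entry) are treated as null (rigid-body) modes; numerical
#: nulls sit around 1e-12 of that scale, physical soft modes far above it
NULL_TOLERANCE = 1e-9
#: minimum retained mode count when selecting M from a reference protein
DEFAULT_MODE_FLOOR = 10

#: problems with at most this many total degrees of freedom are solved densely
_DENSE_DOF_LIMIT = 1500


class NetworkError(ValueError):
    """Raised for degenerate or disconnected elastic networks."""


@dataclass
class ElasticNetwork:
    """Centroids plus quadratic pair couplings.

    Centroid order: the ``n_mainchain`` main-chain centroids first (in
    residue order), then side-chain centroids; ``side_owner[j]`` is the
    residue index owning side centroid ``n_mainchain + j``.
    """

    coords: np.ndarray          # (n_centroids, 3) Å
    pairs: np.ndarray           # (E, 2) int, centroid indices
    strengths: np.ndarray       # (E,) spring constants, energy/Å^2
    n_mainchain: int
    side_owner: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.strengths = np.asarray(self.strengths, dtype=float).reshape(-1)
        self.side_owner = np.asarray(self.side_owner, dtype=int).reshape(-1)
        if len(self.pairs) != len(self.strengths):
            raise NetworkError("pair/strength length mismatch")
        if len(self.pairs) == 0:
            raise NetworkError("network has no couplings")
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise NetworkError("self-coupling in pair list")

    @property
    def n_centroids(self) -> int:
        return len(self.coords)

    @property
    def n_side(self) -> int:
        return self.n_centroids - self.n_mainchain

    def n_components(self) -> int:
        adj = sp.coo_matrix(
            (np.ones(len(self.pairs)), (self.pairs[:, 0], self.pairs[:, 1])),
            shape=(self.n_centroids, self.n_centroids),
        )
        n, _ = connected_components(adj, directed=False)
        return n


@dataclass
class ModeSpectrum:
    """Ascending nonzero eigenvalues and orthonormal mode vectors.

    ``modes[l]`` is the (N, 3) displacement field of mode ``l`` over the
    main-chain centroids, normalized to unit Euclidean norm; mean-square
    fluctuation along mode ``l`` is proportional to ``1/eigenvalues[l]``.
    """

    eigenvalues: np.ndarray    # (M,) ascending, > 0
    modes: np.ndarray          # (M, N, 3)
    n_null: int

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).reshape(-1)
        self.modes = np.asarray(self.modes, dtype=float)
        if self.modes.ndim != 3 or self.modes.shape[0] != len(self.eigenvalues):
            raise ValueError("modes array must be (M, N, 3)")
        if np.any(np.diff(self.eigenvalues) < -1e-12):
            raise ValueError("eigenvalues must be ascending")

    @property
    def M(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_residues(self) -> int:
        return self.modes.shape[1]

    def truncate(self, M: int) -> "ModeSpectrum":
        """Spectrum restricted to the lowest ``M`` modes."""
        if not 1 <= M <= self.M:
            raise ValueError(f"cannot retain {M} of {self.M} modes")
        return ModeSpectrum(self.eigenvalues[:M], self.modes[:M], self.n_null)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_beta_gaussian(
    structure: CapsidStructure,
    cutoff: float = DEFAULT_CUTOFF,
    backbone_bonus: float = 1.0,
    spring_strength: float = 1.0,
) -> ElasticNetwork:
    """Build the two-center elastic network of a structure.

    All centroid pairs (main-main, main-side, side-side) within ``cutoff``
    are coupled with uniform strength; consecutive main-chain centroids of
    the same chain are always coupled, with strength multiplied by
    ``backbone_bonus``.  Glycine contributes no side centroid.
    """
    if structure.n_residues < 2:
        raise NetworkError("need at least 2 residues")
    if cutoff <= 0:
        raise NetworkError("cutoff must be positive")

    n = structure.n_residues
    has_side = structure.has_side
    side_owner = np.flatnonzero(has_side)
    coords = np.vstack([structure.main_coords, structure.side_coords[side_owner]])

    tree = cKDTree(coords)
    pair_set = tree.query_pairs(cutoff, output_type="ndarray")
    strengths = np.full(len(pair_set), float(spring_strength))

    # consecutive main-chain pairs within a protein: always present,
    # strength scaled by the backbone bonus
    bb_pairs = []
    for idx in structure.proteins.values():
        bb_pairs.extend(zip(idx[:-1], idx[1:]))
    bb_pairs = np.asarray(bb_pairs, dtype=int).reshape(-1, 2)
    if len(bb_pairs):
        key = {tuple(sorted(p)) for p in bb_pairs.tolist()}
        is_bb = np.array(
            [tuple(sorted(p)) in key for p in pair_set.tolist()], dtype=bool
        ) if len(pair_set) else np.zeros(0, bool)
        strengths[is_bb] = spring_strength * backbone_bonus
        have = {tuple(sorted(p)) for p in pair_set[is_bb].tolist()}
        extra = np.array([p for p in key if p not in have], dtype=int).reshape(-1, 2)
        if len(extra):
            pair_set = np.vstack([pair_set, extra])
            strengths = np.concatenate(
                [strengths, np.full(len(extra), spring_strength * backbone_bonus)]
            )

    if len(pair_set) == 0:
        raise NetworkError("no couplings within cutoff")
    net = ElasticNetwork(
        coords=coords,
        pairs=pair_set,
        strengths=strengths,
        n_mainchain=n,
        side_owner=side_owner,
        cutoff=cutoff,
    )
    ncomp = net.n_components()
    if ncomp > 1:
        logger.warning(
            "elastic network has %d connected components; the spectrum will "
            "contain extra null modes", ncomp,
        )
    return net


def subnetwork(network: ElasticNetwork, residues: np.ndarray) -> ElasticNetwork:
    """Restrict a network to a residue subset, keeping couplings whose two
    centroids are both owned by retained residues."""
    residues = np.asarray(residues, dtype=int)
    keep_main = np.zeros(network.n_mainchain, dtype=bool)
    keep_main[residues] = True
    keep_side = keep_main[network.side_owner] if network.n_side else np.zeros(0, bool)
    keep = np.concatenate([keep_main, keep_side])
    new_index = -np.ones(network.n_centroids, dtype=int)
    new_index[keep] = np.arange(keep.sum())
    mask = keep[network.pairs[:, 0]] & keep[network.pairs[:, 1]]
    if not mask.any():
        raise NetworkError("residue subset has no internal couplings")
    return ElasticNetwork(
        coords=network.coords[keep],
        pairs=new_index[network.pairs[mask]],
        strengths=network.strengths[mask],
        n_mainchain=int(keep_main.sum()),
        side_owner=new_index[network.side_owner[keep_side]] - int(keep_main.sum())
        if network.n_side
        else np.empty(0, dtype=int),
        cutoff=network.cutoff,
    )


# ---------------------------------------------------------------------------
# Hessian assembly and side-chain elimination
# ---------------------------------------------------------------------------

def hessian(network: ElasticNetwork) -> sp.csr_matrix:
    """Sparse Hessian of the quadratic energy over all centroids (3n x 3n)."""
    i, j = network.pairs[:, 0], network.pairs[:, 1]
    d = network.coords[j] - network.coords[i]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-10):
        raise NetworkError("coincident centroids in coupled pair")
    e = d / r[:, None]
    blocks = network.strengths[:, None, None] * e[:, :, None] * e[:, None, :]

    off = np.arange(3)

    def _block_indices(base_r, base_c):
        r = (3 * base_r)[:, None, None] + off[None, :, None]
        c = (3 * base_c)[:, None, None] + off[None, None, :]
        return np.broadcast_to(r, blocks.shape), np.broadcast_to(c, blocks.shape)

    rows_l, cols_l, vals_l = [], [], []
    # (ii, jj) diagonal blocks +B, (ij, ji) off-diagonal -B
    for base_r, base_c, sign in ((i, i, 1), (j, j, 1), (i, j, -1), (j, i, -1)):
        r, c = _block_indices(base_r, base_c)
        rows_l.append(r.reshape(-1))
        cols_l.append(c.reshape(-1))
        vals_l.append(sign * blocks.reshape(-1))
    rows = np.concatenate(rows_l)
    cols = np.concatenate(cols_l)
    vals = np.concatenate(vals_l)
    n3 = 3 * network.n_centroids
    H = sp.coo_matrix((vals, (rows, cols)), shape=(n3, n3)).tocsr()
    return (H + H.T) * 0.5


def effective_mainchain_matrix(network: ElasticNetwork) -> np.ndarray:
    """Dense effective interaction matrix over the 3N main-chain coordinates.

    Returns the Schur complement H_mm - H_ms H_ss^{-1} H_sm of the full
    two-center Hessian after eliminating side-chain coordinates; for a
    network without side centroids this is the main-chain Hessian itself.
    Symmetric positive semi-definite; its null space contains the six global
    rigid motions.
    """
    H = hessian(network)
    nm = 3 * network.n_mainchain
    if network.n_side == 0:
        return H.toarray()
    # every side centroid must be coupled
    touched = np.zeros(network.n_centroids, dtype=bool)
    touched[network.pairs.reshape(-1)] = True
    lonely = np.flatnonzero(~touched[network.n_mainchain:])
    if len(lonely):
        owners = network.side_owner[lonely]
        raise NetworkError(
            f"isolated side centroid(s) for residue index {owners.tolist()}: "
            "side-chain block is singular"
        )
    Hd = H.toarray()
    Hmm = Hd[:nm, :nm]
    Hms = Hd[:nm, nm:]
    Hss = Hd[nm:, nm:]
    try:
        X = scipy.linalg.solve(Hss, Hms.T, assume_a="pos")
    except scipy.linalg.LinAlgError as exc:
        raise NetworkError(f"singular side-chain block: {exc}") from exc
    Heff = Hmm - Hms @ X
    return (Heff + Heff.T) * 0.5


# ---------------------------------------------------------------------------
# mode computation
# ---------------------------------------------------------------------------

def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-magnitude entry of each mode positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def _split_null(eigvals, eigvecs, scale):
    tol = NULL_TOLERANCE * max(scale, 1e-300)
    nz = eigvals > tol
    return eigvals[nz], eigvecs[:, nz], int(np.sum(~nz))


def compute_modes(
    network: ElasticNetwork, n_modes: int, method: str = "auto"
) -> ModeSpectrum:
    """Lowest ``n_modes`` nonzero eigenpairs of the effective main-chain
    interaction matrix.

    Small problems are solved by dense diagonalization of the Schur
    complement; larger ones by shift-invert Lanczos on the equivalent sparse
    generalized eigenproblem ``H z = lambda B z`` with ``B`` the projector
    onto main-chain coordinates (whose main-chain restriction reproduces the
    Schur-complement eigenpairs without densifying it).  ``method`` forces
    one backend ("dense"/"sparse") instead of the size-based "auto" choice.
    Deterministic up to eigenvector sign.
    """
    nm_dof = 3 * network.n_mainchain
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if n_modes > nm_dof - 1:
        raise ValueError(f"n_modes={n_modes} too large for {nm_dof} main-chain DOFs")
    if n_modes > nm_dof - 6:
        logger.warning(
            "n_modes=%d leaves no room for 6 rigid modes in %d DOFs; "
            "fewer nonzero modes may be returned", n_modes, nm_dof,
        )
    if method not in ("auto", "dense", "sparse"):
        raise ValueError(f"unknown method {method!r}")

    n_dof = 3 * network.n_centroids
    if method == "dense" or (method == "auto" and n_dof <= _DENSE_DOF_LIMIT):
        return _dense_modes(network, n_modes)
    if n_modes + 6 >= nm_dof:  # ARPACK needs k < n; fall back
        return _dense_modes(network, n_modes)

    H = hessian(network)
    diag_b = np.zeros(n_dof)
    diag_b[:nm_dof] = 1.0
    B = sp.diags(diag_b).tocsc()
    scale = H.diagonal().max()
    sigma = -1e-4 * scale
    v0 = np.ones(n_dof) / np.sqrt(n_dof)

    k = min(n_modes + 6, nm_dof - 1)
    while True:
        try:
            vals, vecs = eigsh(
                H.tocsc(), k=k, M=B, sigma=sigma, which="LM", mode="normal", v0=v0
            )
        except Exception as exc:  # ARPACK failures carry diagnostics
            raise NetworkError(f"sparse eigensolver failed: {exc}") from exc
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
        vals = np.maximum(vals, 0.0)
        nz_vals, nz_vecs, n_null = _split_null(vals, vecs, scale)
        if len(nz_vals) >= n_modes or k >= nm_dof - 1:
            break
        k = min(n_modes + n_null + 2, nm_dof - 1)

    if len(nz_vals) < n_modes:
        logger.warning(
            "only %d nonzero modes available (requested %d)", len(nz_vals), n_modes
        )
    nz_vals, nz_vecs = nz_vals[:n_modes], nz_vecs[:, :n_modes]
    main = nz_vecs[:nm_dof]
    # eigsh returns B-orthonormal vectors: main-chain parts are orthonormal
    main = _fix_signs(main)
    return ModeSpectrum(
        eigenvalues=nz_vals,
        modes=main.T.reshape(-1, network.n_mainchain, 3),
        n_null=n_null,
    )


def _dense_modes(network: ElasticNetwork, n_modes: int) -> ModeSpectrum:
    Heff = effective_mainchain_matrix(network)
    scale = hessian(network).diagonal().max()
    vals, vecs = scipy.linalg.eigh(Heff)
    vals = np.maximum(vals, 0.0)
    nz_vals, nz_vecs, n_null = _split_null(vals, vecs, scale)
    if len(nz_vals) < n_modes:
        logger.warning(
            "only %d nonzero modes available (requested %d)", len(nz_vals), n_modes
        )
        n_modes = len(nz_vals)
    vecs = _fix_signs(nz_vecs[:, :n_modes])
    return ModeSpectrum(
        eigenvalues=nz_vals[:n_modes],
        modes=vecs.T.reshape(-1, network.n_mainchain, 3),
        n_null=n_null,
    )


def select_mode_count(
    capsid_spectrum: ModeSpectrum,
    protein_spectrum: ModeSpectrum,
    floor: int = DEFAULT_MODE_FLOOR,
) -> int:
    """Number of capsid modes to retain for strain computation.

    All capsid modes with energy strictly below the fifth nonzero mode of a
    single coat protein are kept, floored at ``floor`` (and capped at the
    number of computed capsid modes).
    """
    if protein_spectrum.M < 5:
        raise ValueError("reference protein spectrum must have >= 5 nonzero modes")
    threshold = protein_spectrum.eigenvalues[4]
    M = int(np.sum(capsid_spectrum.eigenvalues < threshold))
    if M < floor:
        logger.warning(
            "only %d capsid modes below the single-protein threshold; "
            "flooring the retained count at %d", M, floor,
        )
        M = floor
    M = min(M, capsid_spectrum.M)
    return M


def single_protein_spectrum(
    structure: CapsidStructure,
    protein_id: str | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    backbone_bonus: float = 1.0,
    n_modes: int = 5,
) -> ModeSpectrum:
    """Mode spectrum of one isolated coat protein (default: the first),
    built with the same model settings as the full capsid."""
    pid = protein_id if protein_id is not None else next(iter(structure.proteins))
    sub = structure.extract_protein(pid)
    net = build_beta_gaussian(sub, cutoff=cutoff, backbone_bonus=backbone_bonus)
    return compute_modes(net, n_modes)
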
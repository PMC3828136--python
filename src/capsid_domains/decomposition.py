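"""Strain-minimizing partition of residues into quasi-rigid domains.

A group of residues moving as a rigid body keeps all of its internal
pairwise distances fixed.  The geometric strain of a residue pair measures,
over the retained low-energy modes, the mean-square fluctuation of the
projection of the pair's relative displacement onto its native separation
direction — exactly the first-order change of the pair distance.  A
partition into Q domains is scored by the sum of pair strains over all
intra-domain pairs, and for each Q the labelling minimizing that total is
sought by a stochastic greedy search with a split/join refinement that
escapes strongly asymmetric local minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .capsid_io import CapsidStructure
from .enm import ModeSpectrum

logger = logging.getLogger("capsid_domains")

DEFAULT_RESTARTS = 5
DEFAULT_OUTLIER_K = 2.0
DEFAULT_MAX_REFINE_ITER = 10


@dataclass
class Partition:
    """Residue -> domain assignment for a fixed Q, with its strain."""

    labels: np.ndarray            # (N,) ints in 0..Q-1
    Q: int
    per_domain_strain: np.ndarray # (Q,)
    total_strain: float
    seed: int | None = None
    restarts: int = 1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.per_domain_strain = np.asarray(self.per_domain_strain, dtype=float)
        counts = np.bincount(self.labels, minlength=self.Q)
        if len(np.flatnonzero(counts)) != self.Q or self.labels.max() >= self.Q:
            raise ValueError(f"labels do not form exactly {self.Q} nonempty domains")
        tot = float(self.per_domain_strain.sum())
        if not np.isclose(tot, self.total_strain, rtol=1e-9, atol=1e-12):
            raise ValueError("total_strain does not match per-domain sum")


@dataclass
class StrainProfile:
    """Best partition found at each swept Q."""

    partitions: dict[int, Partition]

    @property
    def q_values(self) -> np.ndarray:
        return np.array(sorted(self.partitions), dtype=int)

    @property
    def strains(self) -> np.ndarray:
        return np.array(
            [self.partitions[q].total_strain for q in sorted(self.partitions)]
        )


# ---------------------------------------------------------------------------
# pair strain
# ---------------------------------------------------------------------------

def pair_strain(
    spectrum: ModeSpectrum, structure: CapsidStructure, i: int, j: int
) -> float:
    """Geometric strain of residue pair (i, j) over the retained modes:
    sum_l (1/lambda_l) [e_ij . (u_l,i - u_l,j)]^2 with e_ij the unit native
    separation vector.  Symmetric, nonnegative, zero for co-rigid pairs."""
    if i == j:
        raise ValueError("pair strain requires two distinct residues")
    d = structure.main_coords[j] - structure.main_coords[i]
    r = np.linalg.norm(d)
    if r < 1e-10:
        raise ValueError(f"residues {i} and {j} have coincident native positions")
    e = d / r
    rel = spectrum.modes[:, i, :] - spectrum.modes[:, j, :]  # (M, 3)
    proj = rel @ e
    return float(np.sum(proj**2 / spectrum.eigenvalues))


def strain_matrix(
    spectrum: ModeSpectrum,
    structure: CapsidStructure,
    pair_cutoff: float | None = None,
    block: int = 512,
) -> np.ndarray:
    """Dense (N, N) matrix of pair strains; diagonal zero.

    ``pair_cutoff`` (Å) truncates the pair set to residues within that
    native distance (entries beyond it are set to zero) — a documented
    approximation for very large capsids; by default all pairs are kept.
    """
    x = structure.main_coords
    n = len(x)
    # amplitude-weighted per-residue mode matrices V_i (M, 3)
    V = spectrum.modes / np.sqrt(spectrum.eigenvalues)[:, None, None]
    A = np.einsum("mia,mib->iab", V, V)                # (n, 3, 3) Gram diagonals
    F = np.zeros((n, n))
    for a in range(0, n, block):
        sl = slice(a, min(a + block, n))
        d = x[sl, None, :] - x[None, :, :]            # (b, n, 3)
        r = np.linalg.norm(d, axis=2)
        np.clip(r, 1e-12, None, out=r)
        e = d / r[:, :, None]
        # rel_lij = V_l,i - V_l,j for i in block: (M, b, n, 3) is too big;
        # contract over modes instead: F_ij = e^T (A_i + A_j - C_ij - C_ij^T) e
        # with A_i = V_i^T V_i and C_ij = V_i^T V_j.
        Vi = V[:, sl, :]                               # (M, b, 3)
        Ai = A[sl]                                     # (b, 3, 3)
        C = np.einsum("mia,mjb->ijab", Vi, V)          # (b, n, 3, 3)
        S = Ai[:, None] + A[None, :] - C - np.swapaxes(C, 2, 3)
        F[sl] = np.einsum("ija,ijab,ijb->ij", e, S, e)
    np.fill_diagonal(F, 0.0)
    F = np.maximum(F, 0.0)
    F = (F + F.T) * 0.5
    if pair_cutoff is not None:
        d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
        F[d > pair_cutoff] = 0.0
    return F


def partition_strain(labels: np.ndarray, F: np.ndarray, Q: int | None = None):
    """(total, per-domain strain array) of a labelling under pair-strain
    matrix ``F``.  Per-domain strain sums strains over all unordered
    intra-domain pairs; singleton domains contribute zero."""
    labels = np.asarray(labels, dtype=int)
    Q = int(labels.max()) + 1 if Q is None else Q
    per = np.zeros(Q)
    for d in range(Q):
        idx = np.flatnonzero(labels == d)
        if len(idx) > 1:
            per[d] = F[np.ix_(idx, idx)].sum() * 0.5
    return float(per.sum()), per


# ---------------------------------------------------------------------------
# greedy minimization
# ---------------------------------------------------------------------------

def _greedy_pass(
    labels: np.ndarray,
    F: np.ndarray,
    rng: np.random.Generator,
    trace: list | None = None,
) -> np.ndarray:
    """One greedy minimization run from the given labelling (in place-safe).

    Repeatedly proposes moving a random residue to a random other domain and
    accepts only strict strain decreases that keep every domain nonempty;
    stops once the count of consecutive rejections reaches the residue
    count.  Uses the per-residue/per-domain strain-sum table S[r, d] =
    sum_{j in d} F[r, j] so a proposal costs O(1) and an accepted move O(N).
    """
    labels = np.asarray(labels, dtype=int).copy()
    n = len(labels)
    Q = int(labels.max()) + 1
    S = np.zeros((n, Q))
    for d in range(Q):
        members = labels == d
        if members.any():
            S[:, d] = F[:, members].sum(axis=1)
    sizes = np.bincount(labels, minlength=Q)
    if trace is not None:
        trace.append(partition_strain(labels, F, Q)[0])

    def _move(r, a, b):
        labels[r] = b
        sizes[a] -= 1
        sizes[b] += 1
        col = F[:, r]
        S[:, a] -= col
        S[:, b] += col
        if trace is not None:
            trace.append(partition_strain(labels, F, Q)[0])

    rejections = 0
    while rejections < n:
        r = int(rng.integers(n))
        a = labels[r]
        b = int(rng.integers(Q - 1))
        if b >= a:
            b += 1
        # strict decrease only; never empty a domain
        if sizes[a] > 1 and S[r, b] - S[r, a] < 0.0:
            _move(r, a, b)
            rejections = 0
        else:
            rejections += 1

    # systematic verification: with random proposals, n consecutive
    # rejections can occur while improving moves remain, so confirm local
    # optimality by a vectorized scan over all (residue, domain) moves and
    # descend until none improves
    tiny = 1e-12 * max(float(F.max()), 1.0)
    while True:
        delta = S - S[np.arange(n), labels][:, None]
        delta[sizes[labels] <= 1] = 0.0  # moves that would empty a domain
        r, b = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[r, b] >= -tiny:
            break
        _move(int(r), labels[r], int(b))
    return labels


def _random_labels(n: int, Q: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random labelling guaranteed to have Q nonempty domains."""
    labels = rng.integers(Q, size=n)
    anchors = rng.choice(n, size=Q, replace=False)
    labels[anchors] = np.arange(Q)
    return labels


def greedy_minimize(
    spectrum: ModeSpectrum,
    structure: CapsidStructure,
    Q: int,
    seed: int,
    strain: np.ndarray | None = None,
    trace: list | None = None,
) -> Partition:
    """Greedy strain minimization at fixed Q from a random initial labelling.

    Fully reproducible from ``seed``.  ``strain`` may pass a precomputed
    :func:`strain_matrix` to amortize it across calls; ``trace`` collects
    the total strain after every accepted move (for diagnostics).
    """
    n = structure.n_residues
    if not 2 <= Q <= n:
        raise ValueError(f"Q={Q} out of range [2, {n}]")
    F = strain_matrix(spectrum, structure) if strain is None else strain
    rng = np.random.default_rng(seed)
    labels = _greedy_pass(_random_labels(n, Q, rng), F, rng, trace=trace)
    total, per = partition_strain(labels, F, Q)
    return Partition(labels=labels, Q=Q, per_domain_strain=per,
                     total_strain=total, seed=seed)


# ---------------------------------------------------------------------------
# split/join refinement
# ---------------------------------------------------------------------------

def _split_by_principal_plane(
    idx: np.ndarray, coords: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bisect a domain by the plane through its centroid normal to its
    principal spatial axis; degenerate cases fall back to a median split."""
    x = coords[idx]
    c = x.mean(axis=0)
    xc = x - c
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    side = xc @ vt[0] > 0.0
    if side.all() or not side.any():
        order = np.argsort(xc @ vt[0])
        side = np.zeros(len(idx), dtype=bool)
        side[order[len(idx) // 2:]] = True
    return idx[~side], idx[side]


def refine_split_join(
    partition: Partition,
    spectrum: ModeSpectrum,
    structure: CapsidStructure,
    outlier_k: float = DEFAULT_OUTLIER_K,
    max_iter: int = DEFAULT_MAX_REFINE_ITER,
    strain: np.ndarray | None = None,
    seed: int | None = None,
) -> Partition:
    """Escape asymmetric local minima by joining the two lowest-strain
    domains and splitting the highest-strain one, then re-running the greedy
    pass.  Triggered while some domain's strain exceeds mean + outlier_k*SD
    of the domain strains; Q is preserved; stops on homogeneity,
    non-improvement or ``max_iter``.  Never returns a worse partition.
    """
    F = strain_matrix(spectrum, structure) if strain is None else strain
    rng = np.random.default_rng(partition.seed if seed is None else seed)
    best = partition
    for _ in range(max_iter):
        per = best.per_domain_strain
        if best.Q < 2:
            break
        mu, sd = per.mean(), per.std()
        if per.max() <= mu + outlier_k * sd:
            break  # homogeneous strain distribution
        order = np.argsort(per)
        lo1, lo2 = order[0], order[1]
        hi = order[-1]
        labels = best.labels.copy()
        labels[labels == lo2] = lo1
        part_a, part_b = _split_by_principal_plane(
            np.flatnonzero(labels == hi), structure.main_coords, rng
        )
        labels[part_b] = lo2
        labels = _greedy_pass(labels, F, rng)
        total, per_new = partition_strain(labels, F, best.Q)
        if total < best.total_strain:
            best = Partition(labels=labels, Q=best.Q, per_domain_strain=per_new,
                             total_strain=total, seed=best.seed,
                             restarts=best.restarts)
        else:
            break  # split/join no longer improves
    return best


# ---------------------------------------------------------------------------
# sweep over Q
# ---------------------------------------------------------------------------

def sweep(
    spectrum: ModeSpectrum,
    structure: CapsidStructure,
    q_min: int,
    q_max: int,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    q_values=None,
    strain: np.ndarray | None = None,
    outlier_k: float = DEFAULT_OUTLIER_K,
) -> StrainProfile:
    """Minimize strain at every Q in [q_min, q_max] (or an explicit
    ``q_values`` grid), keeping the best of ``restarts`` independent
    greedy+refine chains per Q.  Deterministic given the master seed."""
    if q_values is None:
        if not 2 <= q_min <= q_max:
            raise ValueError("need 2 <= q_min <= q_max")
        q_values = range(q_min, q_max + 1)
    q_values = sorted(int(q) for q in q_values)
    F = strain_matrix(spectrum, structure) if strain is None else strain
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(q_values) * restarts)
    out: dict[int, Partition] = {}
    for qi, Q in enumerate(q_values):
        best = None
        for r in range(restarts):
            child_seed = int(children[qi * restarts + r].generate_state(1)[0] % (2**31))
            part = greedy_minimize(spectrum, structure, Q, child_seed, strain=F)
            part = refine_split_join(part, spectrum, structure,
                                     outlier_k=outlier_k, strain=F)
            if best is None or part.total_strain < best.total_strain:
                best = part
        best.restarts = restarts
        out[Q] = best
        logger.info("Q=%d: strain %.6g", Q, best.total_strain)
    return StrainProfile(partitions=out)
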
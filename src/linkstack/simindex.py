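"""The twelve topological similarity indices used as link features.

Local indices (CN, PA, AA, LHN, RA) use only neighborhoods and degrees;
global indices (ACT, MFI, RWR, SimRank) use whole-graph structure; and
quasi-local indices (LP, LRW, SRW) use bounded-length paths or walks.

All indices are symmetric in the node pair and are returned both as scalars
for a single pair and as dense N x N matrices.  Diagonal entries are stored
as 0 (pairs with i == j are never scored), with the single exception of
SimRank whose recursion fixes s(v, v) = 1.

The canonical feature ordering, which defines feature-column identity for
everything downstream, is :data:`INDEX_NAMES`:
``[CN, PA, AA, LHN, RA, ACT, MFI, RWR, SimRank, LP, LRW, SRW]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graphio import Network

logger = logging.getLogger(__name__)

INDEX_NAMES = [
    "CN",
    "PA",
    "AA",
    "LHN",
    "RA",
    "ACT",
    "MFI",
    "RWR",
    "SimRank",
    "LP",
    "LRW",
    "SRW",
]

__all__ = [
    "INDEX_NAMES",
    "IndexParams",
    "SimilarityMatrix",
    "cn",
    "pa",
    "aa",
    "lhn",
    "ra",
    "act",
    "cn_matrix",
    "pa_matrix",
    "aa_matrix",
    "lhn_matrix",
    "ra_matrix",
    "act_matrix",
    "mfi",
    "rwr",
    "simrank",
    "lp",
    "lrw",
    "srw",
    "compute_all_indices",
]


@dataclass(frozen=True)
class IndexParams:
    """Tunable parameters of the similarity indices.

    aa_log_base   log base of the Adamic-Adar weight 1/log k; any fixed base
                  rescales scores by a constant and leaves rankings unchanged.
    mfi_alpha     forest-accumulation weight of the matrix-forest index
                  (I + alpha*L)^-1; alpha=1 is the classical index.
    rwr_restart_c continuation probability c of the random walk with restart
                  (the walker teleports home with probability 1-c).
    simrank_decay_C  attenuation of the SimRank recursion.
    lp_alpha      weight of length-3 paths in the local-path index.
    walk_steps_t  step count of the local / superposed random walks.
    """

    aa_log_base: str = "natural"  # natural | log10 | log2
    mfi_alpha: float = 1.0
    rwr_restart_c: float = 0.85
    simrank_decay_C: float = 0.8
    simrank_tol: float = 1e-4
    simrank_max_iter: int = 100
    lp_alpha: float = 0.001
    walk_steps_t: int = 3
    linear_solve_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.aa_log_base not in ("natural", "log10", "log2"):
            raise ValueError(f"unknown aa_log_base {self.aa_log_base!r}")
        if not (0.0 < self.rwr_restart_c < 1.0):
            raise ValueError("rwr_restart_c must be in (0, 1)")
        if not (0.0 < self.simrank_decay_C < 1.0):
            raise ValueError("simrank_decay_C must be in (0, 1)")
        if self.mfi_alpha <= 0:
            raise ValueError("mfi_alpha must be > 0")
        if self.walk_steps_t < 1:
            raise ValueError("walk_steps_t must be >= 1")
        if self.simrank_tol <= 0 or self.linear_solve_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class SimilarityMatrix:
    """A named, symmetric all-pairs score matrix with its parameter snapshot."""

    index_name: str
    values: np.ndarray
    params_used: IndexParams = field(default_factory=IndexParams)
    converged: bool = True

    def score(self, i: int, j: int) -> float:
        return float(self.values[i, j])


def _log(x: np.ndarray | float, base: str) -> np.ndarray | float:
    if base == "natural":
        return np.log(x)
    if base == "log10":
        return np.log10(x)
    return np.log2(x)


def _check_pair(net: Network, i: int, j: int) -> None:
    if i == j:
        raise ValueError("similarity is undefined for i == j")
    if not (0 <= i < net.N and 0 <= j < net.N):
        raise ValueError(f"node index out of range for N={net.N}")


def _zero_diag(m: np.ndarray) -> np.ndarray:
    np.fill_diagonal(m, 0.0)
    return m


# ---------------------------------------------------------------------------
# Local indices: pairwise forms
# ---------------------------------------------------------------------------

def cn(net: Network, i: int, j: int) -> int:
    """Common-neighbor count |Gamma(i) & Gamma(j)|."""
    _check_pair(net, i, j)
    return len(net.neighbors(i) & net.neighbors(j))


def pa(net: Network, i: int, j: int) -> float:
    """Preferential attachment k(i) * k(j)."""
    _check_pair(net, i, j)
    k = net.degrees()
    return float(k[i] * k[j])


def aa(net: Network, i: int, j: int, params: IndexParams = IndexParams()) -> float:
    """Adamic-Adar: common neighbors weighted by 1/log(degree)."""
    _check_pair(net, i, j)
    k = net.degrees()
    common = net.neighbors(i) & net.neighbors(j)
    # A common neighbor has degree >= 2, so log k(l) > 0 and the sum is finite.
    return float(sum(1.0 / _log(float(k[l]), params.aa_log_base) for l in common))


def lhn(net: Network, i: int, j: int) -> float:
    """Leicht-Holme-Newman: CN / (k(i)*k(j)); 0 when there are no common neighbors."""
    _check_pair(net, i, j)
    c = cn(net, i, j)
    if c == 0:
        return 0.0
    k = net.degrees()
    return c / float(k[i] * k[j])


def ra(net: Network, i: int, j: int) -> float:
    """Resource allocation: common neighbors weighted by 1/degree."""
    _check_pair(net, i, j)
    k = net.degrees()
    return float(sum(1.0 / k[l] for l in net.neighbors(i) & net.neighbors(j)))


def act(net: Network, i: int, j: int, params: IndexParams = IndexParams()) -> float:
    """Average-commute-time similarity 1 / (l+_ii + l+_jj - 2 l+_ij).

    Pairs with an isolated endpoint score 0 (no walk ever commutes).
    """
    _check_pair(net, i, j)
    v = net.views()
    if v.degree_vector[i] == 0 or v.degree_vector[j] == 0:
        return 0.0
    lp_ = v.laplacian_pinv
    denom = lp_[i, i] + lp_[j, j] - 2.0 * lp_[i, j]
    if denom <= params.linear_solve_tol:
        logger.warning("ACT denominator %g <= tol for pair (%d,%d); returning 0", denom, i, j)
        return 0.0
    return float(1.0 / denom)


# ---------------------------------------------------------------------------
# All-pairs matrices
# ---------------------------------------------------------------------------

def cn_matrix(net: Network, params: IndexParams = IndexParams()) -> SimilarityMatrix:
    a = net.views().adjacency
    return SimilarityMatrix("CN", _zero_diag(a @ a), params)


def pa_matrix(net: Network, params: IndexParams = IndexParams()) -> SimilarityMatrix:
    k = net.views().degree_vector.astype(float)
    return SimilarityMatrix("PA", _zero_diag(np.outer(k, k)), params)


def aa_matrix(net: Network, params: IndexParams = IndexParams()) -> SimilarityMatrix:
    v = net.views()
    a, k = v.adjacency, v.degree_vector
    w = np.zeros_like(k, dtype=float)
    mask = k >= 2
    w[mask] = 1.0 / _log(k[mask].astype(float), params.aa_log_base)
    return SimilarityMatrix("AA", _zero_diag((a * w) @ a), params)


def lhn_matrix(net: Network, params: IndexParams = IndexParams()) -> SimilarityMatrix:
    v = net.views()
    cnm = v.adjacency @ v.adjacency
    kk = np.outer(v.degree_vector, v.degree_vector).astype(float)
    out = np.zeros_like(cnm, dtype=float)
    np.divide(cnm, kk, out=out, where=cnm > 0)
    return SimilarityMatrix("LHN", _zero_diag(out), params)


def ra_matrix(net: Network, params: IndexParams = IndexParams()) -> SimilarityMatrix:
    v = net.views()
    k = v.degree_vector.astype(float)
    w = np.divide(1.0, k, out=np.zeros_like(k), where=k > 0)
    return SimilarityMatrix("RA", _zero_diag((v.adjacency * w) @ v.adjacency), params)


def act_matrix(net: Network, params: IndexParams = IndexParams()) -> SimilarityMatrix:
    v = net.views()
    lp_ = v.laplacian_pinv
    d = np.diag(lp_)
    denom = d[:, None] + d[None, :] - 2.0 * lp_
    out = np.zeros_like(denom)
    np.divide(1.0, denom, out=out, where=denom > params.linear_solve_tol)
    out = 0.5 * (out + out.T)  # symmetrize away float round-off
    isolated = v.degree_vector == 0
    out[isolated, :] = 0.0
    out[:, isolated] = 0.0
    return SimilarityMatrix("ACT", _zero_diag(out), params)


def mfi(net: Network, params: IndexParams = IndexParams()) -> SimilarityMatrix:
    """Matrix-forest index (I + alpha*L)^-1; I + alpha*L is positive definite."""
    lap = net.views().laplacian
    n = net.N
    s = np.linalg.inv(np.eye(n) + params.mfi_alpha * lap)
    s = 0.5 * (s + s.T)
    return SimilarityMatrix("MFI", _zero_diag(s), params)


def rwr(net: Network, params: IndexParams = IndexParams()) -> SimilarityMatrix:
    """Random walk with restart.

    For each source i the stationary vector solves
    ``pi_i = c P^T pi_i + (1-c) e_i`` — one dense linear solve for all
    sources at once.  Isolated sources get the zero vector.
    """
    v = net.views()
    n = net.N
    c = params.rwr_restart_c
    # columns of Pi are pi_i
    pi = np.linalg.solve(np.eye(n) - c * v.transition.T, (1.0 - c) * np.eye(n))
    isolated = v.degree_vector == 0
    pi[:, isolated] = 0.0
    s = pi + pi.T  # S(i,j) = pi_i(j) + pi_j(i)
    return SimilarityMatrix("RWR", _zero_diag(s), params)


def simrank(net: Network, params: IndexParams = IndexParams()) -> SimilarityMatrix:
    """SimRank: two nodes are similar if their neighbors are similar.

    Fixed-point iteration of
    ``s(i,j) = C / (k_i k_j) * sum_{u in G(i), v in G(j)} s(u,v)`` from the
    identity start, with s(v,v) = 1 pinned each sweep.  Stops when the max
    entry change drops below ``simrank_tol`` or after ``simrank_max_iter``
    sweeps (then the last iterate is returned with ``converged=False``).
    """
    v = net.views()
    a, k = v.adjacency, v.degree_vector.astype(float)
    n = net.N
    kk = np.outer(k, k)
    scale = np.divide(params.simrank_decay_C, kk, out=np.zeros_like(kk), where=kk > 0)
    s = np.eye(n)
    converged = False
    for _ in range(params.simrank_max_iter):
        s_next = scale * (a @ s @ a)
        np.fill_diagonal(s_next, 1.0)
        if np.max(np.abs(s_next - s)) < params.simrank_tol:
            s = s_next
            converged = True
            break
        s = s_next
    if not converged:
        logger.warning("SimRank did not converge in %d iterations", params.simrank_max_iter)
    return SimilarityMatrix("SimRank", s, params, converged=converged)


def lp(net: Network, params: IndexParams = IndexParams()) -> SimilarityMatrix:
    """Local-path index A^2 + alpha * A^3 (path-2 and damped path-3 counts)."""
    a = net.views().adjacency
    a2 = a @ a
    return SimilarityMatrix("LP", _zero_diag(a2 + params.lp_alpha * (a2 @ a)), params)


def _lrw_values(net: Network, t: int) -> np.ndarray:
    """LRW score matrix after exactly t walk steps."""
    v = net.views()
    mt = np.linalg.matrix_power(v.transition, t)  # mt[i, j] = pi_i(j)(t)
    two_m = v.degree_vector.sum()
    if two_m == 0:
        return np.zeros((net.N, net.N))
    q = v.degree_vector.astype(float) / two_m
    half = q[:, None] * mt
    return _zero_diag(half + half.T)


def lrw(net: Network, params: IndexParams = IndexParams()) -> SimilarityMatrix:
    """Local random walk: t-step walk probabilities weighted by the initial
    resource q(v) = k(v) / 2M."""
    return SimilarityMatrix("LRW", _lrw_values(net, params.walk_steps_t), params)


def srw(net: Network, params: IndexParams = IndexParams()) -> SimilarityMatrix:
    """Superposed random walk: cumulative LRW over steps 1..t.

    Computed by accumulating the same propagation rather than re-running
    t separate walks.
    """
    v = net.views()
    n = net.N
    two_m = v.degree_vector.sum()
    if two_m == 0:
        return SimilarityMatrix("SRW", np.zeros((n, n)), params)
    q = v.degree_vector.astype(float) / two_m
    mt = np.eye(n)
    acc = np.zeros((n, n))
    for _ in range(params.walk_steps_t):
        mt = mt @ v.transition
        half = q[:, None] * mt
        acc += half + half.T
    return SimilarityMatrix("SRW", _zero_diag(acc), params)


_MATRIX_FNS = {
    "CN": cn_matrix,
    "PA": pa_matrix,
    "AA": aa_matrix,
    "LHN": lhn_matrix,
    "RA": ra_matrix,
    "ACT": act_matrix,
    "MFI": mfi,
    "RWR": rwr,
    "SimRank": simrank,
    "LP": lp,
    "LRW": lrw,
    "SRW": srw,
}


def compute_all_indices(
    net: Network, params: IndexParams = IndexParams()
) -> list[SimilarityMatrix]:
    """All 12 similarity matrices in the canonical feature order."""
    return [_MATRIX_FNS[name](net, params) for name in INDEX_NAMES]


def write_matrix(sim: SimilarityMatrix, path) -> None:
    """Dump a similarity matrix as TSV with a header naming index and params."""
    header = f"index={sim.index_name} params={sim.params_used}"
    np.savetxt(path, sim.values, delimiter="\t", header=header)
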
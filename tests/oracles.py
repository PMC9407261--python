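"""Independent brute-force oracles for the similarity indices and metrics.

These deliberately avoid the implementation's code paths: set arithmetic for
the local indices, eigendecomposition for the commute-time kernel, explicit
linear-system-free iteration for the walk indices, and pairwise loops for
SimRank and AUC.  They are only ever run on tiny graphs.
"""

from __future__ import annotations

import math

import numpy as np

from linkstack.graphio import Network


def neighbor_sets(net: Network) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(net.N)]
    for i, j in net.edges:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def cn_oracle(net: Network, i: int, j: int) -> int:
    adj = neighbor_sets(net)
    return len(adj[i] & adj[j])


def pa_oracle(net: Network, i: int, j: int) -> float:
    adj = neighbor_sets(net)
    return float(len(adj[i]) * len(adj[j]))


def aa_oracle(net: Network, i: int, j: int, base: str = "natural") -> float:
    adj = neighbor_sets(net)
    logf = {"natural": math.log, "log10": math.log10, "log2": math.log2}[base]
    return sum(1.0 / logf(len(adj[l])) for l in adj[i] & adj[j])


def lhn_oracle(net: Network, i: int, j: int) -> float:
    adj = neighbor_sets(net)
    c = len(adj[i] & adj[j])
    if c == 0:
        return 0.0
    return c / (len(adj[i]) * len(adj[j]))


def ra_oracle(net: Network, i: int, j: int) -> float:
    adj = neighbor_sets(net)
    return sum(1.0 / len(adj[l]) for l in adj[i] & adj[j])


def adjacency(net: Network) -> np.ndarray:
    a = np.zeros((net.N, net.N))
    for i, j in net.edges:
        a[i, j] = a[j, i] = 1.0
    return a


def laplacian_pinv_eig(net: Network) -> np.ndarray:
    """Pseudoinverse of L via eigendecomposition (invert nonzero eigenvalues)."""
    a = adjacency(net)
    lap = np.diag(a.sum(1)) - a
    w, v = np.linalg.eigh(lap)
    inv_w = np.array([0.0 if abs(x) < 1e-9 else 1.0 / x for x in w])
    return (v * inv_w) @ v.T


def act_oracle(net: Network, i: int, j: int, tol: float = 1e-10) -> float:
    adj = neighbor_sets(net)
    if not adj[i] or not adj[j]:
        return 0.0  # isolated endpoint: no walk commutes
    lp = laplacian_pinv_eig(net)
    denom = lp[i, i] + lp[j, j] - 2 * lp[i, j]
    return 0.0 if denom <= tol else 1.0 / denom


def mfi_oracle(net: Network, alpha: float = 1.0) -> np.ndarray:
    """Column-by-column linear solves of (I + alpha L) x = e_i."""
    a = adjacency(net)
    lap = np.diag(a.sum(1)) - a
    m = np.eye(net.N) + alpha * lap
    cols = [np.linalg.solve(m, e) for e in np.eye(net.N)]
    s = np.column_stack(cols)
    np.fill_diagonal(s, 0.0)
    return s


def transition(net: Network) -> np.ndarray:
    a = adjacency(net)
    k = a.sum(1)
    p = np.zeros_like(a)
    nz = k > 0
    p[nz] = a[nz] / k[nz, None]
    return p


def rwr_oracle(net: Network, c: float = 0.85, steps: int = 500) -> np.ndarray:
    """Power iteration of pi = c P^T pi + (1-c) e, all sources at once."""
    p = transition(net)
    n = net.N
    pi = np.eye(n)
    for _ in range(steps):
        pi = c * (p.T @ pi) + (1 - c) * np.eye(n)
    k = adjacency(net).sum(1)
    pi[:, k == 0] = 0.0
    s = pi + pi.T
    np.fill_diagonal(s, 0.0)
    return s


def simrank_oracle(net: Network, C: float = 0.8, sweeps: int = 15) -> np.ndarray:
    """Naive fixed-point iteration, pair by pair, for a fixed sweep count."""
    adj = [sorted(s) for s in neighbor_sets(net)]
    n = net.N
    s = np.eye(n)
    for _ in range(sweeps):
        nxt = np.zeros((n, n))
        for i in range(n):
            nxt[i, i] = 1.0
            for j in range(i + 1, n):
                if adj[i] and adj[j]:
                    block = s[np.ix_(adj[i], adj[j])].sum()
                    nxt[i, j] = nxt[j, i] = C * block / (len(adj[i]) * len(adj[j]))
        s = nxt
    return s


def lp_oracle(net: Network, alpha: float = 0.001) -> np.ndarray:
    """Explicit repeated multiplication for path-2 and path-3 counts."""
    a = adjacency(net)
    a2 = np.einsum("il,lj->ij", a, a)
    a3 = np.einsum("il,lm,mj->ij", a, a, a)
    s = a2 + alpha * a3
    np.fill_diagonal(s, 0.0)
    return s


def lrw_oracle(net: Network, t: int) -> np.ndarray:
    """Explicit probability propagation per source node."""
    p = transition(net)
    n = net.N
    k = adjacency(net).sum(1)
    two_m = k.sum()
    s = np.zeros((n, n))
    if two_m == 0:
        return s
    q = k / two_m
    for i in range(n):
        pi = np.zeros(n)
        pi[i] = 1.0
        for _ in range(t):
            pi = p.T @ pi
        s[i] += q[i] * pi
    s = s + s.T
    np.fill_diagonal(s, 0.0)
    return s


def srw_oracle(net: Network, t: int) -> np.ndarray:
    """Sum of separate LRW computations for tau = 1..t."""
    return sum(lrw_oracle(net, tau) for tau in range(1, t + 1))


def auc_oracle(scores, labels) -> float:
    """Brute-force concordance: P(pos > neg) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def commute_time_mc(net: Network, i: int, j: int, n_walks: int, seed: int = 0) -> float:
    """Monte-Carlo mean round-trip steps i -> j -> i of a simple random walk."""
    adj = [sorted(s) for s in neighbor_sets(net)]
    rng = np.random.default_rng(seed)
    total = 0
    for _ in range(n_walks):
        pos, target, steps, phase = i, j, 0, 0
        while True:
            pos = adj[pos][rng.integers(len(adj[pos]))]
            steps += 1
            if pos == target:
                if phase == 0:
                    phase, target = 1, i
                else:
                    break
        total += steps
    return total / n_walks
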
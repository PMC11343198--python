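"""Cophylogenetic association tests: Hommola, PACo, and ParaFit.

All three tests ask whether symbiont evolutionary distances track the
evolutionary distances of the hosts they were recovered from, against a
permutation null:

* Hommola's test correlates host and symbiont patristic distances over all
  pairs of host-symbiont links (a Mantel-style r) and permutes the host and
  symbiont assignments independently.
* PACo embeds both distance matrices by principal coordinates, superimposes
  the symbiont configuration on the host configuration by least-squares
  Procrustes, and uses the residual sum of squares m2 (small = congruent);
  the null permutes rows of the binary association matrix.
* ParaFit computes the global trace statistic of the fourth-corner matrix
  D = C' A B built from the two principal-coordinate configurations and the
  association matrix, permuting host assignments.

Permutation p-values follow the add-one convention p = (1 + c) / (1 + B),
with ties counted as extreme, so p is never 0 and never below 1/(B+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix

from .phylo import as_rng

__all__ = [
    "TestResult",
    "PCoAEmbedding",
    "pcoa",
    "hommola_statistic",
    "hommola_test",
    "paco_test",
    "parafit_test",
]


class UndefinedStatisticError(ValueError):
    """Raised when a test statistic is undefined (too few links, no variance)."""


@dataclass(frozen=True)
class TestResult:
    method: str  # hommola | paco | parafit
    statistic: float
    n_permutations: int
    p_value: float


@dataclass(frozen=True)
class PCoAEmbedding:
    """Principal-coordinates embedding: points x axes, eigenvalues nonincreasing."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray


# ---------------------------------------------------------------------------
# Principal coordinates


def _gower_center(a: np.ndarray) -> np.ndarray:
    r = a.mean(axis=1, keepdims=True)
    return a - r - r.T + a.mean()


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest constant c such that d_ij + c (i != j) is Euclidean.

    Largest real eigenvalue of the 2n x 2n block matrix
    [[0, 2*G(-d^2/2)], [-I, G(-4*(-d/2))... ]] in Cailliez's construction.
    """
    n = d.shape[0]
    d1 = _gower_center(-0.5 * d**2)
    d2 = _gower_center(-0.5 * d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * d1])
    lower = np.hstack([-np.eye(n), -4.0 * d2])
    eigvals = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(np.max(eigvals.real))


def pcoa(D, correction: str = "none", eps: float = 1e-9) -> PCoAEmbedding:
    """Classical multidimensional scaling of a distance matrix.

    With ``correction="cailliez"`` the off-diagonal distances are augmented
    by the closed-form Cailliez constant whenever negative eigenvalues
    occur, making the matrix Euclidean. Axes with eigenvalue <= ``eps`` x
    the leading eigenvalue are dropped; coordinates are eigenvectors scaled
    by sqrt(eigenvalue).
    """
    d = D.data if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if correction not in ("none", "cailliez"):
        raise ValueError(f"unknown correction {correction!r}")

    def decompose(dd):
        g = _gower_center(-0.5 * dd**2)
        vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = decompose(d)
    if correction == "cailliez" and vals.min() < -eps * max(vals.max(), 1.0):
        c = _cailliez_constant(d)
        d = d + c * (1.0 - np.eye(d.shape[0]))
        vals, vecs = decompose(d)
    scale = max(vals.max(), 0.0)
    keep = vals > eps * max(scale, 1.0)
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return PCoAEmbedding(coordinates=coords, eigenvalues=vals)


# ---------------------------------------------------------------------------
# Shared link plumbing


def _link_arrays(host_D: DistanceMatrix, symb_D: DistanceMatrix, links):
    """Index the link list into the two distance matrices.

    Returns (H, S, hidx, sidx) where H and S are the dense matrices and
    hidx/sidx map each link to its row in H/S. Hosts may repeat across
    links; symbionts must be unique.
    """
    links = list(links)
    symbionts = [s for s, _ in links]
    if len(set(symbionts)) != len(symbionts):
        raise ValueError("each symbiont tip must appear in exactly one link")
    h_ids = {lbl: i for i, lbl in enumerate(host_D.ids)}
    s_ids = {lbl: i for i, lbl in enumerate(symb_D.ids)}
    try:
        hidx = np.asarray([h_ids[h] for _, h in links])
        sidx = np.asarray([s_ids[s] for s, _ in links])
    except KeyError as exc:
        raise KeyError(f"link label missing from distance matrix: {exc}") from exc
    return host_D.data, symb_D.data, hidx, sidx


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise UndefinedStatisticError("zero variance in a distance vector")
    return float((xc * yc).sum() / denom)


# ---------------------------------------------------------------------------
# Hommola


def hommola_statistic(host_D, symb_D, links) -> float:
    """Mantel's r between host and symbiont distances over all link pairs."""
    H, S, hidx, sidx = _link_arrays(host_D, symb_D, links)
    if len(hidx) < 2:
        raise UndefinedStatisticError("need at least 2 links")
    iu, ju = np.triu_indices(len(hidx), k=1)
    return _pearson(H[hidx[iu], hidx[ju]], S[sidx[iu], sidx[ju]])


def hommola_test(host_D, symb_D, links, n_perm: int = 999, rng_seed=0) -> TestResult:
    """Hommola et al.-style permutation test for host-symbiont codivergence.

    The null permutes the host-assignment and symbiont-assignment indexings
    of the links independently; p is the upper-tail add-one estimate for r.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = as_rng(rng_seed)
    H, S, hidx, sidx = _link_arrays(host_D, symb_D, links)
    L = len(hidx)
    if L < 2:
        raise UndefinedStatisticError("need at least 2 links")
    iu, ju = np.triu_indices(L, k=1)
    x = H[hidx[iu], hidx[ju]]
    y = S[sidx[iu], sidx[ju]]
    r_obs = _pearson(x, y)

    hosts = np.unique(hidx)
    n_hosts = len(hosts)
    host_pos = np.searchsorted(hosts, hidx)  # link -> position in `hosts`
    count = 0
    for _ in range(n_perm):
        hperm = hosts[rng.permutation(n_hosts)]
        sperm = sidx[rng.permutation(L)]
        xp = H[hperm[host_pos][iu], hperm[host_pos][ju]]
        yp = S[sperm[iu], sperm[ju]]
        try:
            r_p = _pearson(xp, yp)
        except UndefinedStatisticError:
            continue
        if r_p >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return TestResult("hommola", r_obs, n_perm, p)


# ---------------------------------------------------------------------------
# PACo


def _procrustes_m2(X: np.ndarray, Y: np.ndarray) -> float:
    """Residual sum of squares of the best superposition of Y onto X.

    Both configurations are centered and scaled to unit sum of squares
    before the optimal rotation, so m2 lies in [0, 1].
    """
    def norm(a):
        a = a - a.mean(axis=0)
        ss = np.sqrt((a**2).sum())
        if ss == 0:
            raise UndefinedStatisticError("degenerate configuration")
        return a / ss

    X = norm(X)
    Y = norm(Y)
    s = np.linalg.svd(X.T @ Y, compute_uv=False)
    return float(max(1.0 - s.sum() ** 2, 0.0))


def _pad_columns(a: np.ndarray, b: np.ndarray):
    k = max(a.shape[1], b.shape[1])
    pa = np.zeros((a.shape[0], k))
    pb = np.zeros((b.shape[0], k))
    pa[:, : a.shape[1]] = a
    pb[:, : b.shape[1]] = b
    return pa, pb


def paco_test(host_D, symb_D, links, n_perm: int = 999, rng_seed=0) -> TestResult:
    """Procrustes cophylogenetic test (PACo-style m2 goodness of fit).

    The symbiont principal-coordinate configuration (one row per link) is
    superimposed on the host configuration; small m2 means congruence, so p
    is the lower-tail add-one estimate under row permutations of the
    association matrix.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = as_rng(rng_seed)
    _, _, hidx, sidx = _link_arrays(host_D, symb_D, links)
    if len(hidx) < 3:
        raise UndefinedStatisticError("need at least 3 links")
    Hc = pcoa(host_D, correction="cailliez").coordinates
    Sc = pcoa(symb_D, correction="cailliez").coordinates
    Hc, Sc = _pad_columns(Hc, Sc)
    m2_obs = _procrustes_m2(Hc[hidx], Sc[sidx])
    count = 0
    for _ in range(n_perm):
        hperm = hidx[rng.permutation(len(hidx))]
        try:
            m2_p = _procrustes_m2(Hc[hperm], Sc[sidx])
        except UndefinedStatisticError:
            continue
        if m2_p <= m2_obs + 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return TestResult("paco", m2_obs, n_perm, p)


# ---------------------------------------------------------------------------
# ParaFit


def _parafit_stat(C: np.ndarray, B: np.ndarray, hidx: np.ndarray) -> float:
    # A is the symbionts x hosts incidence; with one host per symbiont,
    # A @ B is just B re-indexed by host assignment.
    D = C.T @ B[hidx]
    return float((D**2).sum())


def parafit_test(host_D, symb_D, links, n_perm: int = 999, rng_seed=0) -> TestResult:
    """Global ParaFit test: trace of D'D with D = C' A B.

    B and C are the host and symbiont principal coordinates (Cailliez
    corrected), A the binary association matrix. The null permutes the host
    assignments within A; p is the upper-tail add-one estimate.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = as_rng(rng_seed)
    _, _, hidx, sidx = _link_arrays(host_D, symb_D, links)
    if len(hidx) < 3:
        raise UndefinedStatisticError("need at least 3 links")
    B = pcoa(host_D, correction="cailliez").coordinates
    C = pcoa(symb_D, correction="cailliez").coordinates
    C = C[sidx]  # one row per link, in link order
    stat_obs = _parafit_stat(C, B, hidx)
    count = 0
    for _ in range(n_perm):
        hperm = hidx[rng.permutation(len(hidx))]
        if _parafit_stat(C, B, hperm) >= stat_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return TestResult("parafit", stat_obs, n_perm, p)
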
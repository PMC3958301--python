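"""Digital compressive sensing of EEG epochs.

Compression multiplies each channel's ``N``-sample epoch by a sparse
random binary measurement matrix Φ (``M × N``, exactly ``d`` ones per
column, default ``d = 4``), which reduces to pure accumulator additions on
a sensor node — only the ``d`` row indices per column need to be stored.
The server recovers the epoch from the ``M`` measurements ``y = Φx``.

Two reconstruction solvers are shipped:

* ``"bsbl"`` — an EM-style block sparse Bayesian learning solver.  The
  signal is partitioned into equal blocks whose coefficients share a
  variance hyperparameter and a common first-order-autoregressive
  intra-block correlation matrix; blocks whose variance collapses are
  pruned.  Raw scalp EEG is not sparse but is block-correlated in the
  time domain, which this prior captures.
* ``"fista"`` — ℓ1-regularized recovery in an orthonormal DCT dictionary
  via FISTA; much faster, vectorizable over many epochs/channels at once,
  and the default for large sweeps.

A dense least-squares path handles the no-compression case ``M ≥ N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, idct
from scipy.linalg import toeplitz
from scipy import sparse as sp

__all__ = [
    "MeasurementMatrix",
    "CompressedEpoch",
    "ReconstructionParams",
    "ReconstructionResult",
    "make_matrix",
    "compress",
    "reconstruct",
    "batch_reconstruct",
    "compression_ratio",
    "format_ratio",
]


@dataclass
class MeasurementMatrix:
    """Sparse binary Φ stored as its per-column nonzero row indices."""

    m: int
    n: int
    d: int
    seed: int
    indices: np.ndarray  # (n, d) distinct row indices per column

    def to_dense(self) -> np.ndarray:
        phi = np.zeros((self.m, self.n))
        for j in range(self.n):
            phi[self.indices[j], j] = 1.0
        return phi

    def to_sparse(self) -> sp.csr_matrix:
        rows = self.indices.ravel()
        cols = np.repeat(np.arange(self.n), self.d)
        vals = np.ones(rows.size)
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.m, self.n))

    def save_indices(self, path) -> None:
        """Column-major index table, d indices per CSV row."""
        np.savetxt(path, self.indices, fmt="%d", delimiter=",")

    @classmethod
    def load_indices(cls, path, m: int, d: int = 4, seed: int = -1
                     ) -> "MeasurementMatrix":
        idx = np.loadtxt(path, dtype=int, delimiter=",", ndmin=2)
        return cls(m=m, n=idx.shape[0], d=idx.shape[1], seed=seed, indices=idx)


@dataclass
class CompressedEpoch:
    """Per-channel compressive measurements of one epoch."""

    y: np.ndarray  # (n_channels, M)
    matrix_seed: int
    m: int
    n: int

    @property
    def cr(self) -> float:
        return compression_ratio(self.m, self.n)


def make_matrix(m: int, n: int, d: int = 4, seed: int = 0) -> MeasurementMatrix:
    """Draw Φ: for each column, ``d`` distinct rows chosen uniformly."""
    if not (1 <= d <= m):
        raise ValueError(f"need 1 <= d <= M, got d={d}, M={m}")
    if m > n:
        raise ValueError(f"need M <= N for a measurement matrix, got "
                         f"M={m}, N={n}")
    rng = np.random.default_rng(seed)
    idx = np.empty((n, d), dtype=np.int64)
    for j in range(n):
        idx[j] = rng.choice(m, size=d, replace=False)
    return MeasurementMatrix(m=m, n=n, d=d, seed=seed, indices=idx)


def compress(x: np.ndarray, phi: MeasurementMatrix) -> np.ndarray:
    """Compute y = Φx by accumulation only.

    Each input sample is added into the ``d`` measurement accumulators its
    column indexes — no multiplications.  Integer input yields integer
    output.
    """
    x = np.asarray(x)
    if x.shape[-1] != phi.n:
        raise ValueError(f"x has length {x.shape[-1]}, expected N={phi.n}")
    out_dtype = np.int64 if np.issubdtype(x.dtype, np.integer) else np.float64
    if x.ndim == 1:
        y = np.zeros(phi.m, dtype=out_dtype)
        np.add.at(y, phi.indices.ravel(), np.repeat(x, phi.d))
        return y
    y = np.zeros(x.shape[:-1] + (phi.m,), dtype=out_dtype)
    for j in range(phi.n):
        for r in phi.indices[j]:
            y[..., r] += x[..., j]
    return y


def compression_ratio(m: int, n: int) -> float:
    """CR = N / M (compression achieved when M < N)."""
    if m <= 0 or n <= 0:
        raise ValueError("M and N must be positive")
    return n / m


def format_ratio(n: int, m: int) -> str:
    """Render N:M in lowest terms, e.g. 512:256 -> '2:1'."""
    g = math.gcd(n, m)
    return f"{n // g}:{m // g}"


@dataclass
class ReconstructionParams:
    """Server-side reconstruction settings."""

    solver: str = "bsbl"            # "bsbl" | "fista"
    block_size: int = 32            # BSBL block partition (last block short)
    max_iter: int = 100
    tol: float = 1e-6
    dictionary: str = "identity"    # sparsifying basis: "identity" | "dct"
    noise_var: float | None = None  # BSBL lambda; None = scaled default
    lam_rel: float = 0.01           # FISTA l1 weight relative to ||A'y||_inf
    prune_gamma: float = 1e-4

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.block_size < 1:
            raise ValueError("block size must be >= 1")


@dataclass
class ReconstructionResult:
    x_hat: np.ndarray
    iterations: int
    residual: float
    converged: bool


def _dictionary(name: str, n: int) -> np.ndarray | None:
    if name == "identity":
        return None
    if name == "dct":
        return idct(np.eye(n), axis=0, norm="ortho")
    raise ValueError(f"unknown dictionary {name!r}")


def _bsbl_em(a: np.ndarray, y: np.ndarray, params: ReconstructionParams
             ) -> tuple[np.ndarray, int, bool]:
    """EM block-sparse Bayesian learning on y = A s + noise."""
    m, n = a.shape
    b = params.block_size
    starts = list(range(0, n, b))
    blocks = [(s, min(s + b, n)) for s in starts]
    g = len(blocks)
    gamma = np.ones(g)
    corr = np.eye(b)
    lam = params.noise_var
    if lam is None:
        lam = 1e-8 * float(y @ y) / m + 1e-12
    mu = np.zeros(n)
    active = np.ones(g, dtype=bool)
    it = 0
    converged = False
    for it in range(1, params.max_iter + 1):
        mu_old = mu
        # Sigma0 A^T assembled block-wise (Sigma0 is block diagonal)
        s0at = np.zeros((n, m))
        for i, (lo, hi) in enumerate(blocks):
            if not active[i]:
                continue
            bb = corr[: hi - lo, : hi - lo]
            s0at[lo:hi] = gamma[i] * (bb @ a[:, lo:hi].T)
        h = a @ s0at + lam * np.eye(m)
        try:
            hinv_y = np.linalg.solve(h, y)
            t = np.linalg.solve(h, s0at.T)  # (m, n)
        except np.linalg.LinAlgError:
            break
        mu = s0at @ hinv_y
        # per-block posterior moments and hyperparameter updates
        num_corr = np.zeros((b, b))
        n_full = 0
        for i, (lo, hi) in enumerate(blocks):
            if not active[i]:
                continue
            k = hi - lo
            bb = corr[:k, :k]
            sig_i = gamma[i] * bb - s0at[lo:hi] @ t[:, lo:hi]
            moment = sig_i + np.outer(mu[lo:hi], mu[lo:hi])
            bb_inv = np.linalg.pinv(bb)
            gamma[i] = max(float(np.trace(bb_inv @ moment)) / k, 0.0)
            if k == b and gamma[i] > 0:
                num_corr += moment / gamma[i]
                n_full += 1
        gmax = gamma.max() if gamma.size else 0.0
        if gmax > 0:
            active &= gamma > params.prune_gamma * gmax
            gamma[~active] = 0.0
        if n_full > 0:
            avg = num_corr / n_full
            d0 = float(np.mean(np.diag(avg)))
            d1 = float(np.mean(np.diag(avg, 1))) if b > 1 else 0.0
            r = 0.0 if d0 <= 0 else float(np.clip(d1 / d0, -0.99, 0.99))
            corr = toeplitz(r ** np.arange(b))
        denom = np.linalg.norm(mu_old) + 1e-12
        if np.linalg.norm(mu - mu_old) / denom < params.tol:
            converged = True
            break
    return mu, it, converged


def _phi_operator(phi) -> sp.csr_matrix | np.ndarray:
    if isinstance(phi, MeasurementMatrix):
        return phi.to_sparse()
    return np.asarray(phi, dtype=float)


def _fista(phi_op, y: np.ndarray, n: int, params: ReconstructionParams,
           use_dct: bool) -> tuple[np.ndarray, int, bool]:
    """Batched FISTA for min ½||y − Φ Ψ s||² + λ||s||₁, columns independent.

    ``y`` is (M, k); returns x_hat (N, k).  With ``use_dct`` the dictionary
    is the orthonormal inverse DCT, so the Lipschitz constant equals
    ||Φ||₂² and is found by power iteration.
    """
    y2 = y if y.ndim == 2 else y[:, None]
    k = y2.shape[1]

    def fwd(s):
        x = idct(s, axis=0, norm="ortho") if use_dct else s
        return phi_op @ x

    def adj(r):
        x = phi_op.T @ r
        return dct(x, axis=0, norm="ortho") if use_dct else x

    rng = np.random.default_rng(0)
    v = rng.standard_normal(n)
    lip = 1.0
    for _ in range(30):
        v2 = phi_op.T @ (phi_op @ v)
        lip = float(np.linalg.norm(v2))
        if lip == 0:
            lip = 1.0
            break
        v = v2 / lip
    step = 1.0 / lip
    aty = adj(y2)
    lam = params.lam_rel * np.abs(aty).max(axis=0, keepdims=True)
    s = np.zeros((n, k))
    z = s.copy()
    t_mom = 1.0
    it = 0
    converged = False
    for it in range(1, params.max_iter + 1):
        grad = adj(fwd(z) - y2)
        s_new = z - step * grad
        s_new = np.sign(s_new) * np.maximum(np.abs(s_new) - step * lam, 0.0)
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_mom * t_mom))
        z = s_new + ((t_mom - 1.0) / t_new) * (s_new - s)
        delta = np.linalg.norm(s_new - s) / (np.linalg.norm(s) + 1e-12)
        s, t_mom = s_new, t_new
        if delta < params.tol:
            converged = True
            break
    x = idct(s, axis=0, norm="ortho") if use_dct else s
    if y.ndim == 1:
        x = x[:, 0]
    return x, it, converged


def reconstruct(y: np.ndarray, phi, params: ReconstructionParams | None = None
                ) -> ReconstructionResult:
    """Recover an epoch estimate x̂ from measurements y.

    ``phi`` may be a :class:`MeasurementMatrix` or a dense array (e.g. an
    identity for no-compression tests).  With ``M >= N`` the dense
    least-squares solution is returned directly.  Non-convergence within
    ``max_iter`` is flagged on the result, not raised.
    """
    params = params or ReconstructionParams()
    y = np.asarray(y, dtype=float)
    if isinstance(phi, MeasurementMatrix):
        m, n = phi.m, phi.n
    else:
        phi = np.asarray(phi, dtype=float)
        m, n = phi.shape
    if y.shape[-1] != m:
        raise ValueError(f"y has length {y.shape[-1]}, expected M={m}")

    dense = phi.to_dense() if isinstance(phi, MeasurementMatrix) else phi
    if m >= n:
        x_hat, *_ = np.linalg.lstsq(dense, y, rcond=None)
        res = float(np.linalg.norm(dense @ x_hat - y))
        return ReconstructionResult(x_hat=x_hat, iterations=0,
                                    residual=res, converged=True)

    if params.solver == "bsbl":
        psi = _dictionary(params.dictionary, n)
        a = dense if psi is None else dense @ psi
        s_hat, it, conv = _bsbl_em(a, y, params)
        x_hat = s_hat if psi is None else psi @ s_hat
    elif params.solver == "fista":
        # l1 recovery needs a sparsifying transform; always solve in DCT
        op = _phi_operator(phi)
        x_hat, it, conv = _fista(op, y, n, params, use_dct=True)
    else:
        raise ValueError(f"unknown solver {params.solver!r}")
    res = float(np.linalg.norm(dense @ x_hat - y))
    return ReconstructionResult(x_hat=x_hat, iterations=it,
                                residual=res, converged=conv)


def batch_reconstruct(y: np.ndarray, phi: MeasurementMatrix,
                      params: ReconstructionParams | None = None
                      ) -> np.ndarray:
    """Reconstruct many epochs/channels at once.

    ``y`` is (k, M) — one row per signal; returns (k, N).  Uses the FISTA
    solver regardless of ``params.solver`` (the batched fast path); BSBL
    is available per-signal through :func:`reconstruct`.
    """
    params = params or ReconstructionParams(solver="fista", dictionary="dct")
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != phi.m:
        raise ValueError("y must be (k, M)")
    if phi.m >= phi.n:
        dense = phi.to_dense()
        x_hat, *_ = np.linalg.lstsq(dense, y.T, rcond=None)
        return x_hat.T
    op = phi.to_sparse()
    x, _, _ = _fista(op, y.T, phi.n, params, use_dct=True)
    return x.T
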
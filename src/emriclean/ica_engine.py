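"""Extended Infomax ICA, full-length projection, selective reconstruction.

The recording (with bad intervals excised) is decomposed as
``x' = A S'`` with a square mixing matrix ``A`` (components = channels).
Fitting maximizes the Infomax likelihood with the extended (sub- and
super-Gaussian) score, by full-batch natural-gradient ascent with an
annealed step size and a seeded subsample warm start. The full-length
sources are ``S = W x`` with ``W = A^-1`` applied to the *uncut* data, and
artifact removal zeroes the flagged columns of ``A`` before re-mixing:
``x_final = A' S``, which equals ``x`` minus the summed back-projection of
the removed components (an exact linear identity).

Component scale/sign indeterminacy is fixed by normalizing each column of
``A`` to unit norm with a positive maximum-magnitude entry; reconstruction
is invariant under this convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ICADecomposition", "RemovalSet", "fit_infomax", "project_full", "reconstruct"]


@dataclass
class ICADecomposition:
    A: np.ndarray  # N x N mixing
    W: np.ndarray  # N x N unmixing (A^-1)
    S_short: np.ndarray  # N x K sources of the excised data
    seed: int
    labels: list[str] | None = None  # channel order reference
    S_full: np.ndarray | None = None  # N x M, set by project_full
    n_iter: int = 0
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.A.shape[0]


@dataclass
class RemovalSet:
    """Component ids flagged artifactual, with per-id evidence."""

    ids: list[int] = field(default_factory=list)
    labels: dict[int, str] = field(default_factory=dict)
    evidence: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("removal ids must be unique")


# ---------------------------------------------------------------------------
# extended Infomax solver
# ---------------------------------------------------------------------------

def _natural_gradient_pass(x, W, signs, step, n_iter, tol, anneal=0.8,
                           anneal_deg=60.0, grow=1.05, grow_deg=30.0,
                           signs_bias=0.02, step_max=1.0):
    """Iterate W <- W + step * (I - K tanh(u) u^T - u u^T) W on sphered x.

    The step grows while successive updates stay aligned (< ``grow_deg``
    degrees apart) and anneals when they turn (> ``anneal_deg``); divergence
    is caught and restarted with a halved step. The inner loop runs in
    single precision (the estimating equations are statistical; their
    sampling error dwarfs float32 rounding) and the result is promoted.
    """
    x = np.ascontiguousarray(x, dtype=np.float32)
    W = W.astype(np.float32)
    signs = signs.astype(np.float32)
    N, K = x.shape
    I = np.eye(N, dtype=np.float32)
    old_dW = None
    it = 0
    converged = False
    while it < n_iter:
        u = W @ x
        y = np.tanh(u)
        g = I - (signs[:, None] * y) @ u.T / K - u @ u.T / K
        dW = step * g @ W
        W_new = W + dW
        if not np.isfinite(W_new).all() or np.abs(W_new).max() > 1e6:
            step *= 0.5
            old_dW = None
            continue
        W = W_new
        m2 = np.mean(u ** 2, axis=1)
        m4 = np.mean(u ** 4, axis=1)
        kurt = m4 / np.maximum(m2 ** 2, 1e-300) - 3.0
        signs = np.where(kurt + signs_bias >= 0, 1.0, -1.0)
        change = float(np.sum(dW ** 2))
        if change > 1e3:
            step *= 0.5
            old_dW = None
        elif old_dW is not None:
            denom = np.sqrt(change * np.sum(old_dW ** 2))
            if denom > 0:
                cosang = np.clip(np.sum(dW * old_dW) / denom, -1.0, 1.0)
                ang = np.degrees(np.arccos(cosang))
                if ang > anneal_deg:
                    step *= anneal
                elif ang < grow_deg:
                    step = min(step * grow, step_max)
        old_dW = dW
        it += 1
        if change < tol:
            converged = True
            break
    return W.astype(np.float64), signs.astype(np.float64), step, it, converged


def fit_infomax(
    x_short: np.ndarray,
    seed: int = 97,
    max_iter: int = 512,
    tol: float = 1e-7,
    labels: list[str] | None = None,
    subsample: int = 8000,
) -> ICADecomposition:
    """Fit extended Infomax ICA to an N x K matrix.

    Deterministic given (input, seed). The data are sphered (ZCA), a warm
    start runs on a seeded subsample of ``subsample`` columns, and the final
    iterations use the full batch. Components are ordered by descending
    back-projection variance; mixing columns are unit-norm with a positive
    maximum-magnitude entry.
    """
    x = np.asarray(x_short, dtype=float)
    if x.ndim != 2:
        raise ValueError("x_short must be 2-D (channels x samples)")
    if not np.isfinite(x).all():
        raise ValueError("x_short contains non-finite values")
    N, K = x.shape
    if K <= N:
        raise ValueError("need more samples than channels")
    if K < N * 25:
        warnings.warn(
            f"only {K} samples for {N} channels; ICA estimates may be unstable",
            stacklevel=2,
        )
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    cov = xc @ xc.T / K
    d, U = np.linalg.eigh(cov)
    if d[0] <= 0 or d[-1] / max(d[0], 1e-300) > 1e10:
        raise np.linalg.LinAlgError(
            "rank-deficient input (condition number > 1e10); exclude degenerate channels"
        )
    sph = U @ np.diag(1.0 / np.sqrt(d)) @ U.T  # ZCA sphering
    xw = sph @ xc

    rng = np.random.default_rng(seed)
    W = np.eye(N)
    signs = np.ones(N)
    step = 0.1
    used = 0
    if K > 2 * subsample:
        idx = np.sort(rng.choice(K, size=subsample, replace=False))
        W, signs, step, it1, _ = _natural_gradient_pass(
            xw[:, idx], W, signs, step, int(max_iter * 0.7), tol * K / subsample
        )
        used = it1
        step = min(step, 0.3)
    W, signs, step, it2, converged = _natural_gradient_pass(
        xw, W, signs, step, max_iter - used, tol
    )
    n_iter = used + it2
    if not converged:
        warnings.warn(
            f"Infomax did not reach tolerance {tol} in {max_iter} iterations",
            stacklevel=2,
        )

    W_total = W @ sph  # fitted on centered data; applied uncentered so that
    A = np.linalg.inv(W_total)  # A @ S reproduces the input exactly
    S = W_total @ x

    # order by back-projection variance, fix scale/sign
    var = np.sum(A ** 2, axis=0) * S.var(axis=1)
    order = np.argsort(var)[::-1]
    A = A[:, order]
    S = S[order]
    norms = np.linalg.norm(A, axis=0)
    flips = np.sign(A[np.argmax(np.abs(A), axis=0), np.arange(N)])
    A = A / (norms * flips)
    S = S * (norms * flips)[:, None]
    W_total = np.linalg.inv(A)

    return ICADecomposition(
        A=A,
        W=W_total,
        S_short=S,
        seed=seed,
        labels=labels,
        n_iter=n_iter,
        converged=converged,
    )


def project_full(dec: ICADecomposition, x_full: np.ndarray) -> np.ndarray:
    """Project the full-length (uncut) data through the fitted unmixing:
    ``S_full = W x_full``. Stores and returns ``S_full``."""
    x_full = np.asarray(x_full, dtype=float)
    if x_full.ndim != 2 or x_full.shape[0] != dec.n_components:
        raise ValueError(
            f"x_full must have {dec.n_components} channels in the fitted order"
        )
    dec.S_full = dec.W @ x_full
    return dec.S_full


def reconstruct(dec: ICADecomposition, removal: RemovalSet) -> np.ndarray:
    """Re-mix the full-length sources with the flagged mixing columns
    zeroed: ``x_final = A' S_full``."""
    if dec.S_full is None:
        raise ValueError("call project_full before reconstruct")
    N = dec.n_components
    for i in removal.ids:
        if not (0 <= i < N):
            raise ValueError(f"component id {i} out of range [0, {N})")
    A_prime = dec.A.copy()
    if removal.ids:
        A_prime[:, list(removal.ids)] = 0.0
    return A_prime @ dec.S_full
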
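"""Masked non-negative CP (PARAFAC) decomposition.

Fits X ~ sum_r a_r (x) b_r (x) c_r with all loadings >= 0, ignoring masked
(missing) entries in the loss.  Missing entries are handled by expectation-
maximization imputation: each sweep replaces them with the current
reconstruction, then applies one round of HALS (hierarchical alternating
least squares) non-negative updates per mode.  The reported RMSE is computed over observed entries only, so a
perturbation of masked values cannot change the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding (rows = mode-n index, columns = the rest)."""
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    """Column-wise Khatri-Rao product of a list of (I_k, R) matrices."""
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, None, :] * m[None, :, :]).reshape(-1, out.shape[1])
    return out


def reconstruct(factors: list[np.ndarray]) -> np.ndarray:
    """Dense tensor from CP factors."""
    shape = tuple(f.shape[0] for f in factors)
    return khatri_rao(list(factors)).sum(axis=1).reshape(shape)


@dataclass
class CPResult:
    factors: list[np.ndarray]  # one (I_k, R) non-negative matrix per mode
    rmse: float  # over observed entries
    converged: bool
    n_iter: int


def _rmse(x: np.ndarray, xhat: np.ndarray, observed: np.ndarray) -> float:
    resid = (x - xhat)[observed]
    return float(np.sqrt((resid**2).mean())) if resid.size else 0.0


def cp_nonneg_masked(
    tensor: np.ndarray,
    mask: np.ndarray | None,
    rank: int,
    seed: int = 0,
    n_restarts: int = 3,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> CPResult:
    """Best-of-restarts masked non-negative CP fit.

    ``mask`` is True where the entry is MISSING; None means fully observed.
    Deterministic per seed.  If no restart reaches the relative-loss
    tolerance within ``max_iter`` sweeps the best fit is returned with
    ``converged=False``.
    """
    x = np.asarray(tensor, dtype=float)
    observed = np.ones(x.shape, dtype=bool) if mask is None else ~np.asarray(mask, bool)
    if not observed.any():
        raise ValueError("tensor has no observed entries")
    x_obs = np.where(observed, x, 0.0)
    ndim = x.ndim
    best: CPResult | None = None
    for restart in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), restart]))
        factors = [rng.uniform(0.1, 1.0, size=(s, rank)) for s in x.shape]
        xhat = reconstruct(factors)
        prev = _rmse(x, xhat, observed)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            x_fill = np.where(observed, x_obs, xhat)
            for mode in range(ndim):
                others = [factors[m] for m in range(ndim) if m != mode]
                kr = khatri_rao(others)  # first-listed mode varies slowest, as in unfold
                xn = unfold(x_fill, mode)
                numer = xn @ kr
                gram = np.ones((rank, rank))
                for m in range(ndim):
                    if m != mode:
                        gram *= factors[m].T @ factors[m]
                # HALS: cyclic non-negative update of each rank-one column
                a = factors[mode]
                for rr in range(rank):
                    denom = max(gram[rr, rr], _EPS)
                    col = a[:, rr] + (numer[:, rr] - a @ gram[:, rr]) / denom
                    a[:, rr] = np.maximum(col, 0.0)
            xhat = reconstruct(factors)
            loss = _rmse(x, xhat, observed)
            if prev > 0 and abs(prev - loss) / max(prev, _EPS) < tol:
                converged = True
                prev = loss
                break
            prev = loss
        result = CPResult(factors=factors, rmse=prev, converged=converged, n_iter=it)
        if best is None or result.rmse < best.rmse:
            best = result
    return best


def factor_congruence(
    factors_a: list[np.ndarray], factors_b: list[np.ndarray]
) -> np.ndarray:
    """Per-factor congruence between two CP models after permutation matching.

    Congruence of a factor pair is the product over modes of the cosine of
    the corresponding loading vectors (scale-indeterminacy drops out).
    Factors of ``b`` are matched to ``a`` by maximum-congruence assignment.
    """
    from scipy.optimize import linear_sum_assignment

    rank = factors_a[0].shape[1]
    score = np.ones((rank, rank))
    for fa, fb in zip(factors_a, factors_b):
        na = fa / np.maximum(np.linalg.norm(fa, axis=0), _EPS)
        nb = fb / np.maximum(np.linalg.norm(fb, axis=0), _EPS)
        score *= np.abs(na.T @ nb)
    row, col = linear_sum_assignment(-score)
    return score[row, col]
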
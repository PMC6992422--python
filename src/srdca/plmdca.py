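"""Weighted asymmetric pseudo-likelihood inference of Potts models.

The generalized Potts model over aligned sequences s = (s_1..s_L),

    P(s) ∝ exp( Σ_i h_i(s_i) + Σ_{i<j} J_ij(s_i, s_j) ),

is fit by maximizing a weighted pseudo-likelihood: the intractable
normalizer is replaced by the product of per-site conditionals

    P(s_i | s_\\i) = softmax_a( h_i(a) + Σ_{j≠i} J_ij(a, s_j) ),

so each site reduces to an L2-regularized multinomial logistic
regression.  In the asymmetric variant used here each site is solved
independently and the two directed estimates of every coupling block
are averaged.  Contact scores are Frobenius norms of the coupling
blocks in the zero-sum gauge (gap state excluded), followed by the
average-product correction (APC).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alignment_io import LabeledMSA

logger = logging.getLogger(__name__)

#: Documented reproducibility tolerance on individual APC scores: two fits of
#: the same data that differ only by numerically irrelevant transformations
#: (weight rescaling, row duplication with halved weights, ...) agree on every
#: score to within this bound under the default optimizer settings.
OPTIMIZER_SCORE_TOL = 1e-4


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class RegularizationConfig:
    """L2 regularization strengths and optimizer settings.

    ``lambda_h``/``lambda_J`` multiply the squared norms of fields and
    (directed) coupling blocks added to the per-sequence-normalized
    negative pseudo-log-likelihood.  0.01/0.01 are the customary
    asymmetric pseudo-likelihood defaults.
    """

    lambda_h: float = 0.01
    lambda_J: float = 0.01
    tol: float = 1e-5       # projected-gradient tolerance per site
    max_iter: int = 500     # L-BFGS iterations per site

    def __post_init__(self) -> None:
        if self.lambda_h < 0 or self.lambda_J < 0:
            raise ValueError("regularization strengths must be non-negative")


@dataclass
class PottsModel:
    """Fields ``h`` (L, q) and couplings ``J`` (L, L, q, q).

    Couplings are stored for every ordered pair with the symmetry
    ``J[j, i] == J[i, j].T`` and zero diagonal blocks.  ``gap_index``
    identifies the state excluded from Frobenius scoring (None for
    gap-free synthetic alphabets).
    """

    h: np.ndarray
    J: np.ndarray
    gap_index: int | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.J = np.asarray(self.J, dtype=np.float64)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError("J must have shape (L, L, q, q)")
        if not np.isfinite(self.h).all() or not np.isfinite(self.J).all():
            raise ValueError("model parameters must be finite")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def validate_symmetry(self, atol: float = 1e-10) -> None:
        if not np.allclose(self.J, self.J.transpose(1, 0, 3, 2), atol=atol):
            raise ValueError("J violates J[i,j] == J[j,i].T")
        diag = self.J[np.arange(self.L), np.arange(self.L)]
        if np.abs(diag).max(initial=0.0) > atol:
            raise ValueError("diagonal coupling blocks must be zero")


@dataclass
class ScoreMatrix:
    """Symmetric residue-pair coupling scores: raw Frobenius and APC-corrected."""

    raw: np.ndarray
    apc: np.ndarray | None = None

    @property
    def L(self) -> int:
        return self.raw.shape[0]

    def best(self) -> np.ndarray:
        """APC scores when available, raw otherwise."""
        return self.raw if self.apc is None else self.apc


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def one_hot(sequences: np.ndarray, q: int) -> np.ndarray:
    """One-hot encode an integer (B, L) matrix to float64 (B, L, q)."""
    B, L = sequences.shape
    Z = np.zeros((B, L, q), dtype=np.float64)
    Z[np.arange(B)[:, None], np.arange(L)[None, :], sequences] = 1.0
    return Z


def neg_pseudo_loglik(
    model: PottsModel, msa: LabeledMSA, reg: RegularizationConfig
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Weighted negative pseudo-log-likelihood and its exact gradient.

    The data term is −(1/B_eff) Σ_b ω_b Σ_i log P(s_i^b | s_\\i^b) with the
    site-conditional softmax over h_i(a) + Σ_{j≠i} J_ij(a, s_j^b); L2
    penalties on h and on each directed block J[i, j] are added.  The
    coupling blocks are treated as directed (per-site) parameters, matching
    the asymmetric inference, so the returned gradient is exact for
    independent perturbations of any J[i, j] entry.
    """
    s, w = msa.sequences, msa.weights
    B, L = s.shape
    q = model.q
    B_eff = w.sum()
    if B_eff <= 0:
        raise ValueError("degenerate weights: B_eff must be positive")
    if not (np.isfinite(model.h).all() and np.isfinite(model.J).all()):
        raise FloatingPointError("non-finite model parameters")
    wn = w / B_eff
    Z = one_hot(s, q)
    gh = np.zeros_like(model.h)
    gJ = np.zeros_like(model.J)
    f = 0.0
    rows = np.arange(B)
    for i in range(L):
        Ji = model.J[i].copy()
        Ji[i] = 0.0
        # logits[b, a] = h_i(a) + Σ_{j≠i} J_ij(a, s_j^b)
        logits = model.h[i] + np.tensordot(Z, Ji, axes=([1, 2], [0, 2]))
        lse = logsumexp(logits, axis=1)
        f -= float(wn @ (logits[rows, s[:, i]] - lse))
        P = np.exp(logits - lse[:, None])
        P[rows, s[:, i]] -= 1.0
        G = wn[:, None] * P
        gh[i] = G.sum(axis=0)
        gJ[i] = np.einsum("ba,bjc->jac", G, Z)
        gJ[i, i] = 0.0
    offdiag = ~np.eye(L, dtype=bool)
    f += reg.lambda_h * float((model.h**2).sum())
    f += reg.lambda_J * float((model.J[offdiag] ** 2).sum())
    gh += 2.0 * reg.lambda_h * model.h
    gJ[offdiag] += 2.0 * reg.lambda_J * model.J[offdiag]
    return f, (gh, gJ)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _site_objective(x, X, y, wn, q, lam_h, lam_J):
    """Objective + gradient of one site's multinomial logistic regression."""
    B, D = X.shape
    h = x[:q]
    W = x[q:].reshape(D, q)
    logits = X @ W
    logits += h
    m = logits.max(axis=1, keepdims=True)
    ex = np.exp(logits - m)
    denom = ex.sum(axis=1)
    logZ = m[:, 0] + np.log(denom)
    rows = np.arange(B)
    f = -float(wn @ (logits[rows, y] - logZ))
    f += lam_h * float(h @ h) + lam_J * float((W * W).sum())
    P = ex / denom[:, None]
    P[rows, y] -= 1.0
    P *= wn[:, None]
    gh = P.sum(axis=0) + 2.0 * lam_h * h
    gW = X.T @ P
    gW += 2.0 * lam_J * W
    return f, np.concatenate([gh, gW.ravel()])


def fit_plmdca(
    msa: LabeledMSA,
    reg: RegularizationConfig | None = None,
    seed: int = 0,
) -> PottsModel:
    """Fit a Potts model by weighted asymmetric pseudo-likelihood.

    Rows with zero weight are dropped up front (they contribute nothing to
    the data term), each site's regression is solved independently with
    L-BFGS from a zero start, and the two directed estimates of every
    coupling block are averaged.  The fit is deterministic given the data,
    weights and optimizer settings; ``seed`` is accepted for interface
    uniformity and recorded nowhere else.
    """
    del seed  # deterministic: zero initialization, deterministic optimizer
    reg = reg or RegularizationConfig()
    active = np.flatnonzero(msa.weights > 0)
    if active.size < msa.B:
        msa = msa.take(active)
    if msa.B < 2:
        raise ValueError("need at least 2 rows with positive weight")
    B_eff = msa.B_eff
    if B_eff <= 0:
        raise ValueError("degenerate weights: B_eff must be positive")
    B, L, q = msa.B, msa.L, msa.q
    wn = msa.weights / B_eff
    Zflat = one_hot(msa.sequences, q).reshape(B, L * q)
    h = np.zeros((L, q))
    Jdir = np.zeros((L, L, q, q))
    n_unconverged = 0
    others = np.arange(L)
    for i in range(L):
        X = np.delete(Zflat, np.s_[i * q : (i + 1) * q], axis=1)
        x0 = np.zeros(q + (L - 1) * q * q)
        res = minimize(
            _site_objective,
            x0,
            args=(X, msa.sequences[:, i], wn, q, reg.lambda_h, reg.lambda_J),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": reg.max_iter, "gtol": reg.tol, "ftol": 1e-12},
        )
        if not res.success and "ABNORMAL" in str(res.message).upper():
            n_unconverged += 1
        h[i] = res.x[:q]
        # W[(j, c), a] -> J_ij(a, c)
        W = res.x[q:].reshape(L - 1, q, q).transpose(0, 2, 1)
        idx = np.delete(others, i)
        Jdir[i, idx] = W
    if n_unconverged:
        warnings.warn(
            f"{n_unconverged}/{L} site regressions stopped abnormally",
            ConvergenceWarning,
        )
    J = 0.5 * (Jdir + Jdir.transpose(1, 0, 3, 2))
    gap = msa.alphabet.gap_index
    return PottsModel(h=h, J=J, gap_index=gap, converged=n_unconverged == 0)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _zero_sum_gauge(blocks: np.ndarray) -> np.ndarray:
    """Double-center the last two axes (row/col means removed, grand mean added)."""
    row = blocks.mean(axis=-1, keepdims=True)
    col = blocks.mean(axis=-2, keepdims=True)
    tot = blocks.mean(axis=(-2, -1), keepdims=True)
    return blocks - row - col + tot


def frobenius_scores(model: PottsModel, apply_gauge: bool = True) -> ScoreMatrix:
    """Raw coupling scores S_ij = ||J_ij|| over the non-gap states.

    Each coupling block is first shifted to the zero-sum gauge over the
    non-gap states (toggleable), then the Frobenius norm is taken over
    those states only; couplings involving the gap never contribute.
    """
    states = np.arange(model.q)
    if model.gap_index is not None:
        states = np.delete(states, model.gap_index)
    sub = model.J[:, :, states][:, :, :, states]
    if apply_gauge:
        sub = _zero_sum_gauge(sub)
    S = np.sqrt((sub**2).sum(axis=(2, 3)))
    np.fill_diagonal(S, 0.0)
    S = 0.5 * (S + S.T)
    return ScoreMatrix(raw=S)


def apc(scores: ScoreMatrix) -> ScoreMatrix:
    """Average-product correction S̃_ij = S_ij − S_i·S_·j / S_··.

    Row, column and total means are taken over off-diagonal entries.  A
    zero total mean (all-zero score matrix) returns the raw scores
    unchanged with a warning.
    """
    S = scores.raw
    L = S.shape[0]
    if L < 2:
        raise ValueError("need at least two columns to APC-correct")
    row = S.sum(axis=1) / (L - 1)          # diagonal is zero by construction
    total = S.sum() / (L * (L - 1))
    if total == 0.0:
        warnings.warn("all-zero score matrix: APC returns raw scores unchanged")
        return ScoreMatrix(raw=S, apc=S.copy())
    corrected = S - np.outer(row, row) / total
    np.fill_diagonal(corrected, 0.0)
    return ScoreMatrix(raw=S, apc=0.5 * (corrected + corrected.T))


def ranked_pairs(
    matrix: np.ndarray, min_sep: int = 5
) -> list[tuple[int, int]]:
    """All pairs i<j with j−i ≥ min_sep, by descending score, ties by (i, j)."""
    L = matrix.shape[0]
    ii, jj = np.triu_indices(L, k=min_sep)
    order = np.lexsort((jj, ii, -matrix[ii, jj]))
    return list(zip(ii[order].tolist(), jj[order].tolist()))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: PottsModel, path: str | Path) -> None:
    np.savez_compressed(
        path,
        h=model.h,
        J=model.J,
        gap_index=np.int64(-1 if model.gap_index is None else model.gap_index),
        converged=np.bool_(model.converged),
    )


def load_model(path: str | Path) -> PottsModel:
    with np.load(path) as data:
        gap = int(data["gap_index"])
        return PottsModel(
            h=data["h"],
            J=data["J"],
            gap_index=None if gap < 0 else gap,
            converged=bool(data["converged"]),
        )


def save_scores(scores: ScoreMatrix, path: str | Path) -> None:
    """Write scores as TSV with 1-based column indices (i, j, raw, apc)."""
    L = scores.L
    ii, jj = np.triu_indices(L, k=1)
    df = pd.DataFrame(
        {
            "i": ii + 1,
            "j": jj + 1,
            "raw": scores.raw[ii, jj],
            "apc": (scores.apc if scores.apc is not None else np.full_like(scores.raw, np.nan))[ii, jj],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_scores(path: str | Path) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t")
    L = int(df["j"].max())
    raw = np.zeros((L, L))
    apc_m = np.zeros((L, L))
    ii = df["i"].to_numpy() - 1
    jj = df["j"].to_numpy() - 1
    raw[ii, jj] = df["raw"].to_numpy()
    raw[jj, ii] = df["raw"].to_numpy()
    apc_m[ii, jj] = df["apc"].to_numpy()
    apc_m[jj, ii] = df["apc"].to_numpy()
    if df["apc"].isna().all():
        return ScoreMatrix(raw=raw)
    return ScoreMatrix(raw=raw, apc=apc_m)
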
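"""Subfamily reweighting: simplex weight scans and kernel contact scores.

All sequences of subfamily k receive a common weight ω_k; the vector
(ω_1..ω_K) is swept over a regular grid on the unit simplex, a weighted
DCA is run at every grid point, and the resulting per-pair APC score
surfaces S̃_ij(ω) are condensed into subfamily-specific contact scores

    F_ijk = Σ_ω φ_k(ω) · (S̃_ij(ω) − ⟨S̃_ij⟩),

with the multilinear kernel φ_k(ω) = ω_k Π_{i≠k} (1 − ω_i) and ⟨·⟩ the
plain mean over grid points.  Large F_ijk assigns contact (i, j) to
subfamily k.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .alignment_io import LabeledMSA
from .plmdca import (
    RegularizationConfig,
    ScoreMatrix,
    apc,
    fit_plmdca,
    frobenius_scores,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightGrid:
    """Regular grid over the (K−1)-simplex with spacing ``step``."""

    K: int
    step: float
    points: np.ndarray  # (P, K), rows sum to 1

    @property
    def P(self) -> int:
        return self.points.shape[0]

    def vertex_index(self, k: int) -> int:
        """Index of the grid point with all weight on subfamily k."""
        hits = np.flatnonzero(np.isclose(self.points[:, k], 1.0, atol=1e-12))
        if hits.size != 1:
            raise ValueError(f"vertex {k} not uniquely on grid")
        return int(hits[0])


def simplex_grid(K: int, step: float) -> WeightGrid:
    """All weight vectors with entries in {0, step, 2·step, …} summing to 1.

    ``1/step`` must be an integer; the grid contains binom(1/step + K − 1,
    K − 1) points including every vertex (one-hot vector).
    """
    if K < 2:
        raise ValueError("need at least 2 subfamilies")
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9 or n < 1:
        raise ValueError(f"1/step must be an integer, got step={step}")
    points = []
    # stars and bars: bar positions -> compositions of n into K parts
    for bars in combinations(range(n + K - 1), K - 1):
        edges = (-1,) + bars + (n + K - 1,)
        comp = [edges[i + 1] - edges[i] - 1 for i in range(K)]
        points.append(comp)
    pts = np.array(points, dtype=np.float64) / n
    return WeightGrid(K=K, step=step, points=pts)


def kernel_phi(k: int, omega: np.ndarray) -> float:
    """Multilinear kernel φ_k(ω) = ω_k · Π_{i≠k} (1 − ω_i).

    Equals 1 at the k-th simplex vertex and 0 at every other vertex;
    smoothly interpolates in between.
    """
    omega = np.asarray(omega, dtype=np.float64)
    if omega.min() < -1e-9 or abs(omega.sum() - 1.0) > 1e-9:
        raise ValueError("omega must lie on the unit simplex")
    others = np.delete(np.arange(omega.size), k)
    return float(omega[k] * np.prod(1.0 - omega[others]))


def _phi_matrix(grid: WeightGrid) -> np.ndarray:
    """(P, K) matrix of kernel values over the grid."""
    return np.array(
        [[kernel_phi(k, w) for k in range(grid.K)] for w in grid.points]
    )


@dataclass
class SRScan:
    """Tensor of APC coupling scores over a simplex weight grid.

    ``scores[p]`` is the symmetric L×L APC score matrix obtained with the
    weights ``grid.points[p]``; skipped (zero-B_eff) grid points are
    flagged and hold NaN slices.  ``precision`` optionally stores the
    overall precision of the top-N predictions per grid point.
    """

    grid: WeightGrid
    scores: np.ndarray  # (P, L, L)
    skipped: np.ndarray  # (P,) bool
    precision: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.scores.shape[1]

    def valid(self) -> np.ndarray:
        return ~self.skipped


@dataclass
class SubfamilyContactScore:
    """Kernel scores F (L, L, K) and the per-pair grid-mean score."""

    F: np.ndarray
    mean_score: np.ndarray

    @property
    def K(self) -> int:
        return self.F.shape[2]

    def argmax_subfamily(self, i: int, j: int) -> int:
        return int(np.argmax(self.F[i, j]))


def _point_key(msa_digest: str, omega: np.ndarray, reg: RegularizationConfig) -> str:
    h = hashlib.sha256()
    h.update(msa_digest.encode())
    h.update(np.round(omega, 12).tobytes())
    h.update(repr(reg).encode())
    return h.hexdigest()[:24]


def run_sr_scan(
    msa: LabeledMSA,
    grid: WeightGrid,
    reg: RegularizationConfig | None = None,
    reference=None,
    N: int | None = None,
    min_sep: int = 5,
    seed: int = 0,
    cache_dir: str | Path | None = None,
) -> SRScan:
    """Run a weighted DCA at every grid point and collect APC score slices.

    At each grid point every sequence of subfamily k gets weight ω_k
    (unlabeled rows get 0); grid points where all weights vanish are
    skipped with a warning recorded in the metadata.  If ``reference``
    (a :class:`srdca.structures.ReferenceMaps`) is given, the overall
    precision of the top-N separation-eligible predictions is stored per
    grid point.  With ``cache_dir`` set, per-point score slices are
    cached on disk keyed by (alignment digest, ω, regularization), so an
    interrupted sweep resumes where it stopped.
    """
    reg = reg or RegularizationConfig()
    if msa.K != grid.K:
        raise ValueError(f"alignment has {msa.K} subfamilies, grid expects {grid.K}")
    for k in range(grid.K):
        if msa.group_rows(k).size == 0:
            raise ValueError(f"subfamily {k} has no labeled rows")
    P, L = grid.P, msa.L
    scores = np.full((P, L, L), np.nan)
    skipped = np.zeros(P, dtype=bool)
    prec = np.full(P, np.nan) if reference is not None else None
    digest = msa.digest()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    skipped_points: list[int] = []
    for p, omega in enumerate(grid.points):
        w = np.zeros(msa.B)
        for k in range(grid.K):
            w[msa.labels == k] = omega[k]
        if w.sum() <= 0:
            skipped[p] = True
            skipped_points.append(p)
            logger.warning("grid point %d (%s): B_eff = 0, skipped", p, omega)
            continue
        cache_file = (
            cache / f"{_point_key(digest, omega, reg)}.npy" if cache is not None else None
        )
        if cache_file is not None and cache_file.exists():
            scores[p] = np.load(cache_file)
        else:
            model = fit_plmdca(msa.with_weights(w), reg, seed=seed)
            scores[p] = apc(frobenius_scores(model)).apc
            if cache_file is not None:
                np.save(cache_file, scores[p])
        if reference is not None:
            from .structures import precision_at_N

            prec[p] = precision_at_N(
                ScoreMatrix(raw=scores[p], apc=scores[p]),
                reference,
                N=N or L,
                min_sep=min_sep,
            )
    meta = {
        "msa_digest": digest,
        "reg": {
            "lambda_h": reg.lambda_h,
            "lambda_J": reg.lambda_J,
            "tol": reg.tol,
            "max_iter": reg.max_iter,
        },
        "seed": seed,
        "skipped_points": skipped_points,
        "min_sep": min_sep,
    }
    return SRScan(grid=grid, scores=scores, skipped=skipped, precision=prec, metadata=meta)


def subfamily_scores(scan: SRScan) -> SubfamilyContactScore:
    """Kernel-integrate the score surfaces into per-subfamily scores F_ijk.

    Each pair's surface is first centered by its mean over (non-skipped)
    grid points, making F invariant to per-pair constant shifts; the
    kernel-weighted sum then measures how much the pair's score rides
    with subfamily k's weight.
    """
    valid = scan.valid()
    if not valid.any():
        raise ValueError("scan contains no valid grid points")
    S = scan.scores[valid]                      # (P', L, L)
    mean = S.mean(axis=0)
    phi = _phi_matrix(scan.grid)[valid]         # (P', K)
    F = np.einsum("pk,pij->ijk", phi, S - mean)
    return SubfamilyContactScore(F=F, mean_score=mean)


def all_candidate_pairs(L: int, min_sep: int = 5) -> list[tuple[int, int]]:
    """Default candidate set: all pairs with sequence separation ≥ min_sep."""
    ii, jj = np.triu_indices(L, k=min_sep)
    return list(zip(ii.tolist(), jj.tolist()))


def rank_subfamily_contacts(
    F: SubfamilyContactScore,
    k: int,
    candidates: list[tuple[int, int]],
    top_n: int,
) -> list[tuple[int, int]]:
    """Top-``top_n`` candidate pairs by F_ijk, descending, ties by (i, j)."""
    if not candidates:
        raise ValueError("candidate pair set is empty")
    if top_n > len(candidates):
        warnings.warn(
            f"top_n={top_n} exceeds {len(candidates)} candidates; returning all"
        )
        top_n = len(candidates)
    ranked = sorted(candidates, key=lambda ij: (-F.F[ij[0], ij[1], k], ij[0], ij[1]))
    return ranked[:top_n]


def interface_average_score(
    scan: SRScan, interface: "set[tuple[int, int]] | list[tuple[int, int]]"
) -> np.ndarray:
    """Mean APC score of an interface's pairs at each grid point.

    Returns one value per grid point (NaN at skipped points); used for
    triangle-plot surfaces of whole-interface coupling strength.
    """
    pairs = sorted(interface)
    if not pairs:
        raise ValueError("interface pair set is empty")
    L = scan.L
    for i, j in pairs:
        if not (0 <= i < L and 0 <= j < L):
            raise ValueError(f"pair ({i}, {j}) outside [0, {L})")
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    return scan.scores[:, ii, jj].mean(axis=1)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_scan(scan: SRScan, path: str | Path) -> None:
    np.savez_compressed(
        path,
        grid_points=scan.grid.points,
        grid_step=np.float64(scan.grid.step),
        scores=scan.scores,
        skipped=scan.skipped,
        precision=scan.precision if scan.precision is not None else np.array([]),
        metadata=json.dumps(scan.metadata),
    )


def load_scan(path: str | Path) -> SRScan:
    with np.load(path, allow_pickle=False) as data:
        pts = data["grid_points"]
        grid = WeightGrid(K=pts.shape[1], step=float(data["grid_step"]), points=pts)
        prec = data["precision"]
        return SRScan(
            grid=grid,
            scores=data["scores"],
            skipped=data["skipped"],
            precision=None if prec.size == 0 else prec,
            metadata=json.loads(str(data["metadata"])),
        )
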
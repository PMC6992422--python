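"""Synthetic labeled alignments with planted subfamily-specific couplings.

The generator mimics the structure of a protein family whose subfamilies
share one fold but carry distinct homo-oligomerization interfaces: all
subfamily models share the same random fields and the same coupling
blocks on a set of shared ("fold") pairs, and each subfamily additionally
receives coupling blocks on its own specific ("interface") pairs.
Sequences are drawn from each subfamily's Potts model by single-site
Gibbs sampling, so the full reweighting pipeline can be exercised with
exact ground truth and no external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import Alphabet, LabeledMSA, write_alignment
from .plmdca import PottsModel

#: residue letters used for gap-free synthetic alphabets
_SYNTH_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_SHARED = ((0, 10), (2, 14), (4, 20), (6, 26), (8, 17), (12, 23))
_DEFAULT_SPECIFIC = (
    ((1, 9), (3, 16), (5, 22)),
    ((7, 15), (11, 21), (13, 27)),
    ((2, 28), (9, 19), (6, 13)),
)


class BenchmarkConfigError(ValueError):
    pass


@dataclass(frozen=True)
class BenchmarkConfig:
    """Planted-coupling benchmark settings.

    Defaults model three subfamilies of 500 sequences each over a
    30-column, 8-state alignment, with 6 shared fold pairs and 3
    interface pairs per subfamily (all at sequence separation ≥ 5).
    Coupling strengths are target Frobenius norms of zero-sum-gauge
    blocks, so planted strength is directly comparable to fitted scores.
    """

    L: int = 30
    q: int = 8
    K: int = 3
    B_k: tuple[int, ...] = (500, 500, 500)
    shared_pairs: tuple[tuple[int, int], ...] = _DEFAULT_SHARED
    specific_pairs: tuple[tuple[tuple[int, int], ...], ...] = _DEFAULT_SPECIFIC
    shared_strength: float = 3.0
    specific_strength: float = 3.0
    field_scale: float = 0.3
    sweeps: int = 25
    burn_in: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or len(self.B_k) != self.K or len(self.specific_pairs) != self.K:
            raise BenchmarkConfigError("K, B_k and specific_pairs must agree")
        if any(b <= 0 for b in self.B_k):
            raise BenchmarkConfigError("all subfamily sizes must be positive")
        if not (2 <= self.q <= len(_SYNTH_SYMBOLS)):
            raise BenchmarkConfigError(f"q must be in [2, {len(_SYNTH_SYMBOLS)}]")
        all_pairs: list[tuple[int, int]] = list(self.shared_pairs)
        for pairs in self.specific_pairs:
            all_pairs.extend(pairs)
        seen = set()
        for i, j in all_pairs:
            if not (0 <= i < j < self.L):
                raise BenchmarkConfigError(f"pair ({i}, {j}) invalid for L={self.L}")
            if (i, j) in seen:
                raise BenchmarkConfigError(
                    f"pair ({i}, {j}) appears in more than one category"
                )
            seen.add((i, j))
        if self.sweeps < 1 or self.burn_in < 0:
            raise BenchmarkConfigError("sweeps >= 1 and burn_in >= 0 required")

    @property
    def alphabet(self) -> Alphabet:
        return Alphabet(_SYNTH_SYMBOLS[: self.q])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BenchmarkConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("B_k", "shared_pairs"):
            if key in raw:
                raw[key] = tuple(map(tuple, raw[key])) if key == "shared_pairs" else tuple(raw[key])
        if "specific_pairs" in raw:
            raw["specific_pairs"] = tuple(
                tuple(map(tuple, group)) for group in raw["specific_pairs"]
            )
        return cls(**raw)


@dataclass
class BenchmarkTruth:
    """Generated benchmark: models, ground-truth maps and the labeled MSA."""

    config: BenchmarkConfig
    models: list[PottsModel]
    shared_map: frozenset
    specific_maps: tuple[frozenset, ...]
    msa: LabeledMSA


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _gauge_block(rng: np.random.Generator, q: int, strength: float) -> np.ndarray:
    """Random q×q coupling block in the zero-sum gauge with a set Frobenius norm."""
    M = rng.standard_normal((q, q))
    M = M - M.mean(axis=0, keepdims=True) - M.mean(axis=1, keepdims=True) + M.mean()
    norm = np.linalg.norm(M)
    if norm == 0:
        raise RuntimeError("degenerate random block")
    return M * (strength / norm)


def _insert_block(J: np.ndarray, i: int, j: int, block: np.ndarray) -> None:
    J[i, j] = block
    J[j, i] = block.T


def plant_models(config: BenchmarkConfig) -> list[PottsModel]:
    """One Potts model per subfamily: common fields and shared-pair blocks,
    plus subfamily-specific blocks on each subfamily's own pairs.

    The draw order is fixed, so identical configs (including seed) give
    bit-identical models.
    """
    rng = np.random.default_rng(config.seed)
    L, q = config.L, config.q
    h = rng.normal(0.0, config.field_scale, size=(L, q))
    J_shared = np.zeros((L, L, q, q))
    for i, j in config.shared_pairs:
        _insert_block(J_shared, i, j, _gauge_block(rng, q, config.shared_strength))
    models = []
    for k in range(config.K):
        J = J_shared.copy()
        for i, j in config.specific_pairs[k]:
            _insert_block(J, i, j, _gauge_block(rng, q, config.specific_strength))
        models.append(PottsModel(h=h.copy(), J=J, gap_index=None))
    return models


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------

def gibbs_sample(
    model: PottsModel,
    B: int,
    sweeps: int,
    burn_in: int,
    seed: int,
    alphabet: Alphabet | None = None,
    id_prefix: str = "seq",
) -> LabeledMSA:
    """Draw B sequences from a Potts model by single-site Gibbs sampling.

    Each sequence is an independent chain started from a uniform random
    configuration; ``burn_in`` sweeps are discarded, ``sweeps`` further
    full-alignment sweeps are run, and the final configurations are
    returned.  All chains are updated in lockstep (vectorized over B).
    """
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    L, q = model.L, model.q
    rng = np.random.default_rng(seed)
    s = rng.integers(0, q, size=(B, L))
    Z = np.zeros((B, L, q))
    Z[np.arange(B)[:, None], np.arange(L)[None, :], s] = 1.0
    rows = np.arange(B)
    J = model.J.copy()
    J[np.arange(L), np.arange(L)] = 0.0
    for _ in range(burn_in + sweeps):
        for i in range(L):
            logits = model.h[i] + np.tensordot(Z, J[i], axes=([1, 2], [0, 2]))
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            cum = np.cumsum(p, axis=1)
            u = rng.random(B) * cum[:, -1]
            new = (cum < u[:, None]).sum(axis=1)
            Z[rows, i, s[:, i]] = 0.0
            s[:, i] = new
            Z[rows, i, new] = 1.0
    alphabet = alphabet or Alphabet(_SYNTH_SYMBOLS[:q])
    return LabeledMSA(
        sequences=s.astype(np.int8),
        ids=[f"{id_prefix}{b}" for b in range(B)],
        alphabet=alphabet,
    )


# ---------------------------------------------------------------------------
# benchmark assembly
# ---------------------------------------------------------------------------

def make_benchmark(config: BenchmarkConfig) -> BenchmarkTruth:
    """Sample every subfamily's alignment, label and concatenate.

    Per-subfamily sampling seeds are derived from the config seed, so the
    whole benchmark is reproducible bit-exactly from the config alone.
    """
    models = plant_models(config)
    child_seeds = np.random.SeedSequence(config.seed).generate_state(config.K) % (2**31)
    blocks = []
    for k in range(config.K):
        blocks.append(
            gibbs_sample(
                models[k],
                B=config.B_k[k],
                sweeps=config.sweeps,
                burn_in=config.burn_in,
                seed=int(child_seeds[k]),
                alphabet=config.alphabet,
                id_prefix=f"sub{k + 1}_seq",
            )
        )
    sequences = np.vstack([b.sequences for b in blocks])
    ids = [i for b in blocks for i in b.ids]
    labels = np.concatenate(
        [np.full(config.B_k[k], k, dtype=np.int64) for k in range(config.K)]
    )
    label_names = tuple(f"sub{k + 1}" for k in range(config.K))
    msa = LabeledMSA(
        sequences=sequences,
        ids=ids,
        alphabet=config.alphabet,
        labels=labels,
        label_names=label_names,
    )
    return BenchmarkTruth(
        config=config,
        models=models,
        shared_map=frozenset(config.shared_pairs),
        specific_maps=tuple(frozenset(p) for p in config.specific_pairs),
        msa=msa,
    )


def write_benchmark(truth: BenchmarkTruth, prefix: str | Path) -> None:
    """Write FASTA + label TSV + ground-truth pair TSVs + config JSON."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_alignment(truth.msa, f"{prefix}.fasta", format="fasta")
    with open(f"{prefix}.labels.tsv", "w") as fh:
        for rid, lab in zip(truth.msa.ids, truth.msa.labels):
            fh.write(f"{rid}\t{truth.msa.label_names[lab]}\n")
    with open(f"{prefix}.truth.tsv", "w") as fh:
        fh.write("i\tj\tcategory\n")
        for i, j in sorted(truth.shared_map):
            fh.write(f"{i + 1}\t{j + 1}\tshared\n")
        for k, pairs in enumerate(truth.specific_maps):
            for i, j in sorted(pairs):
                fh.write(f"{i + 1}\t{j + 1}\t{truth.msa.label_names[k]}\n")
    truth.config.to_json(f"{prefix}.config.json")
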
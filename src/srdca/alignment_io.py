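"""Reading, encoding, filtering, subsampling and labeling of multiple sequence alignments.

Alignments are held as integer matrices over a small categorical alphabet
(20 amino acids plus gap for real protein data).  Every row carries an
identifier, an optional subfamily label and a non-negative statistical
weight; the weights are what the subfamily-reweighting machinery turns.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: 20 amino acids followed by the gap symbol (21 states in total).
PROTEIN_GAPPED = "ACDEFGHIKLMNPQRSTVWY-"


class AlignmentFormatError(ValueError):
    """Raised for ragged or otherwise unparseable alignments."""


class EmptyAlignmentError(ValueError):
    """Raised when an alignment source contains no sequences."""


class DegenerateSampleError(ValueError):
    """Raised when a requested subsample would contain zero rows."""


class LabelingError(ValueError):
    """Raised for unusable subfamily label tables."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered categorical alphabet with an optional gap state.

    The default is the 21-letter protein alphabet (gap last).  Synthetic
    benchmarks use smaller gap-free alphabets; all downstream code reads
    ``q`` and ``gap_index`` from here rather than assuming 21 states.
    """

    symbols: str = PROTEIN_GAPPED

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least two states")

    @property
    def q(self) -> int:
        return len(self.symbols)

    @property
    def gap_index(self) -> int | None:
        return self.symbols.index("-") if "-" in self.symbols else None

    def _lut(self) -> np.ndarray:
        lut = np.full(256, -1, dtype=np.int16)
        for i, c in enumerate(self.symbols):
            lut[ord(c)] = i
        return lut

    def encode(self, seq: str) -> np.ndarray:
        """Encode one sequence string; unknown/ambiguous residues map to the gap."""
        codes = self._lut()[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
        if (codes < 0).any():
            if self.gap_index is None:
                bad = sorted({seq[i] for i in np.flatnonzero(codes < 0)})
                raise AlignmentFormatError(
                    f"symbols {bad} not in gap-free alphabet {self.symbols!r}"
                )
            codes = np.where(codes < 0, self.gap_index, codes)
        return codes.astype(np.int8)

    def decode(self, codes: np.ndarray) -> str:
        arr = np.asarray(codes)
        if arr.min(initial=0) < 0 or arr.max(initial=0) >= self.q:
            raise ValueError("codes outside alphabet range")
        return "".join(self.symbols[c] for c in arr)


#: label value used for rows without a subfamily assignment
UNLABELED = -1


@dataclass
class LabeledMSA:
    """Encoded alignment with per-row identifiers, subfamily labels and weights.

    ``sequences`` is a ``(B, L)`` integer matrix with entries in ``[0, q)``.
    ``labels`` holds a subfamily index per row (``UNLABELED`` = -1 for
    unassigned rows) indexing into ``label_names``.  ``weights`` are the
    per-sequence statistical weights entering the pseudo-likelihood; their
    sum is the effective sample size ``B_eff``.
    """

    sequences: np.ndarray
    ids: list[str]
    alphabet: Alphabet = field(default_factory=Alphabet)
    labels: np.ndarray | None = None
    label_names: tuple[str, ...] = ()
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        if self.sequences.ndim != 2:
            raise ValueError("sequences must be a (B, L) matrix")
        B = self.sequences.shape[0]
        if len(self.ids) != B:
            raise ValueError("one id per row required")
        if self.sequences.size and (
            self.sequences.min() < 0 or self.sequences.max() >= self.alphabet.q
        ):
            raise ValueError("sequence entries outside alphabet range")
        if self.labels is None:
            self.labels = np.full(B, UNLABELED, dtype=np.int64)
        else:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (B,):
                raise ValueError("labels must be one per row")
            if self.labels.max(initial=UNLABELED) >= len(self.label_names):
                raise ValueError("label index outside label_names")
        if self.weights is None:
            self.weights = np.ones(B, dtype=np.float64)
        else:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if self.weights.shape != (B,):
                raise ValueError("weights must be one per row")
            if (self.weights < 0).any():
                raise ValueError("weights must be non-negative")

    # ---- basic geometry -------------------------------------------------
    @property
    def B(self) -> int:
        return self.sequences.shape[0]

    @property
    def L(self) -> int:
        return self.sequences.shape[1]

    @property
    def q(self) -> int:
        return self.alphabet.q

    @property
    def B_eff(self) -> float:
        return float(self.weights.sum())

    @property
    def K(self) -> int:
        """Number of named subfamilies."""
        return len(self.label_names)

    # ---- row-level helpers ----------------------------------------------
    def take(self, index: np.ndarray | Sequence[int]) -> "LabeledMSA":
        index = np.asarray(index, dtype=np.int64)
        return LabeledMSA(
            sequences=self.sequences[index].copy(),
            ids=[self.ids[i] for i in index],
            alphabet=self.alphabet,
            labels=self.labels[index].copy(),
            label_names=self.label_names,
            weights=self.weights[index].copy(),
        )

    def with_weights(self, weights: np.ndarray) -> "LabeledMSA":
        return replace(self, weights=np.asarray(weights, dtype=np.float64).copy())

    def group_rows(self, k: int) -> np.ndarray:
        """Row indices of subfamily ``k``."""
        return np.flatnonzero(self.labels == k)

    def digest(self) -> str:
        """Content hash over sequences and labels (used for scan caching)."""
        h = hashlib.sha256()
        h.update(self.sequences.tobytes())
        h.update(self.labels.tobytes())
        h.update("|".join(self.label_names).encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _drop_insert_columns(rows: list[str]) -> list[str]:
    """Remove Stockholm insert columns (any lowercase residue or '.')."""
    ncol = len(rows[0])
    keep = [
        j
        for j in range(ncol)
        if not any(r[j] == "." or r[j].islower() for r in rows)
    ]
    return ["".join(r[j] for j in keep) for r in rows]


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    alphabet: Alphabet | None = None,
) -> LabeledMSA:
    """Read a FASTA or Stockholm alignment into a :class:`LabeledMSA`.

    Rows get unit weights and no labels.  Stockholm insert columns
    (lowercase letters / '.') are dropped so only match columns remain;
    unknown residue characters encode as the gap state.
    """
    alphabet = alphabet or Alphabet()
    path = Path(path)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    elif format == "stockholm":
        try:
            records = list(AlignIO.read(str(path), "stockholm"))
        except ValueError as exc:
            raise AlignmentFormatError(f"cannot parse {path}: {exc}") from exc
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    if not records:
        raise EmptyAlignmentError(f"no sequences in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentFormatError(
            f"ragged alignment in {path}: row lengths {sorted(lengths)}"
        )
    if format == "stockholm":
        rows = _drop_insert_columns(rows)
    seqs = np.stack([alphabet.encode(r) for r in rows])
    return LabeledMSA(sequences=seqs, ids=ids, alphabet=alphabet)


def write_alignment(msa: LabeledMSA, path: str | Path, format: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(msa.alphabet.decode(row)), id=rid, description="")
        for rid, row in zip(msa.ids, msa.sequences)
    ]
    if format == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif format == "stockholm":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "stockholm")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")


# ---------------------------------------------------------------------------
# filtering / subsampling / labeling
# ---------------------------------------------------------------------------

def identity_filter(msa: LabeledMSA, max_identity: float = 0.9) -> LabeledMSA:
    """Greedy identity filter: keep a sequence iff it is at most
    ``max_identity`` fractionally identical to every previously kept one.

    Identity is computed over all columns, gaps counting as an ordinary
    21st symbol.  The pass is order dependent (first kept wins), which
    makes it idempotent at a fixed threshold.
    """
    if not (0.0 < max_identity < 1.0):
        raise ValueError("max_identity must be in (0, 1)")
    S = msa.sequences
    kept: list[int] = []
    kept_rows = np.empty((0, msa.L), dtype=S.dtype)
    for b in range(msa.B):
        if kept_rows.shape[0]:
            ident = (kept_rows == S[b]).mean(axis=1)
            if (ident > max_identity).any():
                continue
        kept.append(b)
        kept_rows = np.vstack([kept_rows, S[b][None, :]])
    return msa.take(kept)


def subsample(msa: LabeledMSA, B_f: float, seed: int) -> LabeledMSA:
    """Uniform seeded sample without replacement of ``round(B_f * B)`` rows.

    Rounding is half-up; original row order is preserved in the output.
    """
    if not (0.0 < B_f <= 1.0):
        raise ValueError("B_f must be in (0, 1]")
    n = int(np.floor(B_f * msa.B + 0.5))
    if n == 0:
        raise DegenerateSampleError(
            f"B_f={B_f} of B={msa.B} rows yields an empty sample"
        )
    rng = np.random.default_rng(seed)
    index = np.sort(rng.choice(msa.B, size=n, replace=False))
    return msa.take(index)


def load_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``sequence_id <tab> subfamily_name`` table."""
    table: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LabelingError(f"{path}:{lineno}: expected two tab-separated fields")
        sid, name = parts
        if sid in table and table[sid] != name:
            raise LabelingError(f"{path}:{lineno}: conflicting labels for id {sid!r}")
        table[sid] = name
    if not table:
        raise LabelingError(f"empty label table {path}")
    return table


def attach_labels(
    msa: LabeledMSA, label_table: Mapping[str, str] | Iterable[tuple[str, str]]
) -> LabeledMSA:
    """Attach subfamily labels from an id→subfamily-name table.

    Table entries whose ids do not occur in the alignment are ignored with
    a warning; alignment rows absent from the table stay unlabeled.
    Duplicate ids with conflicting labels are an error.
    """
    if not isinstance(label_table, Mapping):
        table: dict[str, str] = {}
        for sid, name in label_table:
            if sid in table and table[sid] != name:
                raise LabelingError(f"conflicting labels for id {sid!r}")
            table[sid] = name
        label_table = table
    names = sorted({label_table[i] for i in msa.ids if i in label_table})
    if not names:
        raise LabelingError("no alignment row matches the label table")
    name_to_idx = {n: i for i, n in enumerate(names)}
    labels = np.full(msa.B, UNLABELED, dtype=np.int64)
    matched = 0
    for row, sid in enumerate(msa.ids):
        if sid in label_table:
            labels[row] = name_to_idx[label_table[sid]]
            matched += 1
    extra = len(set(label_table) - set(msa.ids))
    if extra:
        logger.warning("label table has %d ids not present in the alignment", extra)
    return replace(msa, labels=labels, label_names=tuple(names))
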
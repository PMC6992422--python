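"""Reference contact maps from structures and contact-prediction metrics.

Residue pairs are in contact when any pair of heavy atoms lies below a
distance threshold (5 Å default — deliberately stringent so that nearby
homodimer interfaces stay disjoint).  Intra-molecular contacts come from
residue pairs of one chain, inter-molecular ones from distinct chains of
the declared biological assembly.  Structure residues are mapped onto
alignment columns by global pairwise alignment against the alignment
consensus; the family-level reference combines the intra-molecular union
across structures with per-structure interfaces defined as the
inter-molecular contacts not explained intra-molecularly anywhere.

All in-memory residue/column indices are 0-based; TSV exports are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .alignment_io import LabeledMSA
from .plmdca import ScoreMatrix, ranked_pairs

logger = logging.getLogger(__name__)


class AssemblyError(ValueError):
    pass


class MappingQualityError(ValueError):
    pass


@dataclass
class Chain:
    """One polymer chain: name, one-letter sequence, heavy-atom coordinates.

    ``coords[r]`` is the (n_atoms, 3) array of residue r's heavy atoms;
    residues are indexed by position in the chain (0-based).
    """

    name: str
    sequence: str
    coords: list[np.ndarray]

    @property
    def n_res(self) -> int:
        return len(self.sequence)


@dataclass
class Structure:
    """Polymer chains of one structure (or expanded biological assembly)."""

    source: str
    chains: list[Chain]


@dataclass
class ContactMap:
    """Residue-pair contacts with per-pair kind ('intra' or 'inter').

    Pairs are stored with i ≤ j in the residue (or, after remapping, MSA
    column) index space of a single chain — the map assumes a
    homo-oligomeric assembly whose chains share one sequence.
    """

    pairs: dict[tuple[int, int], str]
    source: str = ""

    @property
    def intra(self) -> set[tuple[int, int]]:
        return {p for p, kind in self.pairs.items() if kind == "intra"}

    @property
    def inter(self) -> set[tuple[int, int]]:
        return {p for p, kind in self.pairs.items() if kind == "inter"}

    def remap(self, mapping: dict[int, int]) -> "ContactMap":
        """Apply a residue→column mapping, dropping unmapped residues."""
        out: dict[tuple[int, int], str] = {}
        for (i, j), kind in self.pairs.items():
            if i in mapping and j in mapping:
                a, b = sorted((mapping[i], mapping[j]))
                # an intra contact anywhere wins over an inter duplicate
                if out.get((a, b)) != "intra":
                    out[(a, b)] = kind
        return ContactMap(pairs=out, source=self.source)


@dataclass
class ReferenceMaps:
    """Family-level reference: intra-molecular union + named interfaces.

    Interface pair sets are disjoint from ``intra_union`` by construction
    and exclude self-pairs (i, i), which coupling analysis cannot score.
    """

    intra_union: frozenset
    interfaces: dict[str, frozenset]

    def __post_init__(self) -> None:
        for name, pairs in self.interfaces.items():
            if pairs & self.intra_union:
                raise ValueError(f"interface {name!r} overlaps the intra union")

    @property
    def global_pairs(self) -> frozenset:
        out = set(self.intra_union)
        for pairs in self.interfaces.values():
            out |= pairs
        return frozenset(out)


# ---------------------------------------------------------------------------
# structure loading
# ---------------------------------------------------------------------------

def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def load_structure(path: str | Path, assembly: str | None = None) -> Structure:
    """Load a PDB/mmCIF file, optionally expanding a named biological assembly.

    Waters, ligands, hydrogens and alternate conformations are removed;
    only amino-acid residues with at least one heavy atom are kept.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_ligands_and_waters()
    st.remove_hydrogens()
    st.remove_alternative_conformations()
    st.remove_empty_chains()
    model = st[0]
    if assembly is not None:
        names = [a.name for a in st.assemblies]
        match = [a for a in st.assemblies if a.name == str(assembly)]
        if not match:
            raise AssemblyError(
                f"assembly {assembly!r} not in {path.name}; available: {names}"
            )
        model = gemmi.make_assembly(
            match[0], model, gemmi.HowToNameCopiedChain.AddNumber
        )
    chains: list[Chain] = []
    for chain in model:
        seq_chars: list[str] = []
        coords: list[np.ndarray] = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            xyz = np.array(
                [[a.pos.x, a.pos.y, a.pos.z] for a in res if not a.is_hydrogen()]
            )
            if xyz.size == 0:
                continue
            seq_chars.append(_one_letter(res.name))
            coords.append(xyz)
        if coords:
            chains.append(Chain(name=chain.name, sequence="".join(seq_chars), coords=coords))
    if not chains:
        raise ValueError(f"no polymer chains found in {path}")
    return Structure(source=path.stem, chains=chains)


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def _chain_atoms(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    xyz = np.vstack(chain.coords)
    res_idx = np.concatenate(
        [np.full(len(c), r) for r, c in enumerate(chain.coords)]
    )
    return xyz, res_idx


def heavy_atom_contact_map(
    structure: Structure, threshold: float = 5.0
) -> ContactMap:
    """Residue-level contact map at a strict heavy-atom distance threshold.

    A pair is in contact iff the minimum heavy-atom distance is strictly
    below ``threshold``.  Contacts within one chain are 'intra' (i < j);
    contacts between distinct chains are 'inter' and pooled over all
    chain pairs of the assembly, symmetrized to i ≤ j (self-pairs (i, i)
    are recorded but never credited by prediction metrics).
    """
    trees = []
    for chain in structure.chains:
        xyz, res_idx = _chain_atoms(chain)
        if not np.isfinite(xyz).all():
            raise ValueError(f"non-finite coordinates in chain {chain.name}")
        trees.append((cKDTree(xyz), xyz, res_idx))
    intra: set[tuple[int, int]] = set()
    inter: set[tuple[int, int]] = set()
    for ci, (tree_i, xyz_i, res_i) in enumerate(trees):
        for cj in range(ci, len(trees)):
            tree_j, xyz_j, res_j = trees[cj]
            hits = tree_i.query_ball_tree(tree_j, r=threshold)
            for ai, neighbors in enumerate(hits):
                for aj in neighbors:
                    if np.linalg.norm(xyz_i[ai] - xyz_j[aj]) >= threshold:
                        continue
                    ri, rj = int(res_i[ai]), int(res_j[aj])
                    if ci == cj:
                        if ri < rj:
                            intra.add((ri, rj))
                    else:
                        inter.add((min(ri, rj), max(ri, rj)))
    # a pair that is an intra contact takes the 'intra' kind even if it is
    # also seen across chains; the inter record would be unusable anyway
    pairs = {p: "inter" for p in inter}
    pairs.update({p: "intra" for p in intra})
    return ContactMap(pairs=pairs, source=structure.source)


# ---------------------------------------------------------------------------
# structure -> MSA mapping
# ---------------------------------------------------------------------------

def consensus_sequence(msa: LabeledMSA) -> str:
    """Per-column majority non-gap residue ('X' for all-gap columns)."""
    out = []
    gap = msa.alphabet.gap_index
    for col in msa.sequences.T:
        counts = np.bincount(col, minlength=msa.q)
        if gap is not None:
            counts[gap] = 0
        if counts.sum() == 0:
            out.append("X")
        else:
            out.append(msa.alphabet.symbols[int(counts.argmax())])
    return "".join(out)


def map_structure_to_msa(
    chain_sequence: str,
    msa: LabeledMSA,
    min_identity: float = 0.3,
) -> dict[int, int]:
    """Map chain residue positions to alignment columns (both 0-based).

    Global pairwise alignment (BLOSUM62, affine gaps, free end gaps) of
    the chain sequence against the alignment consensus; residues map
    only to aligned match columns.  Raises if the aligned identity falls
    below ``min_identity``.
    """
    consensus = consensus_sequence(msa)
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.target_end_gap_score = 0.0
    aligner.query_end_gap_score = 0.0
    aln = aligner.align(consensus, chain_sequence.upper())[0]
    mapping: dict[int, int] = {}
    matches = 0
    aligned = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for offset in range(t1 - t0):
            col, res = t0 + offset, q0 + offset
            mapping[res] = col
            aligned += 1
            if consensus[col] == chain_sequence[res].upper():
                matches += 1
    if aligned == 0 or matches / aligned < min_identity:
        raise MappingQualityError(
            f"chain/consensus identity {matches}/{aligned} below floor {min_identity}"
        )
    return mapping


# ---------------------------------------------------------------------------
# reference construction and metrics
# ---------------------------------------------------------------------------

def build_reference_maps(maps: list[ContactMap]) -> ReferenceMaps:
    """Combine mapped contact maps into the family-level reference.

    The intra-molecular union pools intra pairs across all structures;
    each structure's interface is its inter pairs minus that union (an
    inter pair that is an intra contact in any structure cannot define a
    subfamily-specific feature) and minus self-pairs.
    """
    if not maps:
        raise ValueError("need at least one contact map")
    intra_union = frozenset(p for m in maps for p in m.intra)
    interfaces = {
        m.source: frozenset(
            p for p in m.inter if p not in intra_union and p[0] != p[1]
        )
        for m in maps
    }
    return ReferenceMaps(intra_union=intra_union, interfaces=interfaces)


def precision_at_N(
    scores: ScoreMatrix,
    reference: ReferenceMaps,
    N: int,
    min_sep: int = 5,
) -> float:
    """Fraction of the N top-scored eligible pairs present in the reference.

    Eligible pairs satisfy j − i ≥ min_sep and are ranked by APC score
    (raw if no APC present), ties broken by (i, j).
    """
    if N < 1:
        raise ValueError("N must be positive")
    top = ranked_pairs(scores.best(), min_sep=min_sep)
    if len(top) < N:
        raise ValueError(f"only {len(top)} eligible pairs for N={N}")
    hits = sum(1 for p in top[:N] if p in reference.global_pairs)
    return hits / N


def interface_fraction_at_N(
    scores: ScoreMatrix,
    interface: "frozenset | set",
    N: int,
    min_sep: int = 5,
) -> float:
    """|top-N predictions ∩ interface| / |interface|."""
    if not interface:
        raise ValueError("interface is empty")
    top = ranked_pairs(scores.best(), min_sep=min_sep)
    if len(top) < N:
        raise ValueError(f"only {len(top)} eligible pairs for N={N}")
    hits = sum(1 for p in top[:N] if p in interface)
    return hits / len(interface)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_contact_map(cmap: ContactMap, path: str | Path) -> None:
    """TSV export (i, j, kind, source) with 1-based indices."""
    rows = [
        {"i": i + 1, "j": j + 1, "kind": kind, "source": cmap.source}
        for (i, j), kind in sorted(cmap.pairs.items())
    ]
    pd.DataFrame(rows, columns=["i", "j", "kind", "source"]).to_csv(
        path, sep="\t", index=False
    )


def load_contact_map(path: str | Path) -> ContactMap:
    df = pd.read_csv(path, sep="\t")
    pairs = {
        (int(r.i) - 1, int(r.j) - 1): str(r.kind) for r in df.itertuples()
    }
    source = str(df["source"].iloc[0]) if len(df) else ""
    return ContactMap(pairs=pairs, source=source)
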
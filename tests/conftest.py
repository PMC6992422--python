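import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from srdca.sr_engine import run_sr_scan, simplex_grid
from srdca.synthetic import BenchmarkConfig, make_benchmark

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_truth():
    """Default planted benchmark: K=3 subfamilies x 500 sequences, L=30, q=8."""
    return make_benchmark(BenchmarkConfig())


@pytest.fixture(scope="session")
def coarse_grid():
    return simplex_grid(3, 0.25)


@pytest.fixture(scope="session")
def default_scan(default_truth, coarse_grid):
    """SR scan of the default benchmark over the step-0.25 simplex grid."""
    return run_sr_scan(default_truth.msa, coarse_grid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def toy_pdb_text(chains, waters=False):
    """Minimal synthetic PDB text: one CA atom per residue at a given coordinate.

    ``chains`` maps a chain id to a list of (one-letter residue, (x, y, z)).
    """
    lines = []
    serial = 1
    for chain_id, residues in chains.items():
        for resno, (aa, xyz) in enumerate(residues, 1):
            x, y, z = xyz
            lines.append(
                f"ATOM  {serial:5d}  CA  {THREE_LETTER[aa]} {chain_id}{resno:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        if waters:
            lines.append(
                f"HETATM{serial:5d}  O   HOH {chain_id} 900    "
                f"{99.0:8.3f}{99.0:8.3f}{99.0:8.3f}  1.00  0.00           O"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
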
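import math

import numpy as np
import pytest

from hubscope.structio import AtomRecord, StructureModel


def random_toy_complex(rng: np.random.Generator, max_residues: int = 5,
                       max_atoms_per_res: int = 3, box: float = 15.0,
                       with_hydrogens: bool = True) -> StructureModel:
    """Random two-chain complex, <= 50 atoms, heavy atoms plus optional Hs."""
    atoms = []
    for chain in ("A", "B"):
        n_res = int(rng.integers(1, max_residues + 1))
        for resi in range(1, n_res + 1):
            n_at = int(rng.integers(1, max_atoms_per_res + 1))
            for k in range(n_at):
                x, y, z = rng.uniform(0, box, size=3)
                atoms.append(AtomRecord(chain, resi, "ALA", f"C{k}", "C",
                                        x, y, z))
            if with_hydrogens and rng.random() < 0.5:
                x, y, z = rng.uniform(0, box, size=3)
                atoms.append(AtomRecord(chain, resi, "ALA", "H", "H", x, y, z))
    return StructureModel(atoms)


def oracle_contact_and_distance(model: StructureModel, chain_a: str,
                                chain_b: str, a: float, b: float):
    """Plain nested-loop reference for the residue contact/distance maps."""
    res_a = [k for k in model.chain_residues(chain_a)
             if any(model.atoms[i].is_heavy for i in model.residue_atoms[k])]
    res_b = [k for k in model.chain_residues(chain_b)
             if any(model.atoms[i].is_heavy for i in model.residue_atoms[k])]
    W = np.zeros((len(res_a), len(res_b)))
    D = np.full((len(res_a), len(res_b)), np.inf)
    for p, ka in enumerate(res_a):
        for q, kb in enumerate(res_b):
            for i in model.residue_atoms[ka]:
                ai = model.atoms[i]
                if not ai.is_heavy:
                    continue
                for j in model.residue_atoms[kb]:
                    aj = model.atoms[j]
                    if not aj.is_heavy:
                        continue
                    r = math.dist((ai.x, ai.y, ai.z), (aj.x, aj.y, aj.z))
                    W[p, q] += 0.5 - 0.5 * math.tanh((r - a) / b)
                    D[p, q] = min(D[p, q], r)
    return res_a, res_b, W, D


def bh_oracle(p) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up: q_i = min over ranks >= i of p*m/rank."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
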
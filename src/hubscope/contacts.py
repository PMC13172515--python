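"""Soft contact counting between two chains of a protein complex.

The chain-pair contact count is the double sum of a smooth sigmoidal
switching function over inter-chain atom pairs,

    AB_cnts = sum_{i in A} sum_{j in B} sigma(|r_ij|),
    sigma(r) = 0.5 - 0.5 * tanh((r - a) / b),

where ``a`` is the distance cutoff and ``b`` the smoothing width.  The
switch is 0.5 exactly at the cutoff, approaches 1 well below it and 0 well
above, so AB_cnts counts interactions below the cutoff without a hard step.
Defaults follow the two analysis regimes: all-atom structures use
``a = 5 A, b = 0.5 A`` over heavy atoms; coarse-grained structures use
``a = 10 A, b = 1.0 A`` over one designated bead per residue ("BB").

Residue-level maps aggregate atom-pair weights by residue pair, which makes
the per-pair weight the summed soft count of atom contacts (an optional
binarized view thresholds at 0.5 for plotting).  Coordinates are taken as
given: no periodic-boundary minimum-image convention is applied, so inputs
must be whole (unwrapped) molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structio import StructureModel, Trajectory

__all__ = [
    "ContactParams",
    "ContactMap",
    "DistanceMap",
    "ContactSeries",
    "contact_weight",
    "residue_contact_map",
    "chain_contact_total",
    "min_distance_map",
    "contact_timeseries",
]


@dataclass(frozen=True)
class ContactParams:
    """Parameters of the sigmoidal contact switch.

    ``a``: cutoff distance (A); ``b``: smoothing width (A);
    ``atom_rule``: ``heavy_atoms`` (all non-hydrogen atoms) or
    ``named_bead`` (one designated bead per residue, ``bead_name``).
    """

    a: float = 5.0
    b: float = 0.5
    mode: str = "atomistic"
    atom_rule: str = "heavy_atoms"
    bead_name: str = "BB"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("cutoff a and smoothing b must be positive")
        if self.atom_rule not in ("heavy_atoms", "named_bead"):
            raise ValueError(f"unknown atom_rule {self.atom_rule!r}")

    @classmethod
    def atomistic(cls) -> "ContactParams":
        return cls(a=5.0, b=0.5, mode="atomistic", atom_rule="heavy_atoms")

    @classmethod
    def coarse_grained(cls, bead_name: str = "BB") -> "ContactParams":
        return cls(a=10.0, b=1.0, mode="coarse_grained",
                   atom_rule="named_bead", bead_name=bead_name)


@dataclass
class ContactMap:
    """Residue-pair soft contact weights between two chains."""

    chain_a: str
    chain_b: str
    residues_a: list[tuple[str, int, str]]
    residues_b: list[tuple[str, int, str]]
    weights: np.ndarray
    params: ContactParams

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.residues_a), len(self.residues_b)):
            raise ValueError("weights shape does not match residue lists")
        if (self.weights < 0).any():
            raise ValueError("contact weights must be non-negative")

    @property
    def ab_total(self) -> float:
        """AB_cnts: the chain-pair soft contact count."""
        return float(self.weights.sum())

    def binarized(self, threshold: float = 0.5) -> np.ndarray:
        """Boolean contact view: residue pairs with weight >= threshold."""
        return self.weights >= threshold


@dataclass
class DistanceMap:
    """Minimum heavy-atom distance (A) per residue pair between two chains."""

    chain_a: str
    chain_b: str
    residues_a: list[tuple[str, int, str]]
    residues_b: list[tuple[str, int, str]]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.residues_a), len(self.residues_b)):
            raise ValueError("distance matrix shape does not match residue lists")
        if not np.isfinite(self.d).all() or (self.d < 0).any():
            raise ValueError("distances must be finite and non-negative")


@dataclass
class ContactSeries:
    """Per-frame AB_cnts along a trajectory."""

    frame_labels: list
    ab_totals: np.ndarray
    per_frame_weights: list[np.ndarray] | None = None


def contact_weight(r, params: ContactParams):
    """Sigmoidal switch sigma(r) = 0.5 - 0.5*tanh((r - a)/b); vectorized."""
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("distances must be non-negative")
    out = 0.5 - 0.5 * np.tanh((r - params.a) / params.b)
    return float(out) if out.ndim == 0 else out


def _selected_atoms(model: StructureModel, chain_id: str, params: ContactParams):
    """Coordinates of the selected atoms of a chain plus residue grouping.

    Returns (coords (n,3), group_starts, residue_keys) where atoms of
    residue k occupy the contiguous slice starting at group_starts[k].
    """
    residues = model.chain_residues(chain_id)
    coords: list[list[float]] = []
    starts: list[int] = []
    kept_residues: list[tuple[str, int, str]] = []
    for key in residues:
        atom_idx = model.residue_atoms[key]
        if params.atom_rule == "heavy_atoms":
            sel = [i for i in atom_idx if model.atoms[i].is_heavy]
        else:
            sel = [i for i in atom_idx if model.atoms[i].atom_name == params.bead_name]
        if not sel:
            continue
        starts.append(len(coords))
        kept_residues.append(key)
        for i in sel:
            a = model.atoms[i]
            coords.append([a.x, a.y, a.z])
    if not coords:
        raise ValueError(f"chain {chain_id!r} has no atoms selected by rule "
                         f"{params.atom_rule!r}")
    return np.array(coords, dtype=float), np.array(starts, dtype=int), kept_residues


def _block_reduce(atom_matrix: np.ndarray, starts_a: np.ndarray,
                  starts_b: np.ndarray, op: str) -> np.ndarray:
    """Reduce an atom x atom matrix to residue x residue blocks."""
    ufunc = np.add if op == "sum" else np.minimum
    rows = ufunc.reduceat(atom_matrix, starts_a, axis=0)
    return ufunc.reduceat(rows, starts_b, axis=1)


def residue_contact_map(model: StructureModel, chain_a: str, chain_b: str,
                        params: ContactParams | None = None) -> ContactMap:
    """Residue-pair soft contact map between two chains.

    Each entry w[p][q] sums sigma(|r_ij|) over all selected atom pairs
    (i in residue p of chain_a, j in residue q of chain_b); AB_cnts is the
    grand total.
    """
    params = params or ContactParams.atomistic()
    xyz_a, starts_a, res_a = _selected_atoms(model, chain_a, params)
    xyz_b, starts_b, res_b = _selected_atoms(model, chain_b, params)
    sigma = contact_weight(cdist(xyz_a, xyz_b), params)
    weights = _block_reduce(sigma, starts_a, starts_b, "sum")
    return ContactMap(chain_a, chain_b, res_a, res_b, weights, params)


def chain_contact_total(cmap: ContactMap) -> float:
    """AB_cnts of a contact map (sum of all residue-pair weights)."""
    return cmap.ab_total


def min_distance_map(model: StructureModel, chain_a: str, chain_b: str,
                     params: ContactParams | None = None) -> DistanceMap:
    """Minimum selected-atom Euclidean distance per residue pair."""
    params = params or ContactParams.atomistic()
    xyz_a, starts_a, res_a = _selected_atoms(model, chain_a, params)
    xyz_b, starts_b, res_b = _selected_atoms(model, chain_b, params)
    dist = cdist(xyz_a, xyz_b)
    d = _block_reduce(dist, starts_a, starts_b, "min")
    return DistanceMap(chain_a, chain_b, res_a, res_b, d)


def contact_timeseries(traj: Trajectory, chain_a: str, chain_b: str,
                       params: ContactParams | None = None,
                       keep_weights: bool = False) -> ContactSeries:
    """Apply the contact statistic independently to every trajectory frame."""
    params = params or ContactParams.atomistic()
    totals = []
    weights = [] if keep_weights else None
    for coords in traj.frames:
        frame_model = traj.topology.with_coordinates(coords)
        cmap = residue_contact_map(frame_model, chain_a, chain_b, params)
        totals.append(cmap.ab_total)
        if keep_weights:
            weights.append(cmap.weights)
    labels = (list(traj.frame_times) if traj.frame_times is not None
              else list(range(traj.n_frames)))
    return ContactSeries(labels, np.array(totals), weights)
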
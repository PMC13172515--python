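"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its configuration and seed, and ships
a :class:`TruthRecord` holding the planted parameters so recovery tests
never re-derive them.  Toy structures use single-heavy-atom residues by
default, which keeps brute-force contact oracles trivial; two-atom
residues are available for map-summation tests.

The binding-mode generator builds a miniature ATG8-like chain whose two
LDS pockets are short runs of closely spaced residues, and plants either a
LIR core peptide or an alternative whole chain against both pockets; the
planted occupant's pocket weight exceeds any other candidate's by far more
than the classifier's thresholds, so geometric classification recovers the
planted labels exactly under default rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lirlds import Candidate, LDSDefinition
from .structio import (AtomRecord, Ensemble, LFQMatrix, StructureModel,
                       Trajectory)

__all__ = [
    "TruthRecord",
    "gen_two_chain_complex",
    "gen_mode_ensemble",
    "gen_decay_trajectory",
    "gen_lfq",
    "gen_cell_table",
    "gen_facs_table",
    "largest_remainder_counts",
]


@dataclass
class TruthRecord:
    """Planted ground truth serialized alongside every generated dataset."""

    generator: str
    seed: int
    params: dict
    labels: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"generator": self.generator, "seed": self.seed,
                           "params": self.params, "labels": self.labels},
                          indent=2, default=str)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _atom(chain: str, resi: int, x: float, y: float, z: float,
          resname: str = "ALA", name: str = "CA") -> AtomRecord:
    return AtomRecord(chain, resi, resname, name, "C", float(x), float(y), float(z))


# ---------------------------------------------------------------------------
# Structures


def gen_two_chain_complex(n_res_a: int, n_res_b: int,
                          planted_pairs: list[tuple[int, int, float]],
                          seed: int, spacing: float = 25.0,
                          atoms_per_residue: int = 1,
                          ) -> tuple[StructureModel, TruthRecord]:
    """Two-chain complex with planted residue-pair distances.

    Chain A residues sit on a line with ``spacing`` A separation; chain B
    residues are parked far away (> 3x the default cutoff from chain A)
    except planted ones, each placed exactly its requested distance from
    its chain-A partner.  Requesting two distances for the same chain-B
    residue, or a distance >= spacing/2 (which would drag the residue into
    range of a neighbouring pair), is an infeasible placement.
    """
    seen_b: set[int] = set()
    for res_a, res_b, d in planted_pairs:
        if d <= 0:
            raise ValueError("planted distances must be positive")
        if d >= spacing / 2:
            raise ValueError(
                f"infeasible placement: distance {d} >= spacing/2 ({spacing / 2})")
        if not (1 <= res_a <= n_res_a and 1 <= res_b <= n_res_b):
            raise ValueError(f"planted pair ({res_a},{res_b}) outside chain ranges")
        if res_b in seen_b:
            raise ValueError(f"infeasible placement: chain-B residue {res_b} "
                             "planted twice")
        seen_b.add(res_b)
    planted_by_b = {rb: (ra, d) for ra, rb, d in planted_pairs}
    atoms: list[AtomRecord] = []
    for i in range(1, n_res_a + 1):
        atoms.append(_atom("A", i, spacing * i, 0.0, 0.0))
        if atoms_per_residue > 1:
            atoms.append(_atom("A", i, spacing * i, 0.0, 1.0, name="CB"))
    far_y = 500.0
    for j in range(1, n_res_b + 1):
        if j in planted_by_b:
            ra, d = planted_by_b[j]
            x, y = spacing * ra, d
        else:
            x, y = spacing * j, far_y
        atoms.append(_atom("B", j, x, y, 0.0))
        if atoms_per_residue > 1:
            atoms.append(_atom("B", j, x, y, 1.0, name="CB"))
    truth = TruthRecord(
        "two_chain_complex", seed,
        {"n_res_a": n_res_a, "n_res_b": n_res_b, "spacing": spacing,
         "atoms_per_residue": atoms_per_residue,
         "planted_pairs": [list(p) for p in planted_pairs]})
    return StructureModel(atoms), truth


# geometry of the miniature LDS: two pockets of three clustered residues
_HP1_RESIDUES = [49, 50, 51]
_HP2_RESIDUES = [64, 65, 66]
_HP1_POS = [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (3.0, 0.0, 0.0)]
_HP2_POS = [(8.0, 0.0, 0.0), (9.5, 0.0, 0.0), (11.0, 0.0, 0.0)]
#: anchor positions spanning both pockets at ~3 A; a planted occupant's
#: four anchor residues accrue a pocket weight of several sigma units each
_ANCHOR_POS = [(0.5, 3.0, 0.0), (3.5, 3.0, 0.0), (7.0, 3.0, 0.0), (10.0, 3.0, 0.0)]

#: LIR1 core span on the receptor chain (matches the scanned motif span)
LIR1_SPAN = (186, 189)


def _receptor_chain(planted: bool) -> list[AtomRecord]:
    """Receptor chain R, residues 180..195 with the LIR1 core at 186-189."""
    atoms = []
    core_names = {186: "TRP", 187: "GLU", 188: "GLU", 189: "LEU"}
    far_y = 250.0
    k = 0
    for resi in range(180, 196):
        if planted and resi in core_names:
            x, y, z = _ANCHOR_POS[resi - 186]
        elif planted:
            x, y, z = 4.0 * (resi - 180), 12.0, 0.0
        else:
            x, y, z = 4.0 * (resi - 180), far_y, 0.0
        atoms.append(_atom("R", resi, x, y, z,
                           resname=core_names.get(resi, "ALA")))
        k += 1
    return atoms


def _alt_chain(planted: bool) -> list[AtomRecord]:
    """Alternative whole-chain candidate (ATG7-like), chain T, residues 1-6."""
    atoms = []
    far_y = 350.0
    for resi in range(1, 7):
        if planted and resi <= 4:
            x, y, z = _ANCHOR_POS[resi - 1]
        elif planted:
            x, y, z = 12.0 + 4.0 * resi, 12.0, 0.0
        else:
            x, y, z = 4.0 * resi, far_y, 0.0
        atoms.append(_atom("T", resi, x, y, z))
    return atoms


def _lds_chain() -> list[AtomRecord]:
    atoms = []
    for resi, pos in zip(_HP1_RESIDUES, _HP1_POS):
        atoms.append(_atom("G", resi, *pos))
    for resi, pos in zip(_HP2_RESIDUES, _HP2_POS):
        atoms.append(_atom("G", resi, *pos))
    # scaffold residues away from the docking face
    for k, resi in enumerate([1, 2, 3, 4]):
        atoms.append(_atom("G", resi, 3.0 * k, -25.0, 0.0))
    return atoms


def largest_remainder_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integer counts per label summing to n, by largest-remainder rounding."""
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {total}, expected 1")
    quotas = {k: n * f for k, f in fractions.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    shortfall = n - sum(counts.values())
    by_remainder = sorted(fractions, key=lambda k: -(quotas[k] - counts[k]))
    for k in by_remainder[:shortfall]:
        counts[k] += 1
    return counts


def gen_mode_ensemble(n_models: int, mode_fractions: dict[str, float], seed: int,
                      shuffle: bool = True,
                      ) -> tuple[Ensemble, LDSDefinition, list[Candidate], TruthRecord]:
    """Ensemble of toy complexes with planted binding-mode fractions.

    ``mode_fractions`` maps mode labels — "LIR1-LDS", "ATG7-LDS",
    "unoccupied" — to fractions summing to 1; per-mode model counts follow
    largest-remainder rounding so fraction recovery is exact.  In each
    model exactly the planted candidate's anchor residues sit within
    contact range of both pockets; every other candidate is parked far
    beyond three cutoffs.
    """
    allowed = {"LIR1-LDS", "ATG7-LDS", "unoccupied"}
    unknown = set(mode_fractions) - allowed
    if unknown:
        raise ValueError(f"unknown mode labels {sorted(unknown)}; "
                         f"allowed: {sorted(allowed)}")
    counts = largest_remainder_counts(n_models, mode_fractions)
    labels = [mode for mode, c in counts.items() for _ in range(c)]
    rng = np.random.default_rng(seed)
    if shuffle:
        labels = [labels[i] for i in rng.permutation(n_models)]
    models = []
    for k, mode in enumerate(labels, start=1):
        atoms = (_lds_chain()
                 + _receptor_chain(planted=(mode == "LIR1-LDS"))
                 + _alt_chain(planted=(mode == "ATG7-LDS")))
        models.append(StructureModel(atoms, model_id=k))
    lds = LDSDefinition("GABARAPL2", "G", list(_HP1_RESIDUES), list(_HP2_RESIDUES))
    candidates = [
        Candidate("LIR1", "R", LIR1_SPAN[0], LIR1_SPAN[1], flank=2),
        Candidate("ATG7", "T"),
    ]
    truth = TruthRecord("mode_ensemble", seed,
                        {"n_models": n_models, "mode_fractions": mode_fractions,
                         "counts": counts, "shuffle": shuffle},
                        labels={str(k + 1): lab for k, lab in enumerate(labels)})
    return Ensemble(models), lds, candidates, truth


def gen_decay_trajectory(base_complex: StructureModel, n_frames: int,
                         displacement_per_frame: float, seed: int,
                         move_chain: str = "B",
                         ) -> tuple[Trajectory, TruthRecord]:
    """Trajectory in which one chain rigidly drifts away along +y.

    Frame k translates ``move_chain`` by k * displacement; frame 0 is the
    base complex, so an interface built with the moving chain on the +y
    side dissolves monotonically.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if displacement_per_frame <= 0:
        raise ValueError("displacement_per_frame must be positive")
    base = base_complex.coordinates()
    moving = np.array([a.chain_id == move_chain for a in base_complex.atoms])
    if not moving.any():
        raise KeyError(f"chain {move_chain!r} not in base complex")
    frames = []
    for k in range(n_frames):
        coords = base.copy()
        coords[moving, 1] += k * displacement_per_frame
        frames.append(coords)
    truth = TruthRecord("decay_trajectory", seed,
                        {"n_frames": n_frames, "move_chain": move_chain,
                         "displacement_per_frame": displacement_per_frame})
    return Trajectory(base_complex, frames, frame_times=list(range(n_frames))), truth


# ---------------------------------------------------------------------------
# Quantitative tables


def gen_lfq(n_proteins: int, n_spiked: int, log2_effect: float,
            within_sd: float, missing_rate: float, n_per_group: int,
            seed: int, baseline_mean: float = 25.0, baseline_sd: float = 2.0,
            ) -> tuple[LFQMatrix, TruthRecord]:
    """Spiked LFQ matrix: bait vs control with known enriched proteins.

    Per-protein baseline log2 abundance ~ Normal(25, 2); the first
    ``n_spiked`` proteins are shifted by ``log2_effect`` in the bait
    group; replicate noise ~ Normal(0, within_sd^2); entries are removed
    completely at random at ``missing_rate``.  The emitted matrix is on
    the linear scale with missing as NaN.
    """
    if n_spiked > n_proteins:
        raise ValueError("n_spiked cannot exceed n_proteins")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    base = rng.normal(baseline_mean, baseline_sd, size=n_proteins)
    n_samples = 2 * n_per_group
    log2 = base[:, None] + rng.normal(0.0, within_sd, size=(n_proteins, n_samples))
    log2[:n_spiked, :n_per_group] += log2_effect
    if missing_rate > 0:
        mask = rng.random(size=log2.shape) < missing_rate
        log2[mask] = np.nan
    protein_ids = [f"P{i + 1:05d}" for i in range(n_proteins)]
    sample_ids = ([f"bait_{r + 1}" for r in range(n_per_group)]
                  + [f"control_{r + 1}" for r in range(n_per_group)])
    intensities = pd.DataFrame(2.0 ** log2, index=pd.Index(protein_ids, name="protein_id"),
                               columns=sample_ids)
    samples = pd.DataFrame({
        "condition": ["bait"] * n_per_group + ["control"] * n_per_group,
        "replicate": list(range(1, n_per_group + 1)) * 2,
    }, index=pd.Index(sample_ids, name="sample_id"))
    truth = TruthRecord("lfq", seed,
                        {"n_proteins": n_proteins, "n_spiked": n_spiked,
                         "log2_effect": log2_effect, "within_sd": within_sd,
                         "missing_rate": missing_rate, "n_per_group": n_per_group,
                         "baseline_mean": baseline_mean, "baseline_sd": baseline_sd},
                        labels={"spiked": protein_ids[:n_spiked]})
    return LFQMatrix(intensities, samples), truth


def gen_cell_table(design: list[dict], seed: int, wells_per_group: int = 2,
                   ) -> tuple[pd.DataFrame, TruthRecord]:
    """Single-cell feature table with planted group effects.

    ``design`` is a list of group dicts: condition, genotype, optional
    replicate (default 1), n_cells, and ``features`` mapping feature name
    to (mean, sd).  Features are normal draws truncated at zero; wells are
    assigned round-robin within each group.
    """
    if not design:
        raise ValueError("design must contain at least one group")
    rng = np.random.default_rng(seed)
    rows = []
    cell_counter = 0
    for group in design:
        n = int(group["n_cells"])
        if n < 1:
            raise ValueError("each group needs n_cells >= 1")
        cond, geno = group["condition"], group["genotype"]
        replicate = group.get("replicate", 1)
        features = group["features"]
        draws = {}
        for name, (mean, sd) in features.items():
            if sd < 0:
                raise ValueError(f"negative sd for feature {name!r}")
            draws[name] = np.clip(rng.normal(mean, sd, size=n), 0.0, None)
        for i in range(n):
            cell_counter += 1
            rows.append({
                "cell_id": f"c{cell_counter:06d}",
                "well_id": f"{cond}_{geno}_r{replicate}_w{i % wells_per_group + 1}",
                "replicate": replicate,
                "condition": cond,
                "genotype": geno,
                **{name: draws[name][i] for name in features},
            })
    truth = TruthRecord("cell_table", seed,
                        {"design": design, "wells_per_group": wells_per_group})
    return pd.DataFrame(rows), truth


def gen_facs_table(lines: list[str], conditions: list[str], base_ratio: float,
                   effects: dict[str, float], noise_sd: float, seed: int,
                   n_replicates: int = 3, base_gfp: float = 1.0e4,
                   untreated_label: str = "UT",
                   ) -> tuple[pd.DataFrame, TruthRecord]:
    """Per-sample FACS MFI table for a tandem mCherry/GFP reporter.

    Each sample's reporter ratio is base_ratio * effect[condition] *
    (1 + noise); GFP MFI fluctuates around ``base_gfp`` and mCherry is the
    ratio times GFP.  Every line carries the untreated condition.
    """
    if untreated_label not in conditions:
        raise ValueError(f"conditions must include the untreated label "
                         f"{untreated_label!r}")
    missing = [c for c in conditions if c not in effects]
    if missing:
        raise ValueError(f"effects missing for conditions: {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    for line in lines:
        for cond in conditions:
            for rep in range(1, n_replicates + 1):
                noise = np.clip(rng.normal(0.0, noise_sd), -0.9, None)
                ratio = base_ratio * effects[cond] * (1.0 + noise)
                gfp = base_gfp * (1.0 + np.clip(rng.normal(0.0, 0.05), -0.5, None))
                rows.append({"cell_line": line, "condition": cond,
                             "replicate": rep, "mfi_mcherry": ratio * gfp,
                             "mfi_gfp": gfp})
    truth = TruthRecord("facs", seed,
                        {"lines": lines, "conditions": conditions,
                         "base_ratio": base_ratio, "effects": effects,
                         "noise_sd": noise_sd, "n_replicates": n_replicates})
    return pd.DataFrame(rows), truth
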
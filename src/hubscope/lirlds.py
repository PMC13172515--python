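"""LIR motif scanning and geometric LDS binding-mode classification.

Autophagy receptors bind ATG8-family proteins (LC3s/GABARAPs) through a
4-residue LIR core, [W/F/Y]-x-x-[L/I/V], which docks into the two
hydrophobic pockets (HP1, HP2) of the ATG8 LIR-docking site (LDS).  Given
a complex model, the classifier asks which candidate region — a LIR motif
of a partner chain, or a whole partner chain — actually occupies the LDS,
by measuring soft contact weight (module :mod:`hubscope.contacts`) between
each candidate's atoms and the two pocket residue sets.

A candidate is an eligible occupant when its total pocket weight reaches
``min_weight`` and each pocket individually reaches ``min_pocket_weight``
(a genuine LIR engagement buries residues in both pockets).  The occupant
is the eligible candidate with the largest total; if the runner-up is
within ``margin`` (relative), the call is flagged ambiguous and the tie is
broken toward the lowest motif start.  Models with no eligible candidate
are "unoccupied".  Pocket residue sets are configuration: defaults shipped
for GABARAPL2 and LC3B are curated from conserved HP1/HP2 annotations.

Over a model ensemble, per-mode calls aggregate into occupancy counts and
percentages (e.g. the fraction of models with the LIR1-LDS binding mode).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .contacts import ContactParams, contact_weight
from .structio import Ensemble, SequenceRecord, StructureModel

__all__ = [
    "LIRMotif",
    "LDSDefinition",
    "Candidate",
    "ClassificationRules",
    "BindingModeCall",
    "OccupancySummary",
    "scan_lir",
    "pocket_contact_weights",
    "classify_binding_mode",
    "ensemble_occupancy",
    "DEFAULT_LDS_POCKETS",
]

#: Curated HP1/HP2 pocket residues for common ATG8s (UniProt numbering).
#: These are configuration defaults, overridable per analysis.
DEFAULT_LDS_POCKETS: dict[str, dict[str, list[int]]] = {
    "GABARAPL2": {"hp1": [21, 49, 51, 62], "hp2": [50, 64, 77, 79]},
    "LC3B": {"hp1": [23, 52, 54, 66], "hp2": [53, 67, 70, 82]},
}

_LIR_CORE = re.compile(r"(?=([WFY]..[LIV]))")


@dataclass(frozen=True)
class LIRMotif:
    """A 4-residue LIR core hit, 1-based inclusive span."""

    record_id: str
    start: int
    end: int
    core: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != 3 or len(self.core) != 4:
            raise ValueError("LIR core spans exactly 4 residues")
        if self.core[0] not in "WFY" or self.core[3] not in "LIV":
            raise ValueError(f"{self.core!r} is not a [WFY]xx[LIV] core")


@dataclass
class LDSDefinition:
    """LDS pocket residue sets of an ATG8 chain (source numbering)."""

    atg8_id: str
    chain_id: str
    hp1_residues: list[int]
    hp2_residues: list[int]

    def __post_init__(self) -> None:
        if not self.hp1_residues or not self.hp2_residues:
            raise ValueError("both pocket residue lists must be non-empty")
        if set(self.hp1_residues) & set(self.hp2_residues):
            raise ValueError("HP1 and HP2 residue sets must be disjoint")

    @classmethod
    def from_defaults(cls, atg8_id: str, chain_id: str) -> "LDSDefinition":
        pockets = DEFAULT_LDS_POCKETS[atg8_id]
        return cls(atg8_id, chain_id, list(pockets["hp1"]), list(pockets["hp2"]))

    @classmethod
    def from_json(cls, path: str | Path) -> "LDSDefinition":
        d = json.loads(Path(path).read_text())
        return cls(d["atg8_id"], d["chain_id"],
                   list(d["hp1_residues"]), list(d["hp2_residues"]))


@dataclass(frozen=True)
class Candidate:
    """A potential LDS occupant: a motif span of a chain, or a whole chain.

    ``start``/``end`` (1-based, inclusive) restrict to a motif whose atoms
    are taken with ``flank`` extra residues on each side; both None means
    the whole chain (e.g. a partner protein like ATG7).
    """

    label: str
    chain_id: str
    start: int | None = None
    end: int | None = None
    flank: int = 2

    @property
    def sort_key(self) -> tuple:
        # motif candidates order by start; whole chains after, by chain id
        return (0, self.start, self.label) if self.start is not None \
            else (1, self.chain_id, self.label)

    @classmethod
    def from_motif(cls, motif: LIRMotif, chain_id: str, flank: int = 2) -> "Candidate":
        return cls(motif.label or motif.core, chain_id, motif.start, motif.end, flank)


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds of the occupancy call (echoed in every summary)."""

    min_weight: float = 1.0
    min_pocket_weight: float = 0.25
    margin: float = 0.10  # relative separation below which a call is ambiguous


@dataclass
class BindingModeCall:
    """Per-model binding-mode decision."""

    model_id: int
    mode_label: str
    occupant: Candidate | None
    pocket_weights: dict[str, tuple[float, float]]
    margin: float
    ambiguous: bool = False


@dataclass
class OccupancySummary:
    """Ensemble-level mode counts and percentages."""

    n_models: int
    counts: dict[str, int]
    percentages: dict[str, float]
    rules: ClassificationRules

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_models:
            raise ValueError("mode counts must sum to the number of models")
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"percentages sum to {total}, expected 100")


def scan_lir(seq: SequenceRecord) -> list[LIRMotif]:
    """All [W/F/Y]-x-x-[L/I/V] windows, overlapping allowed, ascending start."""
    hits = []
    for m in _LIR_CORE.finditer(seq.sequence):
        start = m.start() + 1
        hits.append(LIRMotif(seq.id, start, start + 3, m.group(1)))
    return hits


def _candidate_coords(model: StructureModel, cand: Candidate) -> np.ndarray:
    residues = model.chain_residues(cand.chain_id)
    if cand.start is not None:
        lo, hi = cand.start - cand.flank, cand.end + cand.flank
        residues = [k for k in residues if lo <= k[1] <= hi]
        if not residues:
            raise ValueError(
                f"candidate {cand.label!r}: no residues of chain {cand.chain_id!r} "
                f"in span {lo}-{hi}")
    coords = []
    for key in residues:
        for i in model.residue_atoms[key]:
            a = model.atoms[i]
            if a.is_heavy:
                coords.append([a.x, a.y, a.z])
    if not coords:
        raise ValueError(f"candidate {cand.label!r} has no heavy atoms")
    return np.array(coords, dtype=float)


def _pocket_coords(model: StructureModel, lds: LDSDefinition,
                   residue_indices: list[int], pocket_name: str) -> np.ndarray:
    present = {k[1] for k in model.chain_residues(lds.chain_id)}
    missing = sorted(set(residue_indices) - present)
    if missing:
        raise ValueError(
            f"{pocket_name} residues {missing} absent from chain {lds.chain_id!r}")
    coords = []
    for key in model.chain_residues(lds.chain_id):
        if key[1] in residue_indices:
            for i in model.residue_atoms[key]:
                a = model.atoms[i]
                if a.is_heavy:
                    coords.append([a.x, a.y, a.z])
    return np.array(coords, dtype=float)


def pocket_contact_weights(model: StructureModel, lds: LDSDefinition,
                           candidates: list[Candidate],
                           params: ContactParams | None = None,
                           ) -> dict[str, tuple[float, float]]:
    """Soft contact weight of each candidate against HP1 and HP2.

    Returns ``{candidate label: (hp1_weight, hp2_weight)}`` where each
    weight sums sigma(|r_ij|) over candidate heavy atoms x pocket heavy atoms.
    """
    params = params or ContactParams.atomistic()
    hp1 = _pocket_coords(model, lds, lds.hp1_residues, "HP1")
    hp2 = _pocket_coords(model, lds, lds.hp2_residues, "HP2")
    out: dict[str, tuple[float, float]] = {}
    for cand in candidates:
        xyz = _candidate_coords(model, cand)
        w1 = float(contact_weight(np.linalg.norm(
            xyz[:, None, :] - hp1[None, :, :], axis=-1), params).sum())
        w2 = float(contact_weight(np.linalg.norm(
            xyz[:, None, :] - hp2[None, :, :], axis=-1), params).sum())
        out[cand.label] = (w1, w2)
    return out


def classify_binding_mode(model: StructureModel, lds: LDSDefinition,
                          candidates: list[Candidate],
                          rules: ClassificationRules | None = None,
                          params: ContactParams | None = None) -> BindingModeCall:
    """Decide which candidate occupies the LDS in one model."""
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    rules = rules or ClassificationRules()
    weights = pocket_contact_weights(model, lds, candidates, params)
    totals = {c.label: sum(weights[c.label]) for c in candidates}
    eligible = [
        c for c in candidates
        if totals[c.label] >= rules.min_weight
        and min(weights[c.label]) >= rules.min_pocket_weight
    ]
    if not eligible:
        return BindingModeCall(model.model_id, "unoccupied", None, weights,
                               margin=0.0)
    # deterministic under candidate-list reordering: sort by weight, then key
    ranked = sorted(eligible, key=lambda c: (-totals[c.label], c.sort_key))
    top = ranked[0]
    margin = totals[top.label] - (totals[ranked[1].label] if len(ranked) > 1 else 0.0)
    ambiguous = (
        len(ranked) > 1
        and totals[top.label] - totals[ranked[1].label]
        < rules.margin * totals[top.label]
    )
    label = "ambiguous" if ambiguous else f"{top.label}-LDS"
    return BindingModeCall(model.model_id, label, top, weights, margin,
                           ambiguous=ambiguous)


def ensemble_occupancy(ensemble: Ensemble, lds: LDSDefinition,
                       candidates: list[Candidate],
                       rules: ClassificationRules | None = None,
                       params: ContactParams | None = None,
                       ) -> tuple[OccupancySummary, list[BindingModeCall]]:
    """Classify every model independently and tally mode occupancy."""
    rules = rules or ClassificationRules()
    calls = [classify_binding_mode(m, lds, candidates, rules, params)
             for m in ensemble]
    counts: dict[str, int] = {}
    for call in calls:
        counts[call.mode_label] = counts.get(call.mode_label, 0) + 1
    n = len(calls)
    percentages = {k: 100.0 * v / n for k, v in counts.items()}
    # keep the percentage identity exact under floating summation
    drift = 100.0 - sum(percentages.values())
    if percentages and abs(drift) > 0:
        first = next(iter(percentages))
        percentages[first] += drift
    return OccupancySummary(n, counts, percentages, rules), calls
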
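"""Readers and writers for the pipeline's external formats.

Structures arrive as PDB files (single- or multi-model), sequences as
FASTA, quantitative data as delimited tables with a header row.  Everything
is parsed into plain dataclass containers (:class:`StructureModel`,
:class:`Ensemble`, :class:`Trajectory`, :class:`SequenceRecord`,
:class:`LFQMatrix`) that downstream modules consume.

The PDB reader is a deliberate fixed-column implementation of the v3.3
coordinate records: the analysis cites residues by their author numbering,
so residue indices and insertion codes are preserved verbatim, alternate
locations are resolved to the highest-occupancy conformer (ties keep the
first encountered), and malformed coordinate fields fail loudly with the
offending line number.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence as TypingSequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Ensemble",
    "Trajectory",
    "SequenceRecord",
    "LFQMatrix",
    "PDBFormatError",
    "read_structure",
    "write_structure",
    "read_ensemble",
    "write_ensemble",
    "read_trajectory",
    "read_fasta",
    "read_table",
    "read_lfq",
]

#: Elements that do not count as heavy atoms.
_HYDROGEN_ELEMENTS = {"H", "D"}

#: 20 standard residues plus X for unknowns.
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class PDBFormatError(ValueError):
    """Raised when a PDB file violates the fixed-column coordinate format."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record with author numbering preserved verbatim."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    insertion_code: str = ""
    is_hetatm: bool = False

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_ELEMENTS

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain_id, residue_index, insertion_code) — the residue identity."""
        return (self.chain_id, self.residue_index, self.insertion_code)


class StructureModel:
    """A single structural model: atoms grouped into chains and residues.

    Residues within a chain keep file order; atom order is file order.
    """

    def __init__(self, atoms: TypingSequence[AtomRecord], model_id: int = 1):
        if not atoms:
            raise ValueError("StructureModel requires at least one atom")
        self.model_id = int(model_id)
        self.atoms: list[AtomRecord] = list(atoms)
        # chain -> ordered residue keys; residue key -> atom indices
        self.chains: dict[str, list[tuple[str, int, str]]] = {}
        self.residue_atoms: dict[tuple[str, int, str], list[int]] = {}
        for i, atom in enumerate(self.atoms):
            key = atom.residue_key
            if key not in self.residue_atoms:
                self.residue_atoms[key] = []
                self.chains.setdefault(atom.chain_id, []).append(key)
            self.residue_atoms[key].append(i)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in atom (file) order."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def chain_residues(self, chain_id: str) -> list[tuple[str, int, str]]:
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not present (have {sorted(self.chains)})")
        return list(self.chains[chain_id])

    def with_coordinates(self, coords: np.ndarray) -> "StructureModel":
        """Copy of this model with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coordinates of shape {(self.n_atoms, 3)}, got {coords.shape}")
        atoms = [
            AtomRecord(a.chain_id, a.residue_index, a.residue_name, a.atom_name,
                       a.element, float(x), float(y), float(z), a.insertion_code, a.is_hetatm)
            for a, (x, y, z) in zip(self.atoms, coords)
        ]
        return StructureModel(atoms, model_id=self.model_id)


@dataclass
class Ensemble:
    """Ordered set of models; input order is rank order."""

    models: list[StructureModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("Ensemble must contain at least one model")
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("Ensemble model_ids must be unique")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


@dataclass
class Trajectory:
    """Frame sequence over a fixed topology (atom order of the topology)."""

    topology: StructureModel
    frames: list[np.ndarray]
    frame_times: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("Trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            fr = np.asarray(fr, dtype=float)
            if fr.shape != (n, 3):
                raise ValueError(
                    f"frame {k} has {fr.shape[0] if fr.ndim == 2 else 'malformed'} atoms, "
                    f"topology has {n}")
            self.frames[k] = fr

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with 1-based positions."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id!r} contains illegal characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LFQMatrix:
    """Protein x sample label-free intensities (linear scale) with annotations.

    ``intensities``: DataFrame indexed by protein_id, columns sample_ids.
    ``samples``: DataFrame indexed by sample_id with columns condition, replicate.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [s for s in self.intensities.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing annotation rows: {missing}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be >= 0 or missing")

    def condition_samples(self, condition: str) -> list[str]:
        hits = self.samples.index[self.samples["condition"] == condition]
        if len(hits) == 0:
            raise KeyError(f"no samples with condition {condition!r}")
        return [s for s in self.intensities.columns if s in set(hits)]


# ---------------------------------------------------------------------------
# PDB reading / writing


def _parse_pdb_atom_line(line: str, lineno: int) -> tuple[AtomRecord, str, float]:
    """Parse one ATOM/HETATM line; returns (record, altloc, occupancy)."""
    try:
        atom_name = line[12:16].strip()
        altloc = line[16:17].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip() or " "
        residue_index = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
    except ValueError as exc:
        raise PDBFormatError(f"line {lineno}: unparseable ATOM/HETATM field ({exc})") from exc
    if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
        raise PDBFormatError(f"line {lineno}: non-finite coordinate")
    element = line[76:78].strip()
    if not element:
        # fall back on the atom-name convention: first alphabetic character
        element = next((c for c in atom_name if c.isalpha()), "C")
    rec = AtomRecord(
        chain_id=chain_id,
        residue_index=residue_index,
        residue_name=residue_name,
        atom_name=atom_name,
        element=element,
        x=x, y=y, z=z,
        insertion_code=icode,
        is_hetatm=line.startswith("HETATM"),
    )
    return rec, altloc, occupancy


def _resolve_altlocs(parsed: list[tuple[AtomRecord, str, float]]) -> list[AtomRecord]:
    """Keep one conformer per (residue key, atom name): highest occupancy,
    ties resolved to the first encountered."""
    best: dict[tuple, tuple[int, AtomRecord, float]] = {}
    order: list[tuple] = []
    for pos, (rec, altloc, occ) in enumerate(parsed):
        if not altloc:
            key = ("noalt", pos)
            best[key] = (pos, rec, occ)
            order.append(key)
            continue
        key = (rec.residue_key, rec.atom_name)
        if key not in best:
            best[key] = (pos, rec, occ)
            order.append(key)
        elif occ > best[key][2]:
            best[key] = (best[key][0], rec, occ)
    return [best[k][1] for k in order]


def _read_pdb_models(text: str, include_hetatm: bool) -> list[list[AtomRecord]]:
    """Split PDB text into per-model atom lists (file order preserved)."""
    models: list[list[tuple[AtomRecord, str, float]]] = []
    current: list[tuple[AtomRecord, str, float]] = []
    in_model_block = False
    saw_model_kw = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        tag = line[:6].strip()
        if tag == "MODEL":
            saw_model_kw = True
            in_model_block = True
            current = []
        elif tag == "ENDMDL":
            in_model_block = False
            models.append(current)
            current = []
        elif tag in ("ATOM", "HETATM"):
            rec, altloc, occ = _parse_pdb_atom_line(line, lineno)
            if rec.is_hetatm and not include_hetatm:
                continue
            if rec.residue_name == "HOH" and not include_hetatm:
                continue
            current.append((rec, altloc, occ))
    if current or not saw_model_kw:
        if current:
            models.append(current)
    return [_resolve_altlocs(m) for m in models if m]


def read_structure(path: str | Path, strict: bool = True,
                   include_hetatm: bool = False) -> StructureModel:
    """Read a single-model PDB file into a :class:`StructureModel`.

    Hydrogens are retained but flagged ``is_heavy=False``.  HETATM records
    (and waters) are skipped unless ``include_hetatm``.  A malformed
    coordinate field raises :class:`PDBFormatError` naming the line.
    """
    text = Path(path).read_text()
    models = _read_pdb_models(text, include_hetatm)
    if not models:
        raise PDBFormatError(f"{path}: no ATOM records found")
    if len(models) > 1 and strict:
        raise PDBFormatError(
            f"{path}: contains {len(models)} models; use read_ensemble")
    return StructureModel(models[0], model_id=1)


def write_structure(model: StructureModel, path: str | Path | None = None) -> str:
    """Serialize a model to PDB text (and optionally a file)."""
    buf = io.StringIO()
    _write_model_records(buf, model)
    buf.write("END\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def _write_model_records(buf: io.TextIOBase, model: StructureModel) -> None:
    serial = 0
    for a in model.atoms:
        serial += 1
        tag = "HETATM" if a.is_hetatm else "ATOM  "
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        buf.write(
            f"{tag}{serial:5d} {name:<4.4s} {a.residue_name:<3.3s} {a.chain_id:1.1s}"
            f"{a.residue_index:4d}{a.insertion_code or ' ':1.1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2.2s}\n")


def read_ensemble(path: str | Path, strict: bool = True,
                  include_hetatm: bool = False) -> Ensemble:
    """Read a model ensemble.

    ``path`` is either a multi-model PDB (MODEL/ENDMDL blocks; a single
    block-less file yields an ensemble of one) or a directory of
    single-model PDB files taken in lexicographic (rank) order.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(q for q in p.iterdir() if q.suffix.lower() in (".pdb", ".ent"))
        if not files:
            raise FileNotFoundError(f"{path}: no PDB files in directory")
        models = []
        for k, f in enumerate(files, start=1):
            m = read_structure(f, strict=strict, include_hetatm=include_hetatm)
            models.append(StructureModel(m.atoms, model_id=k))
    else:
        atom_sets = _read_pdb_models(p.read_text(), include_hetatm)
        if not atom_sets:
            raise PDBFormatError(f"{path}: no models found")
        models = [StructureModel(atoms, model_id=k)
                  for k, atoms in enumerate(atom_sets, start=1)]
    counts = {m.n_atoms for m in models}
    if len(counts) > 1:
        msg = f"{path}: inconsistent atom counts across models: {sorted(counts)}"
        if strict:
            raise PDBFormatError(msg)
        warnings.warn(msg)
    return Ensemble(models)


def write_ensemble(ensemble: Ensemble, path: str | Path | None = None) -> str:
    """Serialize an ensemble as a multi-model PDB."""
    buf = io.StringIO()
    for m in ensemble.models:
        buf.write(f"MODEL {m.model_id:8d}\n")
        _write_model_records(buf, m)
        buf.write("ENDMDL\n")
    buf.write("END\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_trajectory(topology_path: str | Path, frames_path: str | Path,
                    frame_times: list[float] | None = None) -> Trajectory:
    """Read a trajectory from a topology PDB plus frames.

    Frames are either a multi-model PDB or plain whitespace-delimited XYZ
    blocks (``n_atoms * 3`` floats per frame, any line layout).  A frame
    whose atom count disagrees with the topology raises an error naming
    the frame index.
    """
    topo = read_structure(topology_path, strict=True)
    text = Path(frames_path).read_text()
    if "ATOM" in text or "MODEL" in text:
        ens = read_ensemble(frames_path, strict=False)
        frames = []
        for k, m in enumerate(ens.models):
            if m.n_atoms != topo.n_atoms:
                raise ValueError(
                    f"frame {k} has {m.n_atoms} atoms, topology has {topo.n_atoms}")
            frames.append(m.coordinates())
    else:
        values = np.array(text.split(), dtype=float)
        per_frame = topo.n_atoms * 3
        if values.size == 0 or values.size % per_frame:
            k = values.size // per_frame
            raise ValueError(
                f"frame {k} is truncated: {values.size - k * per_frame} leftover "
                f"values for a {topo.n_atoms}-atom topology")
        frames = list(values.reshape(-1, topo.n_atoms, 3))
    return Trajectory(topo, frames, frame_times)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records; lowercase letters are uppercased, whitespace stripped."""
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise ValueError(f"{path}: sequence data before the first FASTA header")
    records = []
    with io.StringIO(text) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = "".join(str(rec.seq).split()).upper()
            records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# Delimited tables

_SCHEMAS: dict[str, dict] = {
    "cells": {
        "required": ["cell_id", "well_id", "replicate", "condition", "genotype"],
        "group_cols": ["well_id", "replicate", "condition", "genotype"],
    },
    "facs": {
        "required": ["cell_line", "condition", "replicate", "mfi_mcherry", "mfi_gfp"],
        "numeric": ["mfi_mcherry", "mfi_gfp"],
    },
    "lfq_samples": {
        "required": ["sample_id", "condition", "replicate"],
    },
}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate column names: {dupes}")
    return pd.read_csv(path, sep=sep, na_values=["", "NaN", "NA", "nan"],
                       keep_default_na=True)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")


def read_table(path: str | Path, schema_name: str,
               samples_path: str | Path | None = None):
    """Read a delimited table under a named schema.

    ``schema_name`` is one of ``lfq`` (requires ``samples_path`` sidecar),
    ``cells`` or ``facs``.  Empty strings and "NaN" are parsed as missing,
    never coerced to zero.
    """
    if schema_name == "lfq":
        if samples_path is None:
            raise ValueError("lfq schema requires a sample-annotation sidecar (samples_path)")
        return read_lfq(path, samples_path)
    if schema_name not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; expected lfq, cells or facs")
    df = _read_delimited(path)
    schema = _SCHEMAS[schema_name]
    _require_columns(df, schema["required"], path)
    for col in schema.get("numeric", []):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if schema_name == "cells":
        feature_cols = [c for c in df.columns if c not in schema["required"]]
        for col in feature_cols:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def read_lfq(matrix_path: str | Path, samples_path: str | Path) -> LFQMatrix:
    """Read an LFQ intensity matrix (rows proteins) plus its sample sheet."""
    mat = _read_delimited(matrix_path)
    _require_columns(mat, ["protein_id"], matrix_path)
    mat = mat.set_index("protein_id")
    mat = mat.apply(pd.to_numeric, errors="raise")
    samples = _read_delimited(samples_path)
    _require_columns(samples, _SCHEMAS["lfq_samples"]["required"], samples_path)
    samples = samples.set_index("sample_id")
    return LFQMatrix(intensities=mat, samples=samples)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
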
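"""Conformer container and PDB ensemble I/O.

A :class:`Conformer` is one energy-minimized structure: flat arrays of atom
records plus provenance (which variant ensemble it came from, at which MSA
depth, seed and frame). Ensembles are read and written as standard
fixed-width PDB files, one model per file or multi-model, via biotite.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Provenance",
    "Conformer",
    "write_pdb",
    "read_pdb",
    "read_pdb_ensemble",
    "PDBParseError",
]

#: filename convention for ensemble members: <variant>_d<depth>_s<seed>_f<frame>.pdb
_FNAME_RE = re.compile(r"^(?P<variant>.+)_d(?P<depth>\d+)_s(?P<seed>\d+)_f(?P<frame>\d+)\.pdb$")


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed; message names file (and line)."""


@dataclass(frozen=True)
class Provenance:
    """Bookkeeping key identifying one conformer within the study design."""

    variant: str
    depth: int
    seed: int
    frame: int

    def key(self) -> tuple:
        return (self.variant, self.depth, self.seed, self.frame)


@dataclass
class Conformer:
    """One structure: parallel atom-record arrays in Å.

    Invariants: at least one atom, finite coordinates, and unique
    (chain_id, res_id, atom_name) triples.
    """

    atom_name: np.ndarray  # (n,) str
    res_name: np.ndarray   # (n,) str
    res_id: np.ndarray     # (n,) int, author numbering
    chain_id: np.ndarray   # (n,) str
    coord: np.ndarray      # (n, 3) float, Å
    provenance: Provenance | None = None
    energy: float | None = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.ndim != 2 or self.coord.shape[1] != 3 or len(self.coord) == 0:
            raise ValueError("Conformer requires an (n, 3) coordinate array with n >= 1")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("Conformer coordinates must be finite")
        keys = list(zip(self.chain_id, self.res_id, self.atom_name))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain_id, res_id, atom_name) atom records")

    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    def atom_coord(self, res_id: int, atom_name: str) -> np.ndarray:
        """Coordinate of a single named atom; raises KeyError naming the atom."""
        mask = (self.res_id == res_id) & (self.atom_name == atom_name)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"atom {atom_name!r} of residue {res_id} not present")
        return self.coord[idx[0]]

    def has_atom(self, res_id: int, atom_name: str) -> bool:
        return bool(np.any((self.res_id == res_id) & (self.atom_name == atom_name)))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        """Rigid-body copy (used by invariance tests and alignment helpers)."""
        return replace(self, coord=self.coord @ np.asarray(rotation).T + translation)


def _to_atom_array(conf: Conformer) -> struc.AtomArray:
    n = conf.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = conf.coord.astype(np.float32)
    arr.atom_name = conf.atom_name
    arr.res_name = conf.res_name
    arr.res_id = conf.res_id
    arr.chain_id = conf.chain_id
    arr.element = np.array([_element_of(a) for a in conf.atom_name])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def _element_of(atom_name: str) -> str:
    """Element symbol per PDB atom-name conventions (leading letter, digits stripped)."""
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def write_pdb(conf: Conformer, path: Path | str) -> None:
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(conf))
    pdb.write(str(path))


def _find_bad_atom_line(path: Path) -> int | None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    return lineno
    return None


def read_pdb(path: Path | str, provenance: Provenance | None = None) -> list[Conformer]:
    """Parse one PDB file into one Conformer per MODEL block.

    Single-model files yield a one-element list. Alternate locations keep
    altloc A only. Malformed ATOM records raise :class:`PDBParseError`
    naming the file and line.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(altloc="first")
    except Exception as exc:
        lineno = _find_bad_atom_line(path)
        loc = f"{path}" + (f", line {lineno}" if lineno else "")
        raise PDBParseError(f"cannot parse PDB file {loc}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if stack.array_length() == 0:
        raise PDBParseError(f"PDB file {path} contains no atoms")
    out = []
    for model in stack:
        prov = provenance
        out.append(
            Conformer(
                atom_name=np.asarray(model.atom_name),
                res_name=np.asarray(model.res_name),
                res_id=np.asarray(model.res_id, dtype=int),
                chain_id=np.asarray(model.chain_id),
                coord=np.asarray(model.coord, dtype=float),
                provenance=prov,
            )
        )
    if len(out) > 1 and provenance is not None:
        # frame index distinguishes models within a multi-model file
        out = [replace(c, provenance=replace(provenance, frame=provenance.frame + i))
               for i, c in enumerate(out)]
    return out


def provenance_from_filename(path: Path | str) -> Provenance | None:
    m = _FNAME_RE.match(Path(path).name)
    if not m:
        return None
    return Provenance(
        variant=m.group("variant"),
        depth=int(m.group("depth")),
        seed=int(m.group("seed")),
        frame=int(m.group("frame")),
    )


def read_pdb_ensemble(source: Path | str | Sequence[Path | str]) -> list[Conformer]:
    """Read an ensemble from a directory (with optional ``manifest.json``) or
    an explicit list of PDB paths.

    Provenance is taken from the manifest when present, otherwise derived
    from the ``<variant>_d<depth>_s<seed>_f<frame>.pdb`` filename convention.
    """
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        source = Path(source)
        manifest = source / "manifest.json"
        if manifest.exists():
            entries = json.loads(manifest.read_text())["files"]
            paths = [source / e["path"] for e in entries]
            provs = [Provenance(e["variant"], e["depth"], e["seed"], e["frame"])
                     for e in entries]
        else:
            paths = sorted(source.glob("*.pdb"))
            provs = [provenance_from_filename(p) for p in paths]
    else:
        paths = [Path(p) for p in (source if not isinstance(source, (str, Path)) else [source])]
        provs = [provenance_from_filename(p) for p in paths]
    if not paths:
        raise FileNotFoundError(f"no PDB files found in {source}")
    conformers: list[Conformer] = []
    for path, prov in zip(paths, provs):
        conformers.extend(read_pdb(path, provenance=prov))
    return conformers
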
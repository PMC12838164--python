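"""Interpretable geometric/energetic descriptors and the N x 5 feature matrix.

Five descriptors per conformer: catalytic lysine-glutamate salt-bridge
distance, activation-loop end-to-end length, backbone dihedral of the DFG
aspartate, mass-weighted radius of gyration, and the ingested potential
energy. Together they form the common feature currency of every downstream
stage (embedding, landscape, classification, attribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .structures import Conformer

__all__ = [
    "MotifSpec",
    "FeatureMatrix",
    "Scaler",
    "DESCRIPTOR_COLUMNS",
    "META_COLUMNS",
    "salt_bridge_distance",
    "activation_loop_length",
    "dfg_dihedral",
    "radius_of_gyration",
    "dihedral_angle",
    "build_feature_matrix",
    "standardize",
]

DESCRIPTOR_COLUMNS = ["salt_bridge_dist", "aloop_length", "dfg_dihedral", "rg", "energy"]
META_COLUMNS = ["variant", "label", "depth", "seed", "frame"]

# monoisotopic-ish atomic masses (Da); unknown elements fall back to carbon
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


@dataclass(frozen=True)
class MotifSpec:
    """Residue bookkeeping for the kinase activation motifs.

    Author (PDB) numbering throughout. Defaults follow the FGFR2 kinase
    domain: K659-E565 salt bridge, activation loop 610-650. The DFG residue
    number has no universal default for real structures and must be given;
    the synthetic topology supplies its own.
    """

    lys_residue: int = 659
    glu_residue: int = 565
    loop_start: int = 610
    loop_end: int = 650  # inclusive
    dfg_residue: int | None = None
    dihedral_choice: Literal["phi", "psi"] = "psi"

    def __post_init__(self) -> None:
        if self.loop_start > self.loop_end:
            raise ValueError("loop_start must be <= loop_end")
        if self.dihedral_choice not in ("phi", "psi"):
            raise ValueError("dihedral_choice must be 'phi' or 'psi'")


def salt_bridge_distance(conf: Conformer, motif: MotifSpec) -> float:
    """Minimum distance (Å) from the lysine NZ to the glutamate carboxylate
    oxygens (OE1/OE2) — the nearest-oxygen convention."""
    nz = conf.atom_coord(motif.lys_residue, "NZ")
    dists = []
    for oxy in ("OE1", "OE2"):
        if conf.has_atom(motif.glu_residue, oxy):
            dists.append(float(np.linalg.norm(nz - conf.atom_coord(motif.glu_residue, oxy))))
    if not dists:
        raise KeyError(
            f"residue {motif.glu_residue} carries neither OE1 nor OE2"
        )
    return min(dists)


def activation_loop_length(conf: Conformer, motif: MotifSpec) -> float:
    """End-to-end length (Å): Cα(loop_start) to Cα(loop_end)."""
    a = conf.atom_coord(motif.loop_start, "CA")
    b = conf.atom_coord(motif.loop_end, "CA")
    return float(np.linalg.norm(a - b))


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion (degrees in (-180, 180]) by the atan2 convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def dfg_dihedral(conf: Conformer, motif: MotifSpec) -> float:
    """Backbone dihedral of the DFG aspartate: ψ(i) = N,CA,C of i plus N of
    i+1 (default), or φ(i) = C of i-1 plus N,CA,C of i."""
    if motif.dfg_residue is None:
        raise ValueError("MotifSpec.dfg_residue is required for dihedral extraction")
    i = motif.dfg_residue
    if motif.dihedral_choice == "psi":
        quad = [(i, "N"), (i, "CA"), (i, "C"), (i + 1, "N")]
    else:
        quad = [(i - 1, "C"), (i, "N"), (i, "CA"), (i, "C")]
    pts = [conf.atom_coord(r, a) for r, a in quad]
    return dihedral_angle(*pts)


def _atom_masses(atom_names: np.ndarray) -> np.ndarray:
    def mass(name: str) -> float:
        stripped = name.strip().lstrip("0123456789")
        return _MASSES.get(stripped[:1].upper(), _MASSES["C"])

    return np.array([mass(a) for a in atom_names])


def radius_of_gyration(conf: Conformer) -> float:
    """Mass-weighted Rg (Å) over all atoms, element inferred from atom name."""
    m = _atom_masses(conf.atom_name)
    com = np.average(conf.coord, axis=0, weights=m)
    sq = np.sum((conf.coord - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=m)))


@dataclass
class Scaler:
    """Per-column standardization parameters (population sd convention)."""

    mean: np.ndarray
    sd: np.ndarray
    columns: list[str]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.columns):
            raise ValueError(f"expected {len(self.columns)} feature columns, got {X.shape[1]}")
        return (X - self.mean) / self.sd

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd + self.mean


@dataclass
class FeatureMatrix:
    """N rows x 5 descriptor columns plus study-design metadata.

    ``data`` holds META_COLUMNS + DESCRIPTOR_COLUMNS; ``scaler`` is set once
    the matrix has been standardized (training statistics only).
    """

    data: pd.DataFrame
    scaler: Scaler | None = None

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS + DESCRIPTOR_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature matrix missing columns: {missing}")
        if self.data[DESCRIPTOR_COLUMNS].isna().any().any():
            raise ValueError("descriptor columns contain missing values")
        labels = set(self.data["label"].unique())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {labels}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[DESCRIPTOR_COLUMNS].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["label"].to_numpy(dtype=int)

    @property
    def variants(self) -> np.ndarray:
        return self.data["variant"].to_numpy()

    def segment_ids(self) -> np.ndarray:
        """One id per (variant, depth, seed) block — the pseudo-trajectory segments."""
        key = self.data[["variant", "depth", "seed"]].astype(str).agg("|".join, axis=1)
        return key.to_numpy()


def build_feature_matrix(
    conformers: Sequence[Conformer],
    motif: MotifSpec,
    energy_table: pd.DataFrame,
    labels: Mapping[str, int],
) -> FeatureMatrix:
    """Extract all five descriptors and join per-conformer energies.

    ``energy_table`` needs columns variant, depth, seed, frame,
    energy_kj_mol; every conformer must join to exactly one energy row.
    ``labels`` maps variant id -> binary class (0 = WT/benign,
    1 = pathogenic). Rows are sorted by (variant, depth, seed, frame).
    """
    if len(conformers) == 0:
        raise ValueError("no conformers given")
    energy = energy_table.set_index(["variant", "depth", "seed", "frame"])
    if energy.index.has_duplicates:
        dupes = energy.index[energy.index.duplicated()].tolist()[:5]
        raise ValueError(f"duplicate energy rows for keys {dupes}")
    rows = []
    missing = []
    for conf in conformers:
        prov = conf.provenance
        if prov is None:
            raise ValueError("conformer lacks provenance; cannot join energies")
        key = prov.key()
        if conf.energy is not None:
            e = conf.energy
        elif key in energy.index:
            e = float(energy.loc[key, "energy_kj_mol"])
        else:
            missing.append(key)
            continue
        if prov.variant not in labels:
            raise ValueError(f"no class label for variant {prov.variant!r}")
        rows.append(
            {
                "variant": prov.variant,
                "label": int(labels[prov.variant]),
                "depth": prov.depth,
                "seed": prov.seed,
                "frame": prov.frame,
                "salt_bridge_dist": salt_bridge_distance(conf, motif),
                "aloop_length": activation_loop_length(conf, motif),
                "dfg_dihedral": dfg_dihedral(conf, motif),
                "rg": radius_of_gyration(conf),
                "energy": e,
            }
        )
    if missing:
        raise ValueError(f"conformers without matching energy rows: {missing[:5]}"
                         + (f" (+{len(missing) - 5} more)" if len(missing) > 5 else ""))
    df = pd.DataFrame(rows).sort_values(["variant", "depth", "seed", "frame"]).reset_index(drop=True)
    return FeatureMatrix(df)


def standardize(fm: FeatureMatrix) -> tuple[FeatureMatrix, Scaler]:
    """Zero-mean unit-sd columns (population convention); returns the scaler
    so held-out data can be transformed with training statistics only."""
    X = fm.X
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero = [c for c, s in zip(DESCRIPTOR_COLUMNS, sd) if s == 0.0]
    if zero:
        raise ValueError(f"zero-variance descriptor column(s): {zero}")
    scaler = Scaler(mean=mean, sd=sd, columns=list(DESCRIPTOR_COLUMNS))
    data = fm.data.copy()
    data[DESCRIPTOR_COLUMNS] = scaler.transform(X)
    return FeatureMatrix(data, scaler=scaler), scaler
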
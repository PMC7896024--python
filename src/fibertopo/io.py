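"""Readers, writers and provenance for fiber conformations.

Conformations are exchanged as TSV (exact round-trip) or PDB with one
pseudo-atom per base pair (PDB fixed-point precision, 1e-3 nm).  In PDB
files each nucleosome-plus-linker repeat is a chain and the B-factor
column carries the nucleosome index; linker base pairs carry the index
of the upstream core.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.Atom import Atom
from Bio.PDB.Chain import Chain
from Bio.PDB.Model import Model
from Bio.PDB.PDBIO import PDBIO
from Bio.PDB.Residue import Residue
from Bio.PDB.Structure import Structure

from .geometry import FiberConformation

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


class ConformationParseError(ValueError):
    """A conformation file could not be parsed."""


def conformation_table(fiber: FiberConformation) -> pd.DataFrame:
    """bp-resolution coordinate table: bp_index, x/y/z (nm), core index
    (-1 for free linker bp)."""
    pts = fiber.bp_origins()
    lab = fiber.core_index_of_bp()
    return pd.DataFrame({
        "bp_index": np.arange(len(pts)),
        "x_nm": pts[:, 0],
        "y_nm": pts[:, 1],
        "z_nm": pts[:, 2],
        "core_index": lab,
    })


def write_tsv(fiber: FiberConformation, path) -> None:
    conformation_table(fiber).to_csv(path, sep="\t", index=False,
                                     float_format="%.9f")


def read_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    """(coordinates (N, 3) nm, per-bp core index) from a conformation TSV."""
    try:
        df = pd.read_csv(path, sep="\t")
        pts = df[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
        lab = df["core_index"].to_numpy(int)
    except (KeyError, ValueError) as exc:
        raise ConformationParseError(f"malformed conformation TSV: {exc}") from exc
    return pts, lab


def write_pdb(fiber: FiberConformation, path) -> None:
    """One CA pseudo-atom per bp origin; coordinates in Angstrom (nm*10);
    chain per repeat unit, B-factor = nucleosome index."""
    pts = fiber.bp_origins()
    lab = fiber.core_index_of_bp()
    # repeat unit of bp i: its core, or the upstream core for linker bp
    unit = np.maximum.accumulate(np.where(lab >= 0, lab, -1))
    unit[unit < 0] = 0
    structure = Structure("fiber")
    model = Model(0)
    structure.add(model)
    chains = {}
    serial = 1
    for i, p in enumerate(pts):
        cid = _CHAIN_IDS[int(unit[i]) % len(_CHAIN_IDS)]
        if cid not in chains:
            chains[cid] = Chain(cid)
            model.add(chains[cid])
        res = Residue((" ", i + 1, " "), "DBP", "")
        atom = Atom("CA", np.asarray(p, float) * 10.0, float(max(lab[i], 0)),
                    1.0, " ", "CA", serial, element="C")
        serial += 1
        res.add(atom)
        chains[cid].add(res)
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(path))


def read_pdb(path) -> tuple[np.ndarray, np.ndarray]:
    """(coordinates (N, 3) nm, per-bp nucleosome index from B-factor)."""
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("fiber", str(path))
        pts, lab = [], []
        for atom in structure.get_atoms():
            pts.append(atom.get_coord() / 10.0)
            lab.append(int(round(atom.get_bfactor())))
        if not pts:
            raise ConformationParseError(f"no atoms found in {path}")
    except ConformationParseError:
        raise
    except Exception as exc:
        raise ConformationParseError(f"malformed PDB file {path}: {exc}") from exc
    return np.asarray(pts, float), np.asarray(lab, int)


def write_provenance(path, seed: int | None, params: dict) -> None:
    """JSON sidecar making a run reproducible: seed, parameters and the
    package version."""
    from . import __version__
    doc = {
        "package": "fibertopo",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "params": params,
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in obj.__dict__.items() if not k.startswith("_")}
    return str(obj)
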
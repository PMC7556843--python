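"""File I/O: PDB-style bead structures, 3-column SAXS curves, run configs.

Structures are stored as one ATOM record per bead (coordinates in Angstrom
on disk, nm in memory): chain ID encodes the domain, residue number the
global residue index, the atom name the bead class, and the B-factor column
the backbone flag (1 backbone, 0 other).  Multi-frame trajectories use
standard MODEL/ENDMDL blocks.  Parsing is delegated to biotite after a
light pre-validation pass that reports malformed records with their line
number.

SAXS curves are whitespace-separated ``q I(q) [sigma]`` columns with ``#``
comment headers; q in nm^-1 unless read with ``angstrom=True``.
"""

from __future__ import annotations

import hashlib
import io as _io
import string
from pathlib import Path

import numpy as np
import yaml
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .chain import BeadChain
from .saxs import SaxsCurve

__all__ = [
    "read_structure",
    "write_structure",
    "read_saxs",
    "write_saxs",
    "load_config",
    "config_hash",
]

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _chain_to_atoms(chain: BeadChain) -> AtomArray:
    n = chain.n_beads
    atoms = AtomArray(n)
    atoms.coord = chain.positions * 10.0  # nm -> Angstrom
    atoms.res_id = chain.residue_index
    atoms.res_name = np.full(n, "CGB")
    atoms.atom_name = np.array([str(c)[:4] for c in chain.bead_class])
    atoms.chain_id = np.array([_CHAIN_IDS[d % len(_CHAIN_IDS)]
                               for d in chain.domain_id])
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.add_annotation("b_factor", dtype=float)
    atoms.b_factor = chain.backbone.astype(float)
    return atoms


def _atoms_to_chain(atoms: AtomArray) -> BeadChain:
    chain_ids = atoms.chain_id
    domain = np.array([_CHAIN_IDS.index(c) for c in chain_ids])
    backbone = (atoms.b_factor > 0.5 if "b_factor" in atoms.get_annotation_categories()
                else np.ones(len(atoms), dtype=bool))
    return BeadChain(atoms.coord / 10.0, atoms.res_id, domain,
                     atoms.atom_name.astype(object), backbone)


def _prevalidate_pdb(text: str, path: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise ValueError(f"{path}:{lineno}: truncated ATOM record "
                             "(missing coordinates)")
        for start, stop, name in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtext = line[start:stop].strip()
            if not fieldtext:
                raise ValueError(f"{path}:{lineno}: missing {name} coordinate")
            try:
                float(fieldtext)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unparsable {name} coordinate "
                    f"{fieldtext!r}") from None


def write_structure(frames, path, header_lines=()) -> None:
    """Write one BeadChain or a sequence of frames as (multi-model) PDB."""
    if isinstance(frames, BeadChain):
        frames = [frames]
    arrays = [_chain_to_atoms(f) for f in frames]
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        stack = AtomArrayStack(len(arrays), arrays[0].array_length())
        for cat in arrays[0].get_annotation_categories():
            stack.set_annotation(cat, arrays[0].get_annotation(cat))
        stack.coord = np.stack([a.coord for a in arrays])
        pdb.set_structure(stack)
    text = "".join(f"REMARK   1 {line}\n" for line in header_lines)
    text += "\n".join(pdb.lines) + "\n"
    Path(path).write_text(text)


def read_structure(path) -> list[BeadChain]:
    """Read a (multi-model) PDB-style bead file; returns one chain per model."""
    text = Path(path).read_text()
    _prevalidate_pdb(text, str(path))
    pdb = PDBFile.read(_io.StringIO(text))
    chains = []
    for model in range(1, pdb.get_model_count() + 1):
        atoms = pdb.get_structure(model=model, extra_fields=["b_factor"])
        chains.append(_atoms_to_chain(atoms))
    return chains


def write_saxs(curve: SaxsCurve, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# q[nm^-1]  I(q)  sigma\n")
        for k in range(len(curve)):
            cols = [f"{curve.q[k]:.8e}", f"{curve.intensity[k]:.8e}"]
            if curve.sigma is not None:
                cols.append(f"{curve.sigma[k]:.8e}")
            fh.write("  ".join(cols) + "\n")


def read_saxs(path, angstrom: bool = False) -> SaxsCurve:
    """Read a whitespace-separated (q, I, [sigma]) file.

    ``angstrom=True`` converts q from A^-1 to nm^-1 on input.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            if "," in body:
                raise ValueError(
                    f"{path}:{lineno}: comma found; expected whitespace-"
                    "separated columns (q I [sigma])")
            parts = body.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, "
                                 f"got {len(parts)}")
            rows.append([float(p) for p in parts])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows])
    q = arr[:, 0] * (10.0 if angstrom else 1.0)
    sigma = arr[:, 2] if ncol == 3 else None
    return SaxsCurve(q, arr[:, 1], sigma)


def load_config(path, schema: dict | None = None) -> dict:
    """Load a YAML run config; unknown keys are errors (fail-fast).

    ``schema`` maps allowed keys to nested schemas (dict) or None (leaf).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if schema is not None:
        _check_keys(cfg, schema, prefix="")
    return cfg


def _check_keys(cfg: dict, schema: dict, prefix: str) -> None:
    for key, value in cfg.items():
        if key not in schema:
            raise KeyError(f"unknown config key {prefix + key!r}")
        sub = schema[key]
        if isinstance(sub, dict) and isinstance(value, dict):
            _check_keys(value, sub, prefix=f"{prefix}{key}.")


def config_hash(obj) -> str:
    """Short stable hash of a configuration object, for output headers."""
    text = yaml.safe_dump(obj, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
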
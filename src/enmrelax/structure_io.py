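"""Reading and writing Cα coordinates from PDB files.

Only the alpha-carbon trace is consumed: each residue of a protein becomes
one point particle of the elastic network.  Residues are identified by
(chain id, residue number, insertion code); the residue *name* is carried
along but deliberately excluded from identity so that e.g. a nucleotide
analog or point mutant can still be paired with its counterpart structure.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb

__all__ = [
    "Structure",
    "ResiduePairing",
    "read_calpha_structure",
    "match_common_residues",
    "write_calpha_pdb",
    "write_calpha_trajectory_pdb",
]

ResidueId = tuple[str, int, str]


@dataclass
class Structure:
    """An ordered Cα trace: one residue, one coordinate (Å)."""

    chain_ids: list[str]
    residue_numbers: list[int]
    insertion_codes: list[str]
    residue_names: list[str]
    coords: np.ndarray  # (N, 3) float, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.chain_ids)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} residues"
            )
        if len(set(self.residue_ids())) != n:
            raise ValueError("duplicate residue identifiers in structure")

    def __len__(self) -> int:
        return len(self.chain_ids)

    def residue_ids(self) -> list[ResidueId]:
        """(chain_id, residue_number, insertion_code) triples, in order."""
        return list(
            zip(self.chain_ids, self.residue_numbers, self.insertion_codes)
        )

    def subset(self, indices: Sequence[int]) -> "Structure":
        idx = list(indices)
        return Structure(
            chain_ids=[self.chain_ids[i] for i in idx],
            residue_numbers=[self.residue_numbers[i] for i in idx],
            insertion_codes=[self.insertion_codes[i] for i in idx],
            residue_names=[self.residue_names[i] for i in idx],
            coords=self.coords[idx],
        )


@dataclass
class ResiduePairing:
    """Index pairs of residues present in two structures of the same protein."""

    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def indices_a(self) -> list[int]:
        return [p[0] for p in self.pairs]

    @property
    def indices_b(self) -> list[int]:
        return [p[1] for p in self.pairs]


def _altloc_rank(altloc: str) -> int:
    # blank (unique conformation) first, then the conventional 'A'
    if altloc in ("", " ", "."):
        return 0
    if altloc == "A":
        return 1
    return 2


def read_calpha_structure(pdb_text: str, model_index: int | None = None) -> Structure:
    """Extract the Cα trace from PDB-format text.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file (ATOM records per wwPDB v3.3 columns).
    model_index:
        1-based model to use for multi-model files.  Required if the file
        holds more than one model; single-model files need no value.

    Only ATOM records named ``CA`` (carbon, i.e. not calcium HETATMs) are
    kept.  Where a residue's Cα carries alternate locations, altloc blank or
    'A' is preferred, ties broken by highest occupancy, then file order.
    """
    pdb_file = _pdb.PDBFile.read(io.StringIO(pdb_text))
    n_models = pdb_file.get_model_count()
    if n_models > 1 and model_index is None:
        raise ValueError(
            f"file contains {n_models} models; a model_index is required"
        )
    model = 1 if model_index is None else int(model_index)
    atoms = pdb_file.get_structure(
        model=model, altloc="all", extra_fields=["occupancy"]
    )
    mask = (
        (atoms.atom_name == "CA")
        & ~atoms.hetero
        & np.isin(atoms.element, ["C", ""])
    )
    ca = atoms[mask]
    if ca.array_length() == 0:
        raise ValueError("no Cα ATOM records found in PDB text")

    chosen: dict[ResidueId, tuple[int, float, int]] = {}
    order: list[ResidueId] = []
    for i in range(ca.array_length()):
        rid: ResidueId = (
            str(ca.chain_id[i]),
            int(ca.res_id[i]),
            str(ca.ins_code[i]).strip(),
        )
        rank = _altloc_rank(str(ca.altloc_id[i]).strip())
        occ = float(ca.occupancy[i])
        if rid not in chosen:
            chosen[rid] = (rank, occ, i)
            order.append(rid)
        else:
            prev_rank, prev_occ, _ = chosen[rid]
            if (rank, -occ) < (prev_rank, -prev_occ):
                chosen[rid] = (rank, occ, i)

    rows = [chosen[rid][2] for rid in order]
    return Structure(
        chain_ids=[str(ca.chain_id[i]) for i in rows],
        residue_numbers=[int(ca.res_id[i]) for i in rows],
        insertion_codes=[str(ca.ins_code[i]).strip() for i in rows],
        residue_names=[str(ca.res_name[i]) for i in rows],
        coords=ca.coord[rows].astype(float),
    )


def match_common_residues(
    a: Structure,
    b: Structure,
    chain_map: Mapping[str, str] | None = None,
) -> ResiduePairing:
    """Pair the residues whose identifiers occur in both structures.

    Identity is (chain, residue number, insertion code); the residue name is
    ignored.  ``chain_map`` translates chain ids of ``a`` into those of ``b``
    (identity by default — crystal forms of the same protein often, but not
    always, share chain naming).  Order follows ``a``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot pair with an empty structure")
    chain_map = dict(chain_map or {})
    b_lookup = {rid: j for j, rid in enumerate(b.residue_ids())}
    pairs: list[tuple[int, int]] = []
    for i, (chain, resnum, icode) in enumerate(a.residue_ids()):
        key = (chain_map.get(chain, chain), resnum, icode)
        j = b_lookup.get(key)
        if j is not None:
            pairs.append((i, j))
    if not pairs:
        raise ValueError("no common residues between the two structures")
    return ResiduePairing(pairs=pairs)


def _as_atom_array(structure: Structure, coords: np.ndarray) -> struc.AtomArray:
    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array(structure.chain_ids, dtype="U4")
    arr.res_id = np.array(structure.residue_numbers, dtype=int)
    arr.ins_code = np.array(structure.insertion_codes, dtype="U1")
    arr.res_name = np.array(structure.residue_names, dtype="U5")
    arr.atom_name = np.full(n, "CA", dtype="U6")
    arr.element = np.full(n, "C", dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_calpha_pdb(structure: Structure, coords: np.ndarray | None = None) -> str:
    """Render a Structure (or alternate coordinates for it) as CA-only PDB text."""
    coords = structure.coords if coords is None else np.asarray(coords, float)
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(_as_atom_array(structure, coords))
    out = io.StringIO()
    pdb_file.write(out)
    return out.getvalue()


def write_calpha_trajectory_pdb(
    structure: Structure, frames: np.ndarray
) -> str:
    """Render trajectory frames as a multi-model CA-only PDB."""
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 3 or frames.shape[1:] != (len(structure), 3):
        raise ValueError("frames must have shape (n_frames, n_residues, 3)")
    stack = struc.AtomArrayStack(frames.shape[0], len(structure))
    template = _as_atom_array(structure, structure.coords)
    for name in template.get_annotation_categories():
        stack.set_annotation(name, template.get_annotation(name))
    stack.coord = frames
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    out = io.StringIO()
    pdb_file.write(out)
    return out.getvalue()
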
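"""Cα structure models, multi-model PDB I/O, residue reindexing and regions.

Ensembles of predicted conformations are reduced to their Cα traces on a
shared residue numbering (the reference structure's numbering); all
flexibility metrics operate on that representation.  The four flexible
regions of the enzyme — the pigment-binding loop, the two oligomerization
interfaces and helix α10 — are named residue ranges in reference numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)


class StructureError(ValueError):
    """Raised for malformed models, missing atoms or invalid regions."""


@dataclass(frozen=True)
class StructureModel:
    """One conformation: ordered Cα coordinates indexed by residue id."""

    residue_ids: np.ndarray
    coords: np.ndarray
    rank: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        rid = np.asarray(self.residue_ids, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        if rid.ndim != 1 or xyz.shape != (rid.size, 3):
            raise StructureError(
                f"need one Cα triple per residue id (got {rid.shape} ids, {xyz.shape} coords)"
            )
        if np.unique(rid).size != rid.size:
            raise StructureError("duplicate residue ids in model")
        if not np.all(np.isfinite(xyz)):
            raise StructureError("coordinates must be finite")
        order = np.argsort(rid)
        object.__setattr__(self, "residue_ids", rid[order])
        object.__setattr__(self, "coords", xyz[order])

    def select(self, residue_ids: Sequence[int]) -> np.ndarray:
        """Coordinates of the given residue ids (all must be present)."""
        wanted = np.asarray(residue_ids, dtype=int)
        pos = np.searchsorted(self.residue_ids, wanted)
        ok = (pos < self.residue_ids.size) & (self.residue_ids[np.minimum(pos, self.residue_ids.size - 1)] == wanted)
        if not np.all(ok):
            missing = wanted[~ok]
            raise StructureError(f"model {self.label!r} lacks residues {missing.tolist()[:5]}")
        return self.coords[pos]


@dataclass(frozen=True)
class Region:
    """A named inclusive residue range in reference numbering."""

    name: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise StructureError(f"region {self.name}: start > stop")

    @property
    def residue_ids(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 1)


@dataclass(frozen=True)
class RegionSet:
    """Non-overlapping named regions."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for r in self.regions:
            ids = set(range(r.start, r.stop + 1))
            if ids & seen:
                raise StructureError(f"region {r.name} overlaps another region")
            seen |= ids

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def all_residue_ids(self) -> np.ndarray:
        return np.concatenate([r.residue_ids for r in self.regions])


#: the four flexible regions, inclusive reference numbering
DEFAULT_REGIONS = RegionSet((
    Region("pchlide_loop", 230, 242),
    Region("interface_I", 256, 263),
    Region("helix_a10", 316, 338),
    Region("interface_II", 367, 375),
))


@dataclass(frozen=True)
class Ensemble:
    """Ordered conformations sharing a residue id set with a reference."""

    members: tuple[StructureModel, ...]
    reference: StructureModel

    def __post_init__(self) -> None:
        if not self.members:
            raise StructureError("ensemble needs at least one member")
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def shared_residue_ids(self) -> np.ndarray:
        """Residue ids present in the reference and every member; residues
        missing on either side are dropped with a logged count."""
        shared = self.reference.residue_ids
        for m in self.members:
            shared = np.intersect1d(shared, m.residue_ids, assume_unique=True)
        dropped = self.reference.residue_ids.size - shared.size
        if dropped:
            logger.info("dropped %d residues absent from some member", dropped)
        if shared.size == 0:
            raise StructureError("no residues shared between members and reference")
        return shared

    def by_rank(self) -> tuple[StructureModel, ...]:
        return tuple(sorted(self.members, key=lambda m: m.rank))


def reindex(model: StructureModel, mapping: int | Mapping[int, int]) -> StructureModel:
    """Translate residue ids by an integer offset or an explicit bijection.

    Needed when a reference structure numbers residues differently from the
    predictions.  Coordinates are untouched; mapping collisions are an error.
    """
    if isinstance(mapping, int):
        new_ids = model.residue_ids + mapping
    else:
        try:
            new_ids = np.array([mapping[int(r)] for r in model.residue_ids], dtype=int)
        except KeyError as exc:
            raise StructureError(f"mapping lacks residue {exc.args[0]}") from exc
        if np.unique(new_ids).size != new_ids.size:
            raise StructureError("reindex mapping collides (not a bijection)")
    return replace(model, residue_ids=new_ids)


# ---------------------------------------------------------------------------
# PDB I/O (Cα subset; multi-model MODEL/ENDMDL dialect)

def _models_from_atoms(atoms, chain: str | None, label_base: str) -> list[StructureModel]:
    if atoms.array_length() == 0:
        raise StructureError("no atoms in file")
    stack = atoms if isinstance(atoms, struc.AtomArrayStack) else struc.stack([atoms])
    mask = stack.atom_name == "CA"
    if chain is not None:
        if chain not in set(stack.chain_id[mask]):
            raise StructureError(f"chain {chain!r} not found")
        mask &= stack.chain_id == chain
    sub = stack[:, mask]
    if sub.array_length() == 0:
        raise StructureError("no Cα atoms found")
    rid = sub.res_id
    if np.unique(rid).size != rid.size:
        dup = int(rid[np.argmax(np.bincount(rid - rid.min()))])
        raise StructureError(
            f"more than one Cα per residue (e.g. residue {dup}); select a chain"
        )
    out = []
    for i in range(sub.stack_depth()):
        out.append(
            StructureModel(rid, sub.coord[i], rank=i, label=f"{label_base}_{i}")
        )
    return out


def read_models(paths, chain: str | None = None) -> list[StructureModel]:
    """Read Cα models from one multi-model PDB or several single-model files.

    Rank follows file order (model order within a multi-model file); a
    residue without a Cα raises an error naming the residue.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    models: list[StructureModel] = []
    for path in paths:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure()
        for m in _models_from_atoms(atoms, chain, Path(path).stem):
            models.append(replace(m, rank=len(models), label=f"{Path(path).stem}_{len(models)}"))
    if not models:
        raise StructureError("no models read")
    first = models[0].residue_ids
    for m in models[1:]:
        if m.residue_ids.size != first.size or np.any(m.residue_ids != first):
            missing = np.setxor1d(first, m.residue_ids)
            raise StructureError(
                f"model {m.label!r} residue set differs (e.g. residues {missing.tolist()[:5]})"
            )
    return models


def read_reference(path, chain: str | None = None) -> StructureModel:
    """Read the reference structure's Cα trace (first model of the file)."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    return _models_from_atoms(atoms, chain, Path(path).stem)[0]


def write_models(models: Sequence[StructureModel], path) -> None:
    """Write Cα models as a multi-model PDB (MODEL/ENDMDL records)."""
    if not models:
        raise StructureError("no models to write")
    rid = models[0].residue_ids
    n = rid.size
    template = struc.AtomArray(n)
    template.res_id = rid
    template.atom_name = np.full(n, "CA")
    template.res_name = np.full(n, "GLY")
    template.chain_id = np.full(n, "A")
    template.element = np.full(n, "C")
    stack = struc.stack([template] * len(models))
    stack.coord = np.stack([m.coords for m in models])
    pdb = PDBFile()
    pdb.set_structure(stack)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pdb.write(str(path))
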
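"""Molecular geometry containers and extended-XYZ / PDB readers.

The pipeline works on ensembles of conformers of a solute (a rigid
polyanion such as a doubly deprotonated nucleotide) plus ``n`` rigid
water molecules.  Atoms carry a ``fragment_id`` (0 = solute, k >= 1 =
k-th water) and an optional ``site_tag`` naming the chemically relevant
site the atom belongs to (deprotonated amine nitrogen, phosphate
oxygen, ...).

File format: multi-frame extended XYZ.  The comment line of each frame
holds space-separated ``key=value`` pairs; the keys ``label``,
``charge``, ``fragments`` (comma-separated per-atom fragment ids) and
``sites`` (comma-separated per-atom site tags, ``-`` for none) are
interpreted, all other keys are preserved verbatim.  When fragment
metadata is absent, waters are inferred from O-H connectivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

# Recognized hydration-relevant site tags.
PHOSPHATE_O = "PHOSPHATE_O"
AMINE_N10 = "AMINE_N10"
PURINE_O11 = "PURINE_O11"
PURINE_RING_N = "PURINE_RING_N"
RIBOSE_OH = "RIBOSE_OH"
OTHER = "OTHER"

SITE_TAGS = frozenset(
    {PHOSPHATE_O, AMINE_N10, PURINE_O11, PURINE_RING_N, RIBOSE_OH, OTHER}
)

_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe".split()
)

#: Covalent-connectivity distance cutoff used for fragment inference, A.
COVALENT_CUTOFF = 1.7


class StructureError(ValueError):
    """Inconsistent molecular structure (fragments, frames, labels)."""


class ParseError(ValueError):
    """Malformed geometry file."""


@dataclass
class Atom:
    """One atom: element symbol, position (A), fragment id, optional site tag."""

    element: str
    position: np.ndarray
    fragment_id: int = 0
    site_tag: str | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.element not in _ELEMENTS:
            raise StructureError(f"unrecognized element symbol {self.element!r}")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"bad position for {self.element}: {self.position}")
        if self.fragment_id < 0:
            raise StructureError("fragment_id must be >= 0")
        if self.site_tag is not None and self.site_tag not in SITE_TAGS:
            raise StructureError(f"unknown site_tag {self.site_tag!r}")

    @property
    def is_water(self) -> bool:
        return self.fragment_id >= 1

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    def copy(self) -> "Atom":
        return Atom(self.element, self.position.copy(), self.fragment_id, self.site_tag)


@dataclass
class Conformer:
    """A labeled geometry of the solute plus zero or more waters."""

    label: str
    atoms: list[Atom]
    total_charge: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def n_waters(self) -> int:
        return len({a.fragment_id for a in self.atoms if a.fragment_id >= 1})

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def set_positions(self, pos: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=float)
        for a, p in zip(self.atoms, pos):
            a.position = p.copy()

    def solute_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.fragment_id == 0]

    def water_fragment_ids(self) -> list[int]:
        return sorted({a.fragment_id for a in self.atoms if a.fragment_id >= 1})

    def water_atoms(self, fragment_id: int) -> list[Atom]:
        return [a for a in self.atoms if a.fragment_id == fragment_id]

    def atom_indices(self, predicate: Callable[[Atom], bool]) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int
        )

    def validate(self) -> None:
        """Check the water-composition invariant: every water is an O + 2 H."""
        for fid in self.water_fragment_ids():
            frag = self.water_atoms(fid)
            elements = sorted(a.element for a in frag)
            if elements != ["H", "H", "O"]:
                raise StructureError(
                    f"{self.label}: water fragment {fid} has composition "
                    f"{elements}, expected O + 2 H"
                )

    def copy(self, label: str | None = None) -> "Conformer":
        return Conformer(
            label if label is not None else self.label,
            [a.copy() for a in self.atoms],
            self.total_charge,
            dict(self.extra),
        )


@dataclass
class Ensemble:
    """An ordered collection of conformers equilibrated at one temperature."""

    conformers: list[Conformer]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not self.conformers:
            raise StructureError("ensemble must contain at least one conformer")
        if self.temperature <= 0:
            raise StructureError("temperature must be positive")

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i):
        return self.conformers[i]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.conformers]

    def validate(self) -> None:
        labels = self.labels
        if len(set(labels)) != len(labels):
            raise StructureError("duplicate conformer labels in ensemble")
        ref = [(a.element, a.fragment_id) for a in self.conformers[0].solute_atoms()]
        for c in self.conformers:
            c.validate()
            if [(a.element, a.fragment_id) for a in c.solute_atoms()] != ref:
                raise StructureError(
                    f"{c.label}: solute atom count/ordering differs from first frame"
                )


# ---------------------------------------------------------------------------
# fragment inference


def infer_fragments(atoms: Sequence[Atom], cutoff: float = COVALENT_CUTOFF) -> None:
    """Assign fragment ids in place from covalent connectivity.

    Connected components under an interatomic distance ``cutoff``;
    components of composition OH2 become waters numbered by order of
    first appearance in the file, everything else is merged into the
    solute (fragment 0).
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    pos = np.array([a.position for a in atoms])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = (d < cutoff) & ~np.eye(len(atoms), dtype=bool)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)

    water_rank: dict[int, int] = {}
    for ci in range(n_comp):
        members = [atoms[i] for i in np.flatnonzero(comp == ci)]
        elements = sorted(a.element for a in members)
        if elements == ["H", "H", "O"]:
            water_rank[ci] = len(water_rank) + 1
    for a, ci in zip(atoms, comp):
        a.fragment_id = water_rank.get(ci, 0)


# ---------------------------------------------------------------------------
# extended XYZ I/O

_INTERPRETED_KEYS = ("label", "charge", "fragments", "sites")


def _parse_comment(line: str) -> dict:
    meta: dict[str, str] = {}
    for token in line.split():
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k] = v
    return meta


def read_multiframe_xyz(path: str | Path) -> Ensemble:
    """Read a multi-frame extended XYZ file into an :class:`Ensemble`.

    Frames without ``fragments=`` metadata get water fragments inferred
    from connectivity (see :func:`infer_fragments`).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    conformers: list[Conformer] = []
    i = 0
    n_frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}")
        if natoms <= 0:
            raise ParseError(f"{path}:{i + 1}: atom count must be positive")
        if i + 1 + natoms >= len(lines) + 1 and i + 1 + natoms > len(lines):
            raise ParseError(f"{path}:{i + 1}: truncated frame")
        meta = _parse_comment(lines[i + 1]) if i + 1 < len(lines) else {}
        atoms: list[Atom] = []
        frags = None
        if "fragments" in meta:
            frags = [int(x) for x in meta["fragments"].split(",")]
            if len(frags) != natoms:
                raise ParseError(f"{path}:{i + 2}: fragments length != atom count")
        sites = None
        if "sites" in meta:
            sites = [None if s == "-" else s for s in meta["sites"].split(",")]
            if len(sites) != natoms:
                raise ParseError(f"{path}:{i + 2}: sites length != atom count")
        for k in range(natoms):
            ln = i + 2 + k
            if ln >= len(lines):
                raise ParseError(f"{path}:{ln + 1}: truncated frame")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln + 1}: malformed atom line {lines[ln]!r}")
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(f"{path}:{ln + 1}: malformed coordinates")
            atoms.append(
                Atom(
                    parts[0],
                    np.array(xyz),
                    frags[k] if frags else 0,
                    sites[k] if sites else None,
                )
            )
        if frags is None:
            infer_fragments(atoms)
        n_frame += 1
        label = meta.get("label", f"frame-{n_frame}")
        charge = int(meta.get("charge", "0"))
        extra = {k: v for k, v in meta.items() if k not in _INTERPRETED_KEYS}
        conformers.append(Conformer(label, atoms, charge, extra))
        i += 2 + natoms

    if not conformers:
        raise ParseError(f"{path}: no frames found")
    if len({len(c.atoms) for c in conformers}) != 1:
        raise StructureError(f"{path}: inconsistent atom counts across frames")
    ens = Ensemble(conformers)
    ens.validate()
    return ens


def write_multiframe_xyz(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as multi-frame extended XYZ (LF endings, %.6f)."""
    ensemble.validate()
    out = []
    for c in ensemble.conformers:
        out.append(f"{len(c.atoms)}")
        meta = [f"label={c.label}", f"charge={c.total_charge}"]
        meta.append("fragments=" + ",".join(str(a.fragment_id) for a in c.atoms))
        if any(a.site_tag for a in c.atoms):
            meta.append("sites=" + ",".join(a.site_tag or "-" for a in c.atoms))
        meta.extend(f"{k}={v}" for k, v in c.extra.items())
        out.append(" ".join(meta))
        for a in c.atoms:
            x, y, z = a.position
            out.append(f"{a.element} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n", newline="\n")


def read_pdb(path: str | Path, label: str | None = None) -> Conformer:
    """Read a single-model PDB file as one conformer (solute template).

    Waters (residue name HOH/WAT) become water fragments in file order,
    everything else is solute.  Uses Biopython's PDB parser.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    model = PDBParser(QUIET=True).get_structure(label or path.stem, str(path))[0]
    atoms: list[Atom] = []
    water_serials: dict[tuple, int] = {}
    for res in model.get_residues():
        fid = 0
        if res.get_resname().strip() in ("HOH", "WAT"):
            key = res.get_full_id()
            if key not in water_serials:
                water_serials[key] = len(water_serials) + 1
            fid = water_serials[key]
        for at in res.get_atoms():
            atoms.append(
                Atom(at.element.capitalize(), np.array(at.coord, dtype=float), fid)
            )
    if not atoms:
        raise ParseError(f"{path}: no atoms found")
    return Conformer(label or path.stem, atoms)
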
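"""Domain types and membrane geometry shared by all analyses.

Internal length unit is nanometres throughout; Angstrom values are accepted
only at I/O boundaries and converted on entry (1 A = 0.1 nm).

The central objects are a :class:`Topology` (atom/residue identity), a
:class:`Frame` (coordinates plus orthorhombic box at one time point), the
:class:`HairpinSpec` naming the membrane-inserting beta-hairpins and the
anchor residue whose C-alpha defines the insertion coordinate zeta, and
:class:`MembraneBounds`, the per-frame bilayer geometry (lipid z-centre,
leaflet phosphate planes, buffered slab).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "HairpinSpec",
    "MembraneBounds",
    "Zeta",
    "select_hairpin_atoms",
    "membrane_bounds",
    "compute_zeta",
    "rewrap_bilayer",
    "ATOMIC_MASSES",
]

#: Standard atomic masses (u) for the elements that occur in protein /
#: phospholipid / water systems.  Used for centre-of-mass reductions.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "MG": 24.305,
}


def element_from_name(atom_name: str) -> str:
    """Guess the element of an atom from its (force-field) name.

    Strips leading digits, then tries the two-letter and one-letter prefix
    against the mass table. ``"CA"`` is carbon (calcium never occurs in
    these systems), ``"NZ"`` nitrogen, ``"OW"`` oxygen, ``"P8"`` phosphorus.
    """
    stripped = atom_name.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    one = stripped[0].upper()
    if two in ("NA", "CL", "MG") and len(stripped) <= 2:
        return two
    if one in ATOMIC_MASSES:
        return one
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass(frozen=True)
class Atom:
    atom_id: int
    name: str
    residue_name: str
    residue_id: int
    segment: str = ""
    element: str = ""

    def mass(self) -> float:
        el = self.element or element_from_name(self.name)
        try:
            return ATOMIC_MASSES[el.upper()]
        except KeyError:
            raise KeyError(f"no mass tabulated for element {el!r} (atom {self.name})")


class Topology:
    """Immutable table of atoms with a residue index.

    Atom ids must be unique; residue ids need not be contiguous. Atoms are
    addressed by their ``atom_id`` (as written in the structure file), not by
    positional index, so selections survive file reordering.
    """

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate atom_ids in topology")
        self._index_of = {a.atom_id: i for i, a in enumerate(self.atoms)}
        self._residues: dict[int, list[Atom]] = {}
        for a in self.atoms:
            self._residues.setdefault(a.residue_id, []).append(a)

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"<Topology: {len(self)} atoms, {len(self._residues)} residues>"

    def index_of(self, atom_id: int) -> int:
        """Positional index of an atom id into coordinate arrays."""
        return self._index_of[atom_id]

    def indices_of(self, atom_ids: Iterable[int]) -> np.ndarray:
        return np.fromiter(
            (self._index_of[i] for i in atom_ids), dtype=np.intp
        )

    @property
    def residue_ids(self) -> list[int]:
        return sorted(self._residues)

    def residue_atoms(self, residue_id: int) -> list[Atom]:
        try:
            return list(self._residues[residue_id])
        except KeyError:
            raise KeyError(f"residue {residue_id} not in topology")

    def residue_name(self, residue_id: int) -> str:
        return self._residues[residue_id][0].residue_name

    def has_residue(self, residue_id: int) -> bool:
        return residue_id in self._residues

    def select(self, *, residue_names: Iterable[str] | None = None,
               atom_names: Iterable[str] | None = None,
               residue_ids: Iterable[int] | None = None) -> set[int]:
        """Atom-id set matching all given criteria (AND semantics)."""
        rn = {s.upper() for s in residue_names} if residue_names is not None else None
        an = {s.upper() for s in atom_names} if atom_names is not None else None
        ri = set(residue_ids) if residue_ids is not None else None
        out = set()
        for a in self.atoms:
            if rn is not None and a.residue_name.upper() not in rn:
                continue
            if an is not None and a.name.upper() not in an:
                continue
            if ri is not None and a.residue_id not in ri:
                continue
            out.add(a.atom_id)
        return out

    def masses(self, atom_ids: Iterable[int]) -> np.ndarray:
        return np.array([self.atoms[self._index_of[i]].mass() for i in atom_ids])


@dataclass
class Frame:
    """Coordinates (nm) and orthorhombic box (nm) at one time point."""

    time: float  # ps
    coordinates: np.ndarray  # (n_atoms, 3), nm
    box: np.ndarray  # (3,) Lx, Ly, Lz in nm

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive lengths (nm)")

    def validate_against(self, topology: Topology) -> None:
        if len(self.coordinates) != len(topology):
            raise ValueError(
                f"frame has {len(self.coordinates)} coordinates but topology "
                f"has {len(topology)} atoms"
            )


@dataclass(frozen=True)
class HairpinSpec:
    """The two beta-hairpin residue intervals and the zeta anchor residue.

    The anchor is the residue whose C-alpha position along the membrane
    normal defines the insertion coordinate (C191 for gasdermin D,
    K97 for gasdermin A3).
    """

    protein_tag: str
    hairpin_ranges: tuple[tuple[int, int], tuple[int, int]]
    anchor_residue: int

    def __post_init__(self) -> None:
        (a0, a1), (b0, b1) = self.hairpin_ranges
        if a0 > a1 or b0 > b1:
            raise ValueError("hairpin ranges must be (lo, hi) with lo <= hi")
        if max(a0, b0) <= min(a1, b1):
            raise ValueError("hairpin ranges must not overlap")
        if not (a0 <= self.anchor_residue <= a1 or b0 <= self.anchor_residue <= b1):
            raise ValueError("anchor residue must lie inside one hairpin range")

    @classmethod
    def gsdmd(cls) -> "HairpinSpec":
        return cls("GSDMD", ((86, 114), (174, 203)), 191)

    @classmethod
    def gsdma3(cls) -> "HairpinSpec":
        return cls("GSDMA3", ((83, 109), (167, 195)), 97)

    def residue_ids(self) -> set[int]:
        out: set[int] = set()
        for lo, hi in self.hairpin_ranges:
            out.update(range(lo, hi + 1))
        return out


@dataclass(frozen=True)
class MembraneBounds:
    """Per-frame bilayer geometry along the membrane normal (z).

    ``z_center`` is the centre of geometry of all lipid atoms (z only);
    ``z_lower_plane`` / ``z_upper_plane`` are the centres of geometry of the
    phosphate oxygens of each leaflet; the slab is the inter-plane interval
    extended by ``buffer`` (default 0.2 nm) on each side to absorb membrane
    surface roughness.
    """

    z_center: float
    z_lower_plane: float
    z_upper_plane: float
    buffer: float = 0.2

    def __post_init__(self) -> None:
        if not (self.z_lower_plane < self.z_center < self.z_upper_plane):
            raise ValueError("require z_lower_plane < z_center < z_upper_plane")

    @property
    def slab(self) -> tuple[float, float]:
        return (self.z_lower_plane - self.buffer, self.z_upper_plane + self.buffer)

    def in_slab(self, z: float | np.ndarray) -> np.ndarray:
        lo, hi = self.slab
        return (np.asarray(z) >= lo) & (np.asarray(z) <= hi)


@dataclass(frozen=True)
class Zeta:
    """Signed membrane-insertion coordinate (nm), positive intracellular."""

    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("zeta must be finite")


def select_hairpin_atoms(topology: Topology, spec: HairpinSpec) -> set[int]:
    """All atom ids whose residue falls in either hairpin interval (inclusive).

    Raises ``KeyError`` listing every residue id of the spec intervals that
    is absent from the topology.
    """
    wanted = spec.residue_ids()
    missing = sorted(r for r in wanted if not topology.has_residue(r))
    if missing:
        raise KeyError(f"hairpin residues absent from topology: {missing}")
    return topology.select(residue_ids=wanted)


def membrane_bounds(
    frame: Frame,
    topology: Topology,
    lipid_atoms: Iterable[int],
    phosphate_oxygens: Iterable[int],
    buffer: float = 0.2,
) -> MembraneBounds:
    """Locate the bilayer along z for one frame.

    The lipid z-centre of geometry splits the phosphate oxygens into the two
    leaflets; each leaflet plane is the mean z of its oxygens; the slab is
    the plane interval padded by ``buffer`` on each side.

    Raises ``ValueError`` on an empty selection or a degenerate leaflet
    (all phosphate oxygens on one side of the lipid centre).
    """
    lipid_atoms = list(lipid_atoms)
    phosphate_oxygens = list(phosphate_oxygens)
    if not lipid_atoms or not phosphate_oxygens:
        raise ValueError("lipid and phosphate-oxygen selections must be non-empty")
    z_lip = frame.coordinates[topology.indices_of(lipid_atoms), 2]
    z_center = float(np.mean(z_lip))
    z_po = frame.coordinates[topology.indices_of(phosphate_oxygens), 2]
    lower = z_po[z_po < z_center]
    upper = z_po[z_po >= z_center]
    if lower.size == 0 or upper.size == 0:
        raise ValueError(
            "degenerate leaflet: all phosphate oxygens on one side of the "
            f"lipid z-center ({z_center:.3f} nm)"
        )
    return MembraneBounds(
        z_center=z_center,
        z_lower_plane=float(np.mean(lower)),
        z_upper_plane=float(np.mean(upper)),
        buffer=float(buffer),
    )


def compute_zeta(
    frame: Frame,
    topology: Topology,
    spec: HairpinSpec,
    membrane_atoms: Iterable[int],
    mode: Literal["center_of_mass", "center_of_geometry"] = "center_of_mass",
    orientation: int = +1,
) -> Zeta:
    """Signed distance along z between the anchor C-alpha and the membrane middle.

    ``mode`` selects how the membrane reference z is reduced: mass-weighted
    (default, matching the definition of the insertion coordinate) or plain
    centre of geometry. ``orientation`` is +1 when the intracellular side is
    +z, -1 when it is -z; zeta is positive toward the intracellular side.
    """
    membrane_atoms = list(membrane_atoms)
    if not membrane_atoms:
        raise ValueError("membrane selection must be non-empty")
    if orientation not in (+1, -1):
        raise ValueError("orientation must be +1 or -1")
    ca = [
        a for a in topology.residue_atoms(spec.anchor_residue)
        if a.name.upper() == "CA"
    ]
    if len(ca) != 1:
        raise ValueError(
            f"anchor residue {spec.anchor_residue} has {len(ca)} C-alpha atoms; "
            "expected exactly one"
        )
    z_ca = float(frame.coordinates[topology.index_of(ca[0].atom_id), 2])
    z_mem = frame.coordinates[topology.indices_of(membrane_atoms), 2]
    if mode == "center_of_mass":
        w = topology.masses(membrane_atoms)
        z_ref = float(np.average(z_mem, weights=w))
    elif mode == "center_of_geometry":
        z_ref = float(np.mean(z_mem))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Zeta(orientation * (z_ca - z_ref))


def rewrap_bilayer(
    frame: Frame, topology: Topology, lipid_atoms: Iterable[int]
) -> Frame:
    """Recenter the bilayer at the middle of the box along z.

    All analyses assume the bilayer is not split across the z boundary.
    This preprocessing shifts every atom so the lipid z-centre of geometry
    sits at Lz/2 and wraps z back into [0, Lz); x and y are untouched.
    """
    lipid_idx = topology.indices_of(list(lipid_atoms))
    if lipid_idx.size == 0:
        raise ValueError("lipid selection must be non-empty")
    Lz = frame.box[2]
    # circular mean along z: robust even when the slab straddles the boundary
    theta = 2.0 * np.pi * frame.coordinates[lipid_idx, 2] / Lz
    mean_angle = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
    z_center = (mean_angle / (2.0 * np.pi)) * Lz % Lz
    shift = Lz / 2.0 - z_center
    coords = frame.coordinates.copy()
    coords[:, 2] = np.mod(coords[:, 2] + shift, Lz)
    return Frame(time=frame.time, coordinates=coords, box=frame.box.copy())


def minimum_image_xy(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention in x and y for an orthorhombic box.

    ``d`` is an (..., 3) array of displacement vectors; z is left untouched
    (analyses assume the bilayer is not split across the z boundary).
    """
    d = np.array(d, dtype=float, copy=True)
    for ax in (0, 1):
        d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return d
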
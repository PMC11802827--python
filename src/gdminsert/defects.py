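"""Water-defect and lipid-headgroup penetration statistics.

A membrane-inserting beta-hairpin drags a column of water ("water defect")
and lipid phosphate headgroups into the hydrophobic core of the bilayer.
This module counts, per frame,

* water molecules whose oxygen lies both inside the buffered membrane slab
  and inside a cylinder that follows the hairpin centre of geometry,
* phosphorus atoms pulled into the core past their own leaflet's phosphate
  plane by more than a configurable depth margin, and
* phosphorus atoms within a cutoff of any hairpin atom, annotated by lipid
  class so headgroup contacts can be tallied per lipid type (PE / PG /
  cardiolipin).

All geometric boundaries are inclusive (<=); in-plane distances use the
minimum-image convention in x,y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Frame, MembraneBounds, Topology, minimum_image_xy

__all__ = [
    "DefectCylinder",
    "DefectSeries",
    "hairpin_center",
    "count_defect_waters",
    "assign_leaflets",
    "count_core_phosphates",
    "phosphates_near_hairpins",
    "tally_by_class",
    "defect_timeseries",
]


@dataclass(frozen=True)
class DefectCylinder:
    """Counting cylinder centred on the hairpin centre of geometry.

    The axis is parallel to z through the per-frame hairpin centre (x, y);
    default radius 1.0 nm and height 6.0 nm (i.e. +/- 3.0 nm about the
    hairpin centre's z).
    """

    radius: float = 1.0
    height: float = 6.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("cylinder radius and height must be positive")

    def contains(self, points: np.ndarray, center: np.ndarray, box: np.ndarray) -> np.ndarray:
        """Inclusive membership test for an (n, 3) point array (nm)."""
        d = minimum_image_xy(points - center, box)
        r_xy = np.hypot(d[:, 0], d[:, 1])
        return (r_xy <= self.radius) & (np.abs(d[:, 2]) <= self.height / 2.0)


@dataclass
class DefectSeries:
    """Per-frame defect statistics as a tidy table."""

    frames: pd.DataFrame  # columns: time_ps, zeta_nm, n_waters, n_core_phosphates
    water_residue_ids: list[set[int]] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False, float_format="%.6f")


def hairpin_center(frame: Frame, topology: Topology, hairpin_atoms: Iterable[int]) -> np.ndarray:
    """Centre of geometry of the hairpin atoms, recomputed per frame."""
    idx = topology.indices_of(list(hairpin_atoms))
    if idx.size == 0:
        raise ValueError("hairpin selection is empty")
    return frame.coordinates[idx].mean(axis=0)


def count_defect_waters(
    frame: Frame,
    topology: Topology,
    bounds: MembraneBounds,
    cylinder: DefectCylinder,
    water_oxygens: Iterable[int],
    hairpin_atoms: Iterable[int],
) -> tuple[int, set[int]]:
    """Count water molecules in the membrane defect for one frame.

    A water counts iff its oxygen satisfies BOTH the slab criterion
    (z inside the buffered slab) AND the cylinder criterion (in-plane
    distance to the hairpin centre <= radius and |z - centre z| <= height/2).
    Each water residue is counted at most once. Returns the count and the
    set of counted water residue ids.
    """
    water_oxygens = list(water_oxygens)
    if not water_oxygens:
        warnings.warn("empty water selection; defect water count is 0")
        return 0, set()
    center = hairpin_center(frame, topology, hairpin_atoms)
    idx = topology.indices_of(water_oxygens)
    pos = frame.coordinates[idx]
    ok = bounds.in_slab(pos[:, 2]) & cylinder.contains(pos, center, frame.box)
    residues = {
        topology.atoms[topology.index_of(aid)].residue_id
        for aid, hit in zip(water_oxygens, ok)
        if hit
    }
    return len(residues), residues


def assign_leaflets(
    frame: Frame,
    topology: Topology,
    bounds: MembraneBounds,
    phosphorus_atoms: Iterable[int],
) -> dict[int, str]:
    """Assign each phosphorus to the leaflet whose plane is nearer.

    Meant to be called once on the first frame of a trajectory and reused,
    so that a headgroup transiently crossing the midplane keeps its leaflet.
    """
    out: dict[int, str] = {}
    for aid in phosphorus_atoms:
        z = frame.coordinates[topology.index_of(aid), 2]
        d_lo = abs(z - bounds.z_lower_plane)
        d_hi = abs(z - bounds.z_upper_plane)
        out[aid] = "lower" if d_lo <= d_hi else "upper"
    return out


def count_core_phosphates(
    frame: Frame,
    topology: Topology,
    bounds: MembraneBounds,
    cylinder: DefectCylinder,
    phosphorus_atoms: Iterable[int],
    hairpin_atoms: Iterable[int],
    leaflet_of: Mapping[int, str] | None = None,
    depth_margin: float = 0.5,
) -> int:
    """Count phosphates pulled into the membrane core inside the defect.

    A phosphorus counts iff it is inside the cylinder AND displaced toward
    the bilayer centre by more than ``depth_margin`` (nm) past its own
    leaflet's phosphate plane. Leaflet membership defaults to nearest-plane
    assignment on this frame; pass ``leaflet_of`` (from frame 0) to freeze
    assignments across a trajectory.
    """
    phosphorus_atoms = list(phosphorus_atoms)
    if not phosphorus_atoms:
        return 0
    if leaflet_of is None:
        leaflet_of = assign_leaflets(frame, topology, bounds, phosphorus_atoms)
    center = hairpin_center(frame, topology, hairpin_atoms)
    idx = topology.indices_of(phosphorus_atoms)
    pos = frame.coordinates[idx]
    in_cyl = cylinder.contains(pos, center, frame.box)
    n = 0
    for aid, p, hit in zip(phosphorus_atoms, pos, in_cyl):
        if not hit:
            continue
        if leaflet_of[aid] == "upper":
            depth = bounds.z_upper_plane - p[2]
        else:
            depth = p[2] - bounds.z_lower_plane
        if depth > depth_margin:
            n += 1
    return n


def phosphates_near_hairpins(
    frame: Frame,
    topology: Topology,
    hairpin_atoms: Iterable[int],
    phosphorus_atoms: Iterable[int],
    cutoff: float = 1.0,
) -> list[tuple[int, str, float]]:
    """Phosphorus atoms within ``cutoff`` (nm) of any hairpin atom.

    Returns ``(atom_id, residue_name, min_distance_nm)`` records, one per
    qualifying phosphorus, so contacts can be aggregated by lipid class.
    """
    hairpin_atoms = list(hairpin_atoms)
    phosphorus_atoms = list(phosphorus_atoms)
    if not hairpin_atoms or not phosphorus_atoms:
        raise ValueError("hairpin and phosphorus selections must be non-empty")
    hp = frame.coordinates[topology.indices_of(hairpin_atoms)]
    out: list[tuple[int, str, float]] = []
    for aid in phosphorus_atoms:
        p = frame.coordinates[topology.index_of(aid)]
        d = minimum_image_xy(hp - p, frame.box)
        dmin = float(np.sqrt((d * d).sum(axis=1)).min())
        if dmin <= cutoff:
            out.append((aid, topology.atoms[topology.index_of(aid)].residue_name, dmin))
    return out


def tally_by_class(records: Sequence[tuple[int, str, float]]) -> dict[str, int]:
    """Aggregate near-hairpin phosphate records by lipid residue name."""
    tally: dict[str, int] = {}
    for _, resname, _ in records:
        tally[resname] = tally.get(resname, 0) + 1
    return tally


def defect_timeseries(
    trajectory: Iterable[Frame],
    topology: Topology,
    *,
    lipid_atoms: Iterable[int],
    phosphate_oxygens: Iterable[int],
    water_oxygens: Iterable[int],
    phosphorus_atoms: Iterable[int],
    hairpin_atoms: Iterable[int],
    cylinder: DefectCylinder | None = None,
    buffer: float = 0.2,
    depth_margin: float = 0.5,
    zeta_values: Sequence[float] | None = None,
) -> DefectSeries:
    """Apply the per-frame defect counts across a trajectory.

    Leaflet assignment of phosphates is frozen at the first frame. If
    ``zeta_values`` is given it must align frame-for-frame and is carried
    into the output table (otherwise the zeta column is NaN).
    """
    from .model import membrane_bounds  # local import to avoid cycle at module load

    cylinder = cylinder or DefectCylinder()
    lipid_atoms = list(lipid_atoms)
    phosphate_oxygens = list(phosphate_oxygens)
    water_oxygens = list(water_oxygens)
    phosphorus_atoms = list(phosphorus_atoms)
    hairpin_atoms = list(hairpin_atoms)

    rows = []
    water_sets: list[set[int]] = []
    leaflet_of: dict[int, str] | None = None
    for i, frame in enumerate(trajectory):
        frame.validate_against(topology)
        bounds = membrane_bounds(frame, topology, lipid_atoms, phosphate_oxygens, buffer)
        if leaflet_of is None:
            leaflet_of = assign_leaflets(frame, topology, bounds, phosphorus_atoms)
        n_w, resids = count_defect_waters(
            frame, topology, bounds, cylinder, water_oxygens, hairpin_atoms
        )
        n_p = count_core_phosphates(
            frame, topology, bounds, cylinder, phosphorus_atoms, hairpin_atoms,
            leaflet_of=leaflet_of, depth_margin=depth_margin,
        )
        zeta = float(zeta_values[i]) if zeta_values is not None else np.nan
        rows.append((frame.time, zeta, n_w, n_p))
        water_sets.append(resids)
    df = pd.DataFrame(
        rows, columns=["time_ps", "zeta_nm", "n_waters", "n_core_phosphates"]
    )
    return DefectSeries(frames=df, water_residue_ids=water_sets)
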
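"""Readers and writers for structures, reaction-coordinate series and configs.

Structure files (PDB or GRO) are parsed through MDAnalysis and converted to
the package's own :class:`~gdminsert.model.Topology` / ``Frame`` pair with
coordinates in nm (MDAnalysis reports Angstrom internally). GRO output is
written by a small deterministic writer so synthetic fixtures are
byte-identical across runs.

Umbrella-window time series use the two-column xvg dialect produced by
GROMACS pull code: lines starting with ``#`` or ``@`` are comments, data
lines are whitespace-separated floats (time, zeta).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .model import Atom, Frame, HairpinSpec, Topology, element_from_name

__all__ = [
    "read_structure",
    "write_gro",
    "read_xvg_series",
    "write_xvg_series",
    "WindowManifest",
    "RunConfig",
]


def read_structure(path: str | Path) -> tuple[Topology, Frame]:
    """Read a PDB or GRO file into a Topology and a single Frame (nm).

    Requires an orthorhombic box; raises ``ValueError`` when the box is
    missing or triclinic.
    """
    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing chatter
        u = mda.Universe(str(path))
    dims = u.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        raise ValueError(f"{path}: no box information")
    if not np.allclose(dims[3:6], 90.0):
        raise ValueError(f"{path}: only orthorhombic boxes are supported")
    atoms = []
    for a in u.atoms:
        try:
            element = element_from_name(a.name)
        except ValueError:
            element = ""
        segid = str(getattr(a, "segid", "") or "")
        atoms.append(
            Atom(int(a.id), str(a.name), str(a.resname), int(a.resid),
                 segment=segid, element=element)
        )
    topology = Topology(atoms)
    coords = u.atoms.positions.astype(float) * 0.1  # Angstrom -> nm
    box = dims[:3].astype(float) * 0.1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # "no dt information" on single frames
        time = float(getattr(u.trajectory.ts, "time", 0.0) or 0.0)
    return topology, Frame(time=time, coordinates=coords, box=box)


def write_gro(path: str | Path, topology: Topology, frame: Frame,
              title: str = "gdminsert frame") -> None:
    """Write a GRO file (nm, fixed 3-decimal coordinates, deterministic)."""
    frame.validate_against(topology)
    lines = [title, f"{len(topology):5d}"]
    for a, xyz in zip(topology.atoms, frame.coordinates):
        lines.append(
            f"{a.residue_id % 100000:5d}{a.residue_name:<5.5s}{a.name:>5.5s}"
            f"{a.atom_id % 100000:5d}"
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        )
    lines.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xvg_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column xvg-style series: (times, values).

    ``#`` and ``@`` lines are skipped; each data line must carry at least
    two floats. Raises ``ValueError`` with a line number on ragged rows and
    when the file has no data lines at all.
    """
    times, values = [], []
    path = Path(path)
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected >= 2 columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric data: {exc}") from None
    if not times:
        raise ValueError(f"{path}: no data lines")
    return np.array(times), np.array(values)


def write_xvg_series(path: str | Path, times: Sequence[float],
                     values: Sequence[float], comment: str = "") -> None:
    """Write a two-column series (6-decimal fixed format)."""
    lines = ["# time_ps  value"]
    if comment:
        lines.insert(0, f"# {comment}")
    for t, v in zip(times, values):
        lines.append(f"{t:.6f} {v:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class WindowManifest:
    """CSV manifest of umbrella windows: file, center_nm, k_kJ_nm2_mol[, discard]."""

    rows: list[tuple[Path, float, float, float]]

    @classmethod
    def read(cls, path: str | Path) -> "WindowManifest":
        path = Path(path)
        rows = []
        with open(path) as fh:
            for ln, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = [p.strip() for p in line.split(",")]
                if parts[0].lower() in ("file", "series_path", "path"):
                    continue  # header
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: need file,center,k[,discard]")
                series = (path.parent / parts[0]).resolve()
                if not series.exists():
                    raise FileNotFoundError(f"{path}:{ln}: series file {series} not found")
                discard = float(parts[3]) if len(parts) > 3 else 0.0
                rows.append((series, float(parts[1]), float(parts[2]), discard))
        if not rows:
            raise ValueError(f"{path}: empty manifest")
        rows.sort(key=lambda r: r[1])
        return cls(rows=rows)

    def load_windows(self):
        from .wham import UmbrellaWindow

        windows = []
        for series, center, k, discard in self.rows:
            times, values = read_xvg_series(series)
            windows.append(
                UmbrellaWindow(center=center, force_constant=k, samples=values,
                               times=times, equilibration_discard=discard)
            )
        return windows


# default atom-name patterns per force-field dialect
DEFAULT_PHOSPHATE_O_NAMES = ("O1P", "O2P", "OP1", "OP2", "O11", "O12", "O13", "O14")
DEFAULT_LIPID_RESNAMES = ("PE", "PG", "CDL", "POPE", "POPG", "CDL2")
DEFAULT_WATER_RESNAMES = ("SOL", "TIP4", "TIP3", "HOH", "WAT")
DEFAULT_WATER_O_NAMES = ("OW", "O")


@dataclass
class RunConfig:
    """Validated analysis configuration (YAML on disk).

    Selections are name-based so the same config drives real force-field
    structures and the synthetic pseudo-lipid fixtures.
    """

    protein_tag: str = "GSDMD"
    hairpin_ranges: tuple[tuple[int, int], tuple[int, int]] = ((86, 114), (174, 203))
    anchor_residue: int = 191
    lipid_resnames: tuple[str, ...] = DEFAULT_LIPID_RESNAMES
    phosphate_o_names: tuple[str, ...] = DEFAULT_PHOSPHATE_O_NAMES
    phosphorus_names: tuple[str, ...] = ("P", "P8", "P1", "P3")
    water_resnames: tuple[str, ...] = DEFAULT_WATER_RESNAMES
    water_o_names: tuple[str, ...] = DEFAULT_WATER_O_NAMES
    intracellular: str = "+z"
    buffer: float = 0.2
    cylinder_radius: float = 1.0
    cylinder_height: float = 6.0
    depth_margin: float = 0.5
    bin_width: float = 0.05
    temperature: float = 310.0
    tol: float = 1e-10
    shift_at: float = 2.5
    adsorbed_region: tuple[float, float] = (1.0, 2.5)
    inserted_region: tuple[float, float] = (-2.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("buffer", "cylinder_radius", "cylinder_height",
                     "depth_margin", "bin_width", "temperature", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config parameter {name} must be positive")
        if self.intracellular not in ("+z", "-z"):
            raise ValueError("intracellular must be '+z' or '-z'")

    @property
    def orientation(self) -> int:
        return +1 if self.intracellular == "+z" else -1

    def hairpin_spec(self) -> HairpinSpec:
        r = tuple(tuple(int(x) for x in pair) for pair in self.hairpin_ranges)
        return HairpinSpec(self.protein_tag, r, int(self.anchor_residue))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hairpin_ranges", "adsorbed_region", "inserted_region",
                    "lipid_resnames", "phosphate_o_names", "phosphorus_names",
                    "water_resnames", "water_o_names"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in data[key]
                )
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            default_flow_style=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
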
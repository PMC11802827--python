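"""Synthetic fixtures with known ground truth.

Two families of fixtures drive the test and validation suite:

* planted membrane frames — a slab of three-atom pseudo-lipids with
  phosphate-oxygen markers on two leaflet planes, bulk waters kept clear of
  the buffered slab or the counting cylinder, a pseudo-hairpin cluster
  defining the cylinder, and exactly the requested numbers of defect
  waters, core phosphates and near-hairpin phosphates planted strictly
  inside the corresponding geometric criteria with a safety margin, so
  every count has an exact expected value;

* umbrella windows sampled *exactly* from the biased Boltzmann density of
  a declared 1-D potential at a given temperature, via inverse-CDF sampling
  on a fine grid. Exact sampling removes autocorrelation, so WHAM recovery
  tests are sharp: any residual error is estimator error, not sampling
  dynamics.

Every generator is deterministic given a seed and returns a truth record
alongside the fixture.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .model import ATOMIC_MASSES, Atom, Frame, HairpinSpec, Topology
from .wham import KJ_PER_KCAL, UmbrellaWindow, thermal_energy_kj

__all__ = [
    "PotentialSpec",
    "SyntheticTruth",
    "make_membrane_frame",
    "sample_umbrella",
    "make_saltbridge_frame",
    "PLANT_MARGIN",
]

#: Safety margin (nm) kept between every planted object and the nearest
#: geometric boundary, so floating-point noise can never flip a count.
PLANT_MARGIN = 0.05

BASIC = ("LYS", "ARG")
ACIDIC = ("GLU", "ASP")
_LIPID_CLASSES = ("PE", "PE", "PE", "PG", "PG", "CDL")  # rough E. coli PLE mix


@dataclass
class PotentialSpec:
    """Declared 1-D potential G(zeta) in kcal/mol on a finite domain.

    Forms:
      * ``harmonic``: G = 1/2 a (z - m)^2, params {"a", "m"}
        (a in kcal mol^-1 nm^-2)
      * ``double_well``: G = A [ (z - c)^2 - w^2 ]^2 / w^4 + b z,
        params {"A", "c", "w", "b"} — minima near c -/+ w separated by a
        barrier of height ~A at z = c, tilted by the linear term b z
      * ``tabulated``: params {"zeta": [...], "G": [...]} with linear
        interpolation
    """

    form: str
    params: dict
    domain: tuple[float, float] = (-2.5, 3.0)

    def energy(self, z: np.ndarray | float) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        p = self.params
        if self.form == "harmonic":
            return 0.5 * p["a"] * (z - p["m"]) ** 2
        if self.form == "double_well":
            A, c, w, b = p["A"], p["c"], p["w"], p.get("b", 0.0)
            return A * ((z - c) ** 2 - w**2) ** 2 / w**4 + b * z
        if self.form == "tabulated":
            return np.interp(z, np.asarray(p["zeta"]), np.asarray(p["G"]))
        raise ValueError(f"unknown potential form {self.form!r}")

    def tabulate(self, n: int = 2001) -> tuple[np.ndarray, np.ndarray]:
        z = np.linspace(*self.domain, n)
        return z, np.asarray(self.energy(z))

    def to_dict(self) -> dict:
        return {"form": self.form, "params": dict(self.params),
                "domain": list(self.domain)}


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside every synthetic fixture."""

    seed: int
    n_defect_waters: int = 0
    defect_water_residue_ids: list[int] = field(default_factory=list)
    n_core_phosphates: int = 0
    near_hairpin_by_class: dict[str, int] = field(default_factory=dict)
    zeta: float | None = None
    z_center: float | None = None
    z_lower_plane: float | None = None
    z_upper_plane: float | None = None
    potential: dict | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _annulus(rng: np.random.Generator, n: int, r_lo: float, r_hi: float) -> np.ndarray:
    """n random points in the annulus r_lo <= r <= r_hi (uniform in area)."""
    if r_hi <= r_lo:
        raise ValueError(f"empty annulus [{r_lo}, {r_hi}]")
    r = np.sqrt(rng.uniform(r_lo**2, r_hi**2, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def make_membrane_frame(
    *,
    box: tuple[float, float, float] = (8.0, 8.0, 10.0),
    half_thickness: float = 2.0,
    lipids_per_leaflet: int = 60,
    n_bulk_waters: int = 300,
    n_defect_waters: int = 0,
    n_core_phosphates: int = 0,
    near_hairpin_by_class: dict[str, int] | None = None,
    zeta: float = 0.0,
    cylinder_radius: float = 1.0,
    cylinder_height: float = 6.0,
    buffer: float = 0.2,
    depth_margin: float = 0.5,
    plane_jitter: float = 0.03,
    hairpin_spec: HairpinSpec | None = None,
    seed: int = 0,
) -> tuple[Topology, Frame, SyntheticTruth]:
    """Build a planted bilayer frame with exactly known analysis outcomes.

    Geometry: bilayer centred at z = Lz/2, phosphate planes near +/-
    ``half_thickness`` about the centre; a pseudo-hairpin ladder of
    single-CA residues hugs the box axis in the lower half of the membrane
    (as an inserting hairpin tip would), and its anchor CA is pinned so
    that the frame's insertion coordinate equals ``zeta`` exactly, against
    the realized mass-weighted lipid z-centre.

    Planting contracts (margin ``PLANT_MARGIN`` everywhere):

    * defect waters satisfy both the buffered-slab and the cylinder
      criterion; bulk waters violate at least one;
    * core phosphates sit inside the cylinder, sunk ``depth_margin + 0.3``
      nm past the upper plane, but > 1.05 nm from every hairpin atom so
      they never enter the near-hairpin tally;
    * near-hairpin phosphates (per lipid class) rest on the lower plane
      within 0.95 nm of the bottom of the hairpin, where their penetration
      depth is zero;
    * ordinary lipids stay outside ``cylinder_radius + 0.6`` laterally.

    Raises ``ValueError`` when the requested combination cannot be placed
    (e.g. an anchor at this ``zeta`` would sit within the near-hairpin
    cutoff of a planted core phosphate).
    """
    rng = np.random.default_rng(seed)
    near_hairpin_by_class = dict(near_hairpin_by_class or {})
    hairpin_spec = hairpin_spec or HairpinSpec("custom", ((1, 5), (7, 11)), 3)
    Lx, Ly, Lz = box
    zc = Lz / 2.0
    cx, cy = Lx / 2.0, Ly / 2.0
    r_exclude = cylinder_radius + 0.6
    r_max = min(Lx, Ly) / 2.0 - 0.1
    if r_exclude + 0.2 > r_max:
        raise ValueError("box too small for the requested cylinder")
    if half_thickness + buffer + 0.6 > Lz / 2.0:
        raise ValueError("box too shallow for the requested bilayer")

    # --- hairpin ladder (z positions fixed, anchor pinned later) -----------
    hp_resids = sorted(hairpin_spec.residue_ids())
    n_hp = len(hp_resids)
    ladder = zc + np.linspace(-0.6 * half_thickness, -0.15 * half_thickness, n_hp)
    hp_xy = np.array([cx, cy]) + rng.uniform(-0.02, 0.02, (n_hp, 2))
    anchor_pos = hp_resids.index(hairpin_spec.anchor_residue)
    hp_xy[anchor_pos] = (cx, cy)

    # --- lipid bookkeeping: decide every z before computing the reference --
    sink = depth_margin + 0.3
    z_hi_nominal = zc + half_thickness
    z_lo_nominal = zc - half_thickness
    n_planted = n_core_phosphates + sum(near_hairpin_by_class.values())
    n_plain = 2 * lipids_per_leaflet - n_planted
    if n_plain < 4:
        raise ValueError("planted lipids exceed the requested lipid count")
    n_plain_up = n_plain // 2
    n_plain_lo = n_plain - n_plain_up

    plain_up_z = z_hi_nominal + rng.uniform(-plane_jitter, plane_jitter, n_plain_up)
    plain_lo_z = z_lo_nominal + rng.uniform(-plane_jitter, plane_jitter, n_plain_lo)
    core_z = np.full(n_core_phosphates, z_hi_nominal - sink)
    near_classes = [c for c, n in sorted(near_hairpin_by_class.items())
                    for _ in range(n)]
    near_z = np.full(len(near_classes), z_lo_nominal)

    # realized membrane references, computed exactly from the decided z's:
    # phosphate marker O sits 0.02 nm coreward of P, tail bead 0.8 nm coreward
    def _lipid_zs(p_z: np.ndarray, upper: bool) -> np.ndarray:
        s = -1.0 if upper else +1.0
        return np.concatenate([p_z, p_z + 0.02 * s, p_z + 0.8 * s])

    all_up_pz = np.concatenate([plain_up_z, core_z])
    all_lo_pz = np.concatenate([plain_lo_z, near_z])
    z_all = np.concatenate([_lipid_zs(all_up_pz, True), _lipid_zs(all_lo_pz, False)])
    m_one = np.array([ATOMIC_MASSES["P"], ATOMIC_MASSES["O"], ATOMIC_MASSES["C"]])
    w_up = np.repeat(m_one, [all_up_pz.size] * 3)
    w_lo = np.repeat(m_one, [all_lo_pz.size] * 3)
    z_com = float(np.average(z_all, weights=np.concatenate([w_up, w_lo])))
    z_cog = float(np.mean(z_all))
    anchor_z = z_com + zeta  # insertion coordinate uses the lipid z-CoM

    hp_z = ladder.copy()
    hp_z[anchor_pos] = anchor_z
    cog = np.array([hp_xy[:, 0].mean(), hp_xy[:, 1].mean(), hp_z.mean()])

    # realized leaflet phosphate-oxygen planes (what the analysis will see)
    up_o = all_up_pz - 0.02
    lo_o = all_lo_pz + 0.02
    plane_hi = float(np.mean(up_o[up_o >= z_cog]))
    plane_lo = float(np.mean(lo_o[lo_o < z_cog]))
    if not np.all(up_o >= z_cog) or not np.all(lo_o < z_cog):
        raise ValueError("a phosphate marker crossed the lipid z-centre")
    slab_lo, slab_hi = plane_lo - buffer, plane_hi + buffer

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    aid = 0
    resid_counter = [max(hp_resids) + 100]

    def add(name: str, resname: str, resid: int, xyz, element: str) -> None:
        nonlocal aid
        aid += 1
        atoms.append(Atom(aid, name, resname, resid, element=element))
        coords.append(np.asarray(xyz, dtype=float))

    for i, rid in enumerate(hp_resids):
        resname = "CYS" if rid == hairpin_spec.anchor_residue else "GLY"
        add("CA", resname, rid, (hp_xy[i, 0], hp_xy[i, 1], hp_z[i]), "C")

    def add_lipid(p_xyz: np.ndarray, cls: str, upper: bool) -> None:
        resid_counter[0] += 1
        rid = resid_counter[0]
        s = -1.0 if upper else +1.0
        add("P8", cls, rid, p_xyz, "P")
        add("OP1", cls, rid, p_xyz + np.array([0.0, 0.0, 0.02 * s]), "O")
        add("C1", cls, rid, p_xyz + np.array([0.0, 0.0, 0.8 * s]), "C")

    # planted core phosphates: lateral ring inside the cylinder, clear of the
    # whole hairpin ladder (and anchor) by > 1.05 nm
    for j in range(n_core_phosphates):
        if plane_hi - core_z[j] <= depth_margin + PLANT_MARGIN:
            raise ValueError(
                "infeasible geometry: realized upper plane too low to sink "
                "core phosphates past the depth margin"
            )
        dz_min = np.min(np.abs(core_z[j] - hp_z))
        r_need = 0.0
        if dz_min < 1.05:
            r_need = math.sqrt(1.05**2 - dz_min**2) - 0.02 + PLANT_MARGIN
        r_ceiling = cylinder_radius - PLANT_MARGIN
        if r_need >= r_ceiling:
            raise ValueError(
                "infeasible geometry: a core phosphate cannot be both inside "
                "the cylinder and clear of the near-hairpin cutoff at this "
                "zeta; move the anchor or widen the cylinder"
            )
        xy = _annulus(rng, 1, max(r_need, 0.1), r_ceiling)[0]
        add_lipid(np.array([cog[0] + xy[0], cog[1] + xy[1], core_z[j]]), "PE", True)

    # planted near-hairpin phosphates: on the lower plane, within 0.95 nm of
    # the deepest hairpin atom
    bottom = int(np.argmin(np.abs((near_z[0] if near_classes else 0.0) - hp_z)))
    dz = abs(near_z[0] - hp_z[bottom]) if near_classes else 0.0
    for j, cls in enumerate(near_classes):
        if dz >= 0.95:
            raise ValueError(
                "infeasible geometry: hairpin ladder does not reach within "
                "0.95 nm of the lower plane"
            )
        r_allow = math.sqrt(0.95**2 - dz**2) - 0.02
        xy = _annulus(rng, 1, 0.05, max(r_allow, 0.1))[0]
        add_lipid(np.array([hp_xy[bottom, 0] + xy[0], hp_xy[bottom, 1] + xy[1],
                            near_z[j]]), cls, False)

    # ordinary lipids, outside the cylinder neighbourhood
    for z in plain_up_z:
        xy = _annulus(rng, 1, r_exclude, r_max)[0]
        add_lipid(np.array([cog[0] + xy[0], cog[1] + xy[1], z]),
                  _LIPID_CLASSES[resid_counter[0] % len(_LIPID_CLASSES)], True)
    for z in plain_lo_z:
        xy = _annulus(rng, 1, r_exclude, r_max)[0]
        add_lipid(np.array([cog[0] + xy[0], cog[1] + xy[1], z]),
                  _LIPID_CLASSES[resid_counter[0] % len(_LIPID_CLASSES)], False)

    # --- waters -------------------------------------------------------------
    z_win_lo = max(slab_lo, cog[2] - cylinder_height / 2) + PLANT_MARGIN
    z_win_hi = min(slab_hi, cog[2] + cylinder_height / 2) - PLANT_MARGIN
    if z_win_hi <= z_win_lo:
        raise ValueError("infeasible geometry: defect window is empty")
    defect_ids: list[int] = []
    for _ in range(n_defect_waters):
        xy = _annulus(rng, 1, 1e-6, cylinder_radius - PLANT_MARGIN)[0]
        z = rng.uniform(z_win_lo, z_win_hi)
        resid_counter[0] += 1
        add("OW", "SOL", resid_counter[0], (cog[0] + xy[0], cog[1] + xy[1], z), "O")
        defect_ids.append(resid_counter[0])
    for _ in range(n_bulk_waters):
        resid_counter[0] += 1
        kind = rng.integers(0, 3)
        if kind == 0 and slab_hi + PLANT_MARGIN < Lz - 0.1:
            z = rng.uniform(slab_hi + PLANT_MARGIN, Lz - 0.1)
            xyz = (rng.uniform(0.1, Lx - 0.1), rng.uniform(0.1, Ly - 0.1), z)
        elif kind == 1 and slab_lo - PLANT_MARGIN > 0.1:
            z = rng.uniform(0.1, slab_lo - PLANT_MARGIN)
            xyz = (rng.uniform(0.1, Lx - 0.1), rng.uniform(0.1, Ly - 0.1), z)
        else:  # in-slab but laterally outside the cylinder
            xy = _annulus(rng, 1, cylinder_radius + PLANT_MARGIN, r_max)[0]
            z = rng.uniform(z_lo_nominal, z_hi_nominal)
            xyz = (cog[0] + xy[0], cog[1] + xy[1], z)
        add("OW", "SOL", resid_counter[0], xyz, "O")

    topology = Topology(atoms)
    frame = Frame(time=0.0, coordinates=np.vstack(coords), box=np.array(box))
    truth = SyntheticTruth(
        seed=int(seed),
        n_defect_waters=int(n_defect_waters),
        defect_water_residue_ids=defect_ids,
        n_core_phosphates=int(n_core_phosphates),
        near_hairpin_by_class=near_hairpin_by_class,
        zeta=float(zeta),
        z_center=z_cog,
        z_lower_plane=plane_lo,
        z_upper_plane=plane_hi,
    )
    return topology, frame, truth


def sample_umbrella(
    potential: PotentialSpec,
    centers: Sequence[float],
    k: float = 1000.0,
    n_per_window: int = 20000,
    temperature: float = 310.0,
    seed: int = 0,
    grid_step: float = 0.005,
) -> list[UmbrellaWindow]:
    """Draw exact samples from the biased Boltzmann density of each window.

    For window i the density is p_i(z) ~ exp[-(G(z) + k/2 (z - z_i)^2)/kT]
    with G in kcal/mol (converted to kJ/mol internally) and k in
    kJ nm^-2 mol^-1. Sampling is inverse-CDF on a grid of step
    ``grid_step`` (nm) over the potential's domain; raises ``ValueError``
    when more than 99.9% of a window's biased mass falls outside the domain.
    """
    rng = np.random.default_rng(seed)
    kT = thermal_energy_kj(temperature)
    lo, hi = potential.domain
    sigma = math.sqrt(kT / k) if k > 0 else (hi - lo)
    ext = 6.0 * sigma + 0.5  # probe range for out-of-domain mass
    n_grid = max(int(np.ceil((hi - lo + 2 * ext) / grid_step)) + 1, 1001)
    z_ext = np.linspace(lo - ext, hi + ext, n_grid)
    G_ext = np.asarray(potential.energy(np.clip(z_ext, lo, hi))) * KJ_PER_KCAL
    inside = (z_ext >= lo) & (z_ext <= hi)

    windows: list[UmbrellaWindow] = []
    for zi in centers:
        u_ext = G_ext + 0.5 * k * (z_ext - zi) ** 2
        w_ext = np.exp(-(u_ext - u_ext.min()) / kT)
        total = np.trapezoid(w_ext, z_ext)
        got = np.trapezoid(np.where(inside, w_ext, 0.0), z_ext)
        if got / total < 1e-3:
            raise ValueError(
                f"window at {zi} nm: >99.9% of biased mass outside the "
                f"potential domain [{lo}, {hi}] nm"
            )
        z = z_ext[inside]
        w = w_ext[inside]
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(z))])
        cdf /= cdf[-1]
        keep = np.concatenate([[True], np.diff(cdf) > 0])  # strictly increasing
        u = rng.uniform(0.0, 1.0, n_per_window)
        samples = np.interp(u, cdf[keep], z[keep])
        times = np.arange(n_per_window, dtype=float)
        windows.append(UmbrellaWindow(center=float(zi), force_constant=float(k),
                                      samples=samples, times=times))
    return windows


# ---------------------------------------------------------------------------
# idealized salt-bridge geometry

_CO_BOND_A = 1.25     # carboxylate C-O bond length, Angstrom
_OCO_ANGLE_DEG = 124  # O-C-O angle of an idealized carboxylate
_CN_GUA_A = 1.33      # guanidinium C-N bond length, Angstrom


def make_saltbridge_frame(
    pair_type: tuple[str, str], central_distance_A: float
) -> tuple[Topology, Frame]:
    """Minimal two-residue system at an exact central-atom separation.

    The acidic residue carries an idealized planar carboxylate (C-O 1.25 A,
    O-C-O 124 deg) whose bisector points along +x toward the basic residue;
    the basic residue carries the lysine terminal nitrogen or an idealized
    guanidinium (CZ with three N at 120 deg in-plane). The central atoms
    are exactly ``central_distance_A`` apart along x. Coordinates nm.
    """
    b_type, a_type = (t.upper() for t in pair_type)
    if b_type not in BASIC or a_type not in ACIDIC:
        raise ValueError(f"unknown pair type {pair_type}")
    if central_distance_A <= 0:
        raise ValueError("central distance must be positive")
    d = central_distance_A * 0.1  # nm
    co = _CO_BOND_A * 0.1
    half = math.radians(_OCO_ANGLE_DEG / 2.0)
    origin = np.array([2.0, 4.0, 4.0])

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    aid = 0

    def add(name, resname, resid, xyz, element):
        nonlocal aid
        aid += 1
        atoms.append(Atom(aid, name, resname, resid, element=element))
        coords.append(origin + np.asarray(xyz, dtype=float))

    c_name = "CD" if a_type == "GLU" else "CG"
    o_names = ("OE1", "OE2") if a_type == "GLU" else ("OD1", "OD2")
    add("CA", a_type, 1, (-0.3, 0.0, 0.0), "C")
    add(c_name, a_type, 1, (0.0, 0.0, 0.0), "C")
    for name, s in zip(o_names, (+1, -1)):
        add(name, a_type, 1, (co * math.cos(half), s * co * math.sin(half), 0.0), "O")

    if b_type == "LYS":
        add("CA", b_type, 2, (d + 0.3, 0.0, 0.0), "C")
        add("NZ", b_type, 2, (d, 0.0, 0.0), "N")
    else:
        add("CA", b_type, 2, (d + 0.4, 0.0, 0.0), "C")
        add("CZ", b_type, 2, (d, 0.0, 0.0), "C")
        gn = _CN_GUA_A * 0.1
        for j, name in enumerate(("NH1", "NH2", "NE")):
            ang = math.radians(180.0 + 120.0 * j)
            add(name, b_type, 2,
                (d + gn * math.cos(ang), gn * math.sin(ang), 0.0), "N")

    return Topology(atoms), Frame(time=0.0, coordinates=np.vstack(coords),
                                  box=np.array([12.0, 8.0, 8.0]))
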
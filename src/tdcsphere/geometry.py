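"""Multi-shell spherical head geometry, 10-20 sensor layout and frontal atlas.

Coordinate convention (used throughout the package): head centre at the
origin, +z through the vertex (Cz), +x through the nasion, right-handed,
so the left hemisphere has y > 0.  All lengths are millimetres, all
conductivities S/m.

The head is five concentric conductive shells (white matter, gray matter,
CSF, skull, scalp).  Electric fields are sampled on a quasi-uniform node
set on the mid-gray-matter sphere, labelled with a spherical-patch
analogue of a ten-region-per-hemisphere frontal parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TISSUES = ("wm", "gm", "csf", "skull", "scalp")

#: Default tissue conductivities (S/m), the values commonly used by
#: simulation platforms for DC stimulation.
DEFAULT_CONDUCTIVITIES = {
    "wm": 0.126,
    "gm": 0.275,
    "csf": 1.654,
    "skull": 0.010,
    "scalp": 0.465,
}

#: Default shell outer radii (mm), innermost first.
DEFAULT_RADII = {"wm": 70.0, "gm": 78.0, "csf": 81.0, "skull": 86.0, "scalp": 92.0}

#: Gray-matter shell thickness (mm) standing in for a reference cortical
#: thickness of 2.41 mm (the shell also absorbs cortical folding).
REFERENCE_GM_SHELL_MM = 8.0
REFERENCE_CORTICAL_THICKNESS_MM = 2.41

FRONTAL_REGIONS = (
    "PMC", "SMC", "ACC", "mPFC", "mOFC",
    "FEF", "lPMC", "dlPFC", "ilPFC", "lOFC",
)
NON_FRONTAL = "non-frontal"


class GeometryError(ValueError):
    """Raised for invalid shell nesting or off-sphere positions."""


class AtlasError(ValueError):
    """Raised when a patch table leaves gaps or overlaps."""


@dataclass(frozen=True)
class ShellSpec:
    """One conductive shell: tissue label, outer radius (mm), conductivity (S/m)."""

    name: str
    outer_radius: float
    conductivity: float

    def __post_init__(self):
        if self.name not in TISSUES:
            raise ValueError(f"unknown tissue {self.name!r}; expected one of {TISSUES}")
        if not self.outer_radius > 0:
            raise GeometryError(f"shell {self.name}: outer radius must be > 0")
        if not self.conductivity > 0:
            raise ValueError(f"shell {self.name}: conductivity must be > 0")


@dataclass(frozen=True)
class HeadModel:
    """Five strictly nested shells plus subject metadata."""

    shells: tuple[ShellSpec, ...]
    subject_id: str = "default"
    group: str = "none"

    def __post_init__(self):
        if len(self.shells) != 5:
            raise GeometryError(f"expected 5 shells, got {len(self.shells)}")
        names = tuple(s.name for s in self.shells)
        if names != TISSUES:
            raise GeometryError(f"shells must be ordered {TISSUES}, got {names}")
        radii = [s.outer_radius for s in self.shells]
        if not all(a < b for a, b in zip(radii, radii[1:])):
            raise GeometryError(f"shell outer radii must strictly increase, got {radii}")
        if self.group not in ("AD", "control", "none"):
            raise ValueError(f"group must be AD/control/none, got {self.group!r}")

    def shell(self, tissue: str) -> ShellSpec:
        for s in self.shells:
            if s.name == tissue:
                return s
        raise KeyError(tissue)

    def radius(self, tissue: str) -> float:
        return self.shell(tissue).outer_radius

    def thickness(self, tissue: str) -> float:
        """Radial thickness of a shell (innermost shell: its full radius)."""
        i = TISSUES.index(tissue)
        inner = 0.0 if i == 0 else self.shells[i - 1].outer_radius
        return self.shells[i].outer_radius - inner

    @property
    def scalp_radius(self) -> float:
        return self.shells[-1].outer_radius

    @property
    def mid_gm_radius(self) -> float:
        """Radius of the mid-gray-matter sampling sphere."""
        return 0.5 * (self.radius("wm") + self.radius("gm"))

    def radii(self) -> np.ndarray:
        return np.array([s.outer_radius for s in self.shells])

    def conductivities(self) -> np.ndarray:
        return np.array([s.conductivity for s in self.shells])

    def with_gm_thickness(self, gm_thickness: float) -> "HeadModel":
        """Return a model with the GM shell rescaled, holding the WM and CSF
        outer radii fixed, so GM thinning becomes CSF thickening."""
        wm = self.radius("wm")
        csf = self.radius("csf")
        new_gm = wm + gm_thickness
        if not wm < new_gm < csf:
            raise GeometryError(
                f"gm thickness {gm_thickness} incompatible with wm={wm}, csf={csf}"
            )
        shells = tuple(
            replace(s, outer_radius=new_gm) if s.name == "gm" else s
            for s in self.shells
        )
        return replace(self, shells=shells)


def build_head_model(
    shells: Iterable[ShellSpec] | None = None,
    *,
    radii: Mapping[str, float] | None = None,
    conductivities: Mapping[str, float] | None = None,
    subject_id: str = "default",
    group: str = "none",
) -> HeadModel:
    """Construct a validated five-shell head model.

    Either pass explicit ``shells`` (innermost first) or override the
    default ``radii`` / ``conductivities`` per tissue.
    """
    if shells is None:
        r = dict(DEFAULT_RADII)
        c = dict(DEFAULT_CONDUCTIVITIES)
        if radii:
            r.update(radii)
        if conductivities:
            c.update(conductivities)
        shells = [ShellSpec(t, r[t], c[t]) for t in TISSUES]
    return HeadModel(tuple(shells), subject_id=subject_id, group=group)


# ---------------------------------------------------------------------------
# 10-20 sensor layout
# ---------------------------------------------------------------------------

def _sph(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit vector from polar angle theta (from +z) and azimuth phi
    (from +x toward +y, i.e. positive = left)."""
    th, ph = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    ang = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if ang < 1e-12:
        return a.copy()
    return (np.sin((1 - t) * ang) * a + np.sin(t * ang) * b) / np.sin(ang)


@dataclass(frozen=True)
class SensorLayout:
    """Extended 10-20 positions as unit direction vectors on the scalp sphere."""

    positions: dict[str, np.ndarray]
    scalp_radius: float

    def __contains__(self, label: str) -> bool:
        return label in self.positions

    def direction(self, label: str) -> np.ndarray:
        try:
            return self.positions[label]
        except KeyError:
            raise KeyError(f"unknown 10-20 label {label!r}") from None

    def point(self, label: str) -> np.ndarray:
        return self.direction(label) * self.scalp_radius

    def labels(self) -> list[str]:
        return sorted(self.positions)


#: The classic 19-channel 10-20 set, used as the neighbour pool for 4x1
#: ring cathodes (modern temporal names T7/T8/P7/P8).
CLASSIC_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)


def layout_1020(head: HeadModel) -> SensorLayout:
    """Extended 10-20 layout on the scalp sphere by the proportional scheme.

    Midline electrodes sit on the nasion-inion great circle at 10 % steps
    of the 180 deg arc; the outer circle (Fp1 ... O1) sits at 72 deg polar
    angle at 10 % steps of the circumference; intermediate rows are
    great-circle interpolations between their temporal and midline ends.
    """
    pos: dict[str, np.ndarray] = {}
    # midline: nasion (theta 90, front) -> vertex -> inion
    pos["Fpz"] = _sph(72, 0)
    pos["AFz"] = _sph(54, 0)
    pos["Fz"] = _sph(36, 0)
    pos["FCz"] = _sph(18, 0)
    pos["Cz"] = _sph(0, 0)
    pos["CPz"] = _sph(18, 180)
    pos["Pz"] = _sph(36, 180)
    pos["POz"] = _sph(54, 180)
    pos["Oz"] = _sph(72, 180)
    pos["Iz"] = _sph(90, 180)
    # outer circle, left then right (mirror phi -> -phi)
    circle = {"Fp1": 18, "AF7": 36, "F7": 54, "FT7": 72, "T7": 90,
              "TP7": 108, "P7": 126, "PO7": 144, "O1": 162}
    for lab, phi in circle.items():
        pos[lab] = _sph(72, phi)
        pos[lab.replace("7", "8").replace("1", "2")] = _sph(72, -phi)
    # coronal arcs: temporal end -> midline end, electrodes at quarter points
    arcs = {
        "F": ("F7", "Fz", ("F5", "F3", "F1")),
        "FC": ("FT7", "FCz", ("FC5", "FC3", "FC1")),
        "C": ("T7", "Cz", ("C5", "C3", "C1")),
        "CP": ("TP7", "CPz", ("CP5", "CP3", "CP1")),
        "P": ("P7", "Pz", ("P5", "P3", "P1")),
    }
    for _row, (tlab, mlab, labs) in arcs.items():
        a, b = pos[tlab], pos[mlab]
        for lab, t in zip(labs, (0.25, 0.5, 0.75)):
            v = _slerp(a, b, t)
            pos[lab] = v
            right = lab.translate(str.maketrans("1357", "2468"))
            pos[right] = v * np.array([1.0, -1.0, 1.0])
    # AF row between Fp and F rows
    pos["AF3"] = _slerp(pos["AF7"], pos["AFz"], 0.5)
    pos["AF4"] = pos["AF3"] * np.array([1.0, -1.0, 1.0])
    pos = {k: v / np.linalg.norm(v) for k, v in pos.items()}
    return SensorLayout(pos, scalp_radius=head.scalp_radius)


# ---------------------------------------------------------------------------
# Frontal atlas and cortical sampling mesh
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionAtlas:
    """Spherical-patch frontal parcellation: ten regions per hemisphere.

    Patches are (polar, azimuth) bands on the anterior half-sphere, mirror
    symmetric about the midsagittal plane; everything else is non-frontal.
    ``patch_table`` maps region name -> tuple of bands
    (theta_lo, theta_hi, aphi_lo, aphi_hi) in degrees, with
    aphi = \\|azimuth\\| so the same row serves both hemispheres.  A bare
    4-tuple is accepted as a single band.
    """

    patch_table: dict[str, tuple]

    def __post_init__(self):
        # normalize: every region holds a tuple of bands
        tab = {}
        for name, bands in self.patch_table.items():
            if bands and np.isscalar(bands[0]):
                bands = (tuple(bands),)
            tab[name] = tuple(tuple(b) for b in bands)
        object.__setattr__(self, "patch_table", tab)
        self.validate()

    def bands(self, region: str) -> tuple[tuple[float, float, float, float], ...]:
        return self.patch_table[region]

    def validate(self) -> None:
        # probe a fine grid of the claimed frontal sector for gaps/overlaps
        th = np.linspace(0.01, self.theta_max() - 0.01, 160)
        ap = np.linspace(0.01, 89.99, 160)
        T, P = np.meshgrid(th, ap)
        hits = np.zeros(T.shape, dtype=int)
        for r in FRONTAL_REGIONS:
            for lo, hi, alo, ahi in self.patch_table[r]:
                hits += ((T >= lo) & (T < hi) & (P >= alo) & (P < ahi)).astype(int)
        if hits.max() > 1:
            raise AtlasError("frontal patches overlap")
        if hits.min() < 1:
            raise AtlasError("frontal patches leave a gap in the frontal sector")

    def theta_max(self) -> float:
        return max(hi for bands in self.patch_table.values() for _, hi, _, _ in bands)

    def label_nodes(self, nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (region, hemisphere) string arrays for unit node vectors."""
        x, y, z = nodes[:, 0], nodes[:, 1], nodes[:, 2]
        theta = np.rad2deg(np.arccos(np.clip(z, -1, 1)))
        phi = np.rad2deg(np.arctan2(y, x))
        region = np.full(len(nodes), NON_FRONTAL, dtype=object)
        hemi = np.where(y >= 0, "L", "R")
        frontal = np.abs(phi) < 90.0
        for name, bands in self.patch_table.items():
            for lo, hi, alo, ahi in bands:
                m = (
                    frontal & (theta >= lo) & (theta < hi)
                    & (np.abs(phi) >= alo) & (np.abs(phi) < ahi)
                )
                region[m] = name
        return region.astype(str), hemi.astype(str)


#: Default patch table: polar/azimuth bands on the anterior half-sphere,
#: with the dlPFC cell centred on the radial projection of F3
#: (polar ~51 deg, azimuth ~34 deg).  Bands are (theta_lo, theta_hi,
#: \\|phi\\|_lo, \\|phi\\|_hi) degrees; ilPFC wraps around dlPFC laterally
#: and inferiorly.
DEFAULT_PATCH_TABLE = {
    "PMC": (0.0, 25.0, 0.0, 25.0),
    "FEF": (0.0, 25.0, 25.0, 90.0),
    "SMC": (25.0, 40.0, 0.0, 20.0),
    "lPMC": (25.0, 40.0, 20.0, 90.0),
    "ACC": (40.0, 62.0, 0.0, 20.0),
    "dlPFC": (40.0, 62.0, 20.0, 48.0),
    "ilPFC": ((40.0, 62.0, 48.0, 90.0), (62.0, 95.0, 25.0, 90.0)),
    "mPFC": (62.0, 95.0, 0.0, 25.0),
    "mOFC": (95.0, 115.0, 0.0, 25.0),
    "lOFC": (95.0, 115.0, 25.0, 90.0),
}


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors by the Fibonacci (golden-spiral) lattice."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


@dataclass
class CorticalMesh:
    """Sampling nodes on (or near) the mid-GM sphere.

    ``nodes`` are unit direction vectors; ``radii`` the per-node sampling
    radius (mm, constant for the canonical mesh, perturbed for synthetic
    folded-cortex subjects); ``inward_normal`` unit vectors (radially inward
    for the canonical mesh); equal ``area_weight`` per node summing to the
    sampling-sphere area.
    """

    nodes: np.ndarray
    radii: np.ndarray
    inward_normal: np.ndarray
    region: np.ndarray
    hemisphere: np.ndarray
    area_weight: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def positions(self) -> np.ndarray:
        return self.nodes * self.radii[:, None]

    def is_region(self, region: str, hemisphere: str | None = None) -> np.ndarray:
        m = self.region == region
        if hemisphere is not None:
            m &= self.hemisphere == hemisphere
        return m

    def to_frame(self) -> pd.DataFrame:
        p = self.positions()
        return pd.DataFrame(
            {
                "node_id": np.arange(self.n_nodes),
                "x": p[:, 0], "y": p[:, 1], "z": p[:, 2],
                "nx": self.inward_normal[:, 0],
                "ny": self.inward_normal[:, 1],
                "nz": self.inward_normal[:, 2],
                "region": self.region,
                "hemisphere": self.hemisphere,
                "area_weight": self.area_weight,
            }
        )


def build_atlas(
    head: HeadModel,
    n_nodes: int = 5000,
    seed: int = 0,
    patch_table: Mapping[str, tuple[float, float, float, float]] | None = None,
) -> tuple[RegionAtlas, CorticalMesh]:
    """Build the frontal atlas and a labelled mid-GM sampling mesh.

    The node set is a Fibonacci lattice (deterministic; ``seed`` is kept in
    the signature for config provenance and future stochastic meshes).
    """
    if n_nodes < 2000:
        raise ValueError("n_nodes must be >= 2000 for stable region statistics")
    atlas = RegionAtlas(dict(patch_table or DEFAULT_PATCH_TABLE))
    nodes = fibonacci_sphere(n_nodes)
    r_mid = head.mid_gm_radius
    region, hemi = atlas.label_nodes(nodes)
    area = np.full(n_nodes, 4.0 * np.pi * r_mid**2 / n_nodes)
    mesh = CorticalMesh(
        nodes=nodes,
        radii=np.full(n_nodes, r_mid),
        inward_normal=-nodes,
        region=region,
        hemisphere=hemi,
        area_weight=area,
    )
    return atlas, mesh
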
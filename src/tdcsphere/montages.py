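"""Electrode montages and the two-rule 4x1 ring-montage optimizer.

The library reproduces the montage set of published DLPFC stimulation
protocols for dementia patients: four bipolar pad montages plus a uniform
4x1 high-definition ring centred on F3, all at 2 mA total anodal current.
The optimizer searches a candidate set of eight 4x1 rings over the left
frontal cortex and applies two rules on the solved field: (1) the frontal
region receiving the strongest anodal (inward) normal component must be the
left dlPFC; (2) among survivors, maximize the anodal-minus-cathodal normal
component in the left dlPFC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    CLASSIC_1020,
    CorticalMesh,
    FRONTAL_REGIONS,
    HeadModel,
    RegionAtlas,
    SensorLayout,
)
from . import solver as _solver

HD_ELECTRODE_AREA_CM2 = np.pi * 0.6**2  # 1.2 cm diameter disc


class ConfigurationError(ValueError):
    """Missing electrode label or malformed montage definition."""


@dataclass(frozen=True)
class Electrode:
    """One electrode: 10-20 label or explicit unit direction, signed current
    (mA, positive = anode), pad area (cm^2), shape tag."""

    position: str | tuple[float, float, float]
    current_mA: float
    area_cm2: float
    shape: str = "pad"  # pad | hd

    def direction(self, layout: SensorLayout) -> np.ndarray:
        if isinstance(self.position, str):
            if self.position not in layout:
                raise ConfigurationError(
                    f"10-20 label {self.position!r} not present in the sensor layout"
                )
            return layout.direction(self.position)
        d = np.asarray(self.position, dtype=float)
        n = np.linalg.norm(d)
        if not np.isclose(n, 1.0, atol=1e-3):
            raise ConfigurationError("explicit electrode position must be a unit vector")
        return d / n


@dataclass(frozen=True)
class MontageSpec:
    """A named electrode set with a family tag (bipolar or hd_4x1)."""

    id: str
    electrodes: tuple[Electrode, ...]
    family: str
    layout: SensorLayout
    points_per_pad: int = 32

    def __post_init__(self):
        if self.family not in ("bipolar", "hd_4x1"):
            raise ConfigurationError(f"unknown montage family {self.family!r}")
        net = sum(e.current_mA for e in self.electrodes)
        if abs(net) > 1e-12:
            raise ConfigurationError(
                f"montage {self.id!r}: currents sum to {net:.3e} mA, not zero"
            )
        if self.family == "hd_4x1":
            anodes = [e for e in self.electrodes if e.current_mA > 0]
            cathodes = [e for e in self.electrodes if e.current_mA < 0]
            if len(anodes) != 1 or len(cathodes) != 4:
                raise ConfigurationError(
                    f"montage {self.id!r}: a 4x1 ring needs 1 anode + 4 cathodes"
                )

    @property
    def anode_labels(self) -> tuple[str, ...]:
        return tuple(
            e.position for e in self.electrodes
            if e.current_mA > 0 and isinstance(e.position, str)
        )

    def total_anodal_current(self) -> float:
        return sum(e.current_mA for e in self.electrodes if e.current_mA > 0)

    def point_sources(self, head: HeadModel) -> tuple[np.ndarray, np.ndarray]:
        """Discretize every electrode into point sources on the scalp sphere.

        Pads become equivalent-area spherical caps covered by a Fibonacci
        lattice of >= ``points_per_pad`` points sharing the pad current;
        HD electrodes (~1.1 cm^2) are near-points and use a single source.
        """
        R_cm = head.scalp_radius / 10.0
        dirs: list[np.ndarray] = []
        cur: list[float] = []
        for e in self.electrodes:
            centre = e.direction(self.layout)
            if e.shape == "hd":
                dirs.append(centre[None, :])
                cur.append(e.current_mA)
                continue
            npts = max(self.points_per_pad, 1)
            cos_alpha = 1.0 - e.area_cm2 / (2.0 * np.pi * R_cm**2)
            if cos_alpha <= -1.0:
                raise ConfigurationError(
                    f"pad area {e.area_cm2} cm^2 exceeds the scalp sphere"
                )
            pts = _cap_lattice(centre, cos_alpha, npts)
            dirs.append(pts)
            cur.extend([e.current_mA / len(pts)] * len(pts))
        return np.vstack(dirs), np.asarray(cur)


def _cap_lattice(centre: np.ndarray, cos_alpha: float, n: int) -> np.ndarray:
    """Fibonacci lattice covering the spherical cap {x . centre >= cos_alpha}."""
    i = np.arange(n)
    z = 1.0 - (1.0 - cos_alpha) * (2.0 * i + 1.0) / (2.0 * n)
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    return local @ _rotation_to(centre).T


def _rotation_to(target: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to the unit vector ``target``."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(z @ target, -1.0, 1.0))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, target)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def hd_ring(
    layout: SensorLayout,
    anode: str,
    cathodes: tuple[str, str, str, str],
    montage_id: str | None = None,
    anode_current_mA: float = 2.0,
) -> MontageSpec:
    """A 4x1 HD ring: one anode plus four cathodes at -anode/4 each."""
    elecs = [Electrode(anode, anode_current_mA, HD_ELECTRODE_AREA_CM2, "hd")]
    for c in cathodes:
        elecs.append(Electrode(c, -anode_current_mA / 4.0, HD_ELECTRODE_AREA_CM2, "hd"))
    return MontageSpec(
        id=montage_id or f"hd_{anode}",
        electrodes=tuple(elecs),
        family="hd_4x1",
        layout=layout,
    )


def montage_library(layout: SensorLayout, points_per_pad: int = 32) -> list[MontageSpec]:
    """The five fixed montages of the study (the sixth is the optimized ring).

    Bipolar pads carry the areas of the original protocols; the dual-anode
    montage splits its 2 mA total equally between the two DLPFC pads, as a
    single-channel stimulator does across ganged pads.  The right
    supraorbital area (SOA) is taken at Fp2.
    """
    mk = lambda *a, **k: MontageSpec(*a, **k, layout=layout, points_per_pad=points_per_pad)
    lib = [
        # dual anode over both DLPFC, cathode at the inion
        mk(
            "bipolar_F3F4_Iz",
            (
                Electrode("F3", 1.0, 35.0),
                Electrode("F4", 1.0, 35.0),
                Electrode("Iz", -2.0, 35.0),
            ),
            "bipolar",
        ),
        # left DLPFC anode, right DLPFC cathode
        mk(
            "bipolar_F3_F4",
            (Electrode("F3", 2.0, 36.0), Electrode("F4", -2.0, 36.0)),
            "bipolar",
        ),
        # left DLPFC anode, contralateral supraorbital cathode (small/large pads)
        mk(
            "bipolar_F3_SOA24",
            (Electrode("F3", 2.0, 24.0), Electrode("Fp2", -2.0, 100.0)),
            "bipolar",
        ),
        # left DLPFC anode, right supraorbital cathode
        mk(
            "bipolar_F3_SOA35",
            (Electrode("F3", 2.0, 35.0), Electrode("Fp2", -2.0, 35.0)),
            "bipolar",
        ),
        hd_ring(layout, "F3", ("F7", "C3", "Fz", "Fp1"), montage_id="hd_uniform_F3"),
    ]
    return lib


LEFT_ANODE_BIPOLAR = ("bipolar_F3_F4", "bipolar_F3_SOA24", "bipolar_F3_SOA35")
DUAL_ANODE_BIPOLAR = "bipolar_F3F4_Iz"

#: Default anodes of the eight candidate 4x1 rings over the left DLPFC.
CANDIDATE_ANODES = ("F3", "F5", "F1", "FC3", "AF3", "FC5", "F7", "C3")


def nearest_1020_cathodes(
    layout: SensorLayout, anode: str, pool: tuple[str, ...] = CLASSIC_1020
) -> tuple[str, str, str, str]:
    """The four classic 10-20 electrodes nearest (great-circle) to the anode."""
    a = layout.direction(anode)
    cands = [(float(np.arccos(np.clip(a @ layout.direction(p), -1, 1))), p)
             for p in pool if p != anode and p in layout]
    cands.sort()
    return tuple(p for _, p in cands[:4])


def candidate_set(
    layout: SensorLayout, anodes: tuple[str, ...] = CANDIDATE_ANODES
) -> list[MontageSpec]:
    """The eight candidate 4x1 rings: each anode with its four nearest
    classic 10-20 neighbours as cathodes.  For F3 this reproduces the
    uniform ring (F7, C3, Fz, Fp1)."""
    return [hd_ring(layout, a, nearest_1020_cathodes(layout, a)) for a in anodes]


# ---------------------------------------------------------------------------
# Two-rule optimizer
# ---------------------------------------------------------------------------

@dataclass
class CandidateReport:
    """Exhaustive per-candidate record of the optimizer run."""

    table: pd.DataFrame  # one row per candidate
    selected_id: str | None

    def __repr__(self):
        return f"CandidateReport(selected={self.selected_id!r}, n={len(self.table)})"


def _regional_anodal_cathodal(
    field: _solver.FieldSolution, mesh: CorticalMesh, region_mask: np.ndarray
) -> tuple[float, float]:
    """Area-weighted mean of the positive (anodal) and of the negative
    (cathodal) normal-component values within a region.  Returns 0 for an
    absent polarity."""
    nc = field.normal_component[region_mask]
    w = mesh.area_weight[region_mask]
    out = []
    for m in (nc > 0, nc < 0):
        out.append(float(np.average(nc[m], weights=w[m])) if m.any() else 0.0)
    return out[0], out[1]


def optimize_hd_montage(
    head: HeadModel,
    candidates: list[MontageSpec],
    mesh: CorticalMesh,
    atlas: RegionAtlas,
    n_max: int = _solver.DEFAULT_N_MAX,
    statistic: str = "mean",
) -> tuple[MontageSpec | None, CandidateReport]:
    """Select the best 4x1 ring for this head by the two rules.

    Rule 1: over the twenty frontal regions, the one with the highest anodal
    value (``statistic`` = area-weighted mean of positive normal components,
    or ``"peak"`` for the regional maximum) must be the left dlPFC.
    Rule 2: among survivors, maximize mean anodal minus \\|mean cathodal\\|
    normal component in the left dlPFC; ties break by candidate order.

    Returns (selected montage or None, exhaustive report).  No admissible
    candidate is reported, not raised.
    """
    if statistic not in ("mean", "peak"):
        raise ValueError("statistic must be 'mean' or 'peak'")
    for c in candidates:
        if c.family != "hd_4x1":
            raise ConfigurationError(f"candidate {c.id!r} is not a 4x1 ring")
    target = mesh.is_region("dlPFC", "L")
    rows = []
    for cand in candidates:
        fld = _solver.solve_field(head, cand, mesh, n_max=n_max)
        best_region, best_val = None, -np.inf
        for reg in FRONTAL_REGIONS:
            for hemi in ("L", "R"):
                m = mesh.is_region(reg, hemi)
                if not m.any():
                    continue
                if statistic == "mean":
                    a, _ = _regional_anodal_cathodal(fld, mesh, m)
                else:
                    a = float(np.max(fld.normal_component[m], initial=0.0))
                if a > best_val:
                    best_region, best_val = f"{reg}-{hemi}", a
        anodal, cathodal = _regional_anodal_cathodal(fld, mesh, target)
        rows.append(
            {
                "candidate_id": cand.id,
                "anode": cand.anode_labels[0] if cand.anode_labels else "",
                "max_anodal_region": best_region,
                "ldlpfc_mean_anodal": anodal,
                "ldlpfc_mean_cathodal": cathodal,
                "rule1_pass": best_region == "dlPFC-L",
                "rule2_score": anodal - abs(cathodal),
            }
        )
    table = pd.DataFrame(rows)
    table["selected"] = False
    admissible = table.index[table["rule1_pass"]]
    selected = None
    if len(admissible):
        best = admissible[np.argmax(table.loc[admissible, "rule2_score"].to_numpy())]
        table.loc[best, "selected"] = True
        selected = candidates[int(best)]
    return selected, CandidateReport(table=table, selected_id=selected.id if selected else None)
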
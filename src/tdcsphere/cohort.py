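"""Synthetic cohorts: atrophic ("AD") and normal ("control") head models.

Two generators are provided.  The geometry-based generator draws
per-subject cortical thickness from group-specific normal distributions
(AD 2.26 +/- 0.12 mm, control 2.41 +/- 0.10 mm), maps thickness to the
gray-matter shell (reference 2.41 mm <-> 8 mm shell), and holds the CSF
outer radius fixed so cortical thinning becomes CSF expansion.  Because a
smooth sphere has none of the local geometry of folded cortex, each subject
also carries two stand-ins for anatomical irregularity whose amplitude is
larger in the atrophic group: a smooth random perturbation of the cortical
sampling radius (widened sulci sample the field at more variable depths)
and a random dispersion of the cortical surface normals (greater
orientation variability of the atrophic cortical sheet).  These drive the
within-region field variability that real atrophy produces.

The statistical generator draws metric tables directly from a known
hierarchical linear model, for validating the inference engine against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation as SpRotation

from . import inference as _inf
from .geometry import (
    CorticalMesh,
    RegionAtlas,
    HeadModel,
    REFERENCE_CORTICAL_THICKNESS_MM,
    REFERENCE_GM_SHELL_MM,
    build_atlas,
    build_head_model,
    fibonacci_sphere,
    layout_1020,
)
from .metrics import focality_table, region_summary
from .montages import MontageSpec, candidate_set, montage_library, optimize_hd_montage
from .solver import solve_field


@dataclass(frozen=True)
class CohortParams:
    """Generative settings for the two-group head-model cohort."""

    n_per_group: int = 24
    control_thickness_mm: float = 2.41
    control_thickness_sd: float = 0.10
    ad_thickness_mm: float = 2.26
    ad_thickness_sd: float = 0.12
    #: SD (mm) of the per-subject jitter applied to the WM outer radius
    #: (control group; AD scaled by ``ad_variability_factor``).  Skull and
    #: scalp are held identical across subjects: the cohorts are matched,
    #: and fixing the outer shells isolates the GM/CSF effects of atrophy.
    radius_jitter_sd_mm: float = 0.35
    #: SD (mm) of the smooth cortical sampling-radius roughness field.
    roughness_amp_mm: float = 0.30
    #: Scale (deg) of the random tilt of cortical surface normals.
    normal_dispersion_deg: float = 14.0
    #: SD (deg) of the per-subject rigid rotation of the cortical
    #: parcellation relative to the scalp electrodes.  Scalp-landmark
    #: targeting of the DLPFC misses the individual anatomical target by
    #: roughly 1-2 cm, which is 8-15 deg on an adult head; 8 deg SD for
    #: controls (atrophic group scaled by ``ad_variability_factor``).
    atlas_rotation_sd_deg: float = 8.0
    #: AD anatomical-variability multiplier on jitter, roughness, dispersion.
    ad_variability_factor: float = 1.5
    seed: int = 0
    max_redraws: int = 100

    def __post_init__(self):
        for a in ("control_thickness_mm", "control_thickness_sd",
                  "ad_thickness_mm", "ad_thickness_sd"):
            if not getattr(self, a) > 0:
                raise ValueError(f"{a} must be > 0")


@dataclass(frozen=True)
class Subject:
    """One synthetic subject: head geometry plus irregularity settings."""

    head: HeadModel
    cortical_thickness_mm: float
    roughness_amp_mm: float
    normal_dispersion_deg: float
    mesh_seed: int
    #: Rodrigues vector (axis * angle, radians) rotating this subject's
    #: cortical parcellation relative to the scalp electrodes.
    atlas_rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def subject_id(self) -> str:
        return self.head.subject_id

    @property
    def group(self) -> str:
        return self.head.group


def _thickness_to_shell(thickness_mm: float) -> float:
    return REFERENCE_GM_SHELL_MM * thickness_mm / REFERENCE_CORTICAL_THICKNESS_MM


def generate_cohort(params: CohortParams) -> list[Subject]:
    """Draw the two-group cohort; deterministic given ``params.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    base = build_head_model()
    subjects: list[Subject] = []
    groups = [
        ("control", params.control_thickness_mm, params.control_thickness_sd, 1.0),
        ("AD", params.ad_thickness_mm, params.ad_thickness_sd, params.ad_variability_factor),
    ]
    for group, mu, sd, vf in groups:
        for i in range(params.n_per_group):
            th = -1.0
            for _ in range(params.max_redraws):
                th = rng.normal(mu, sd)
                if th > 0.5:  # physically sensible cortical thickness
                    break
            else:
                raise RuntimeError("exceeded redraw budget for cortical thickness")
            head = base.with_gm_thickness(_thickness_to_shell(th))
            # jitter the WM outer radius, preserving nesting; CSF outer,
            # skull and scalp radii stay fixed across the whole cohort
            jit = float(np.clip(rng.normal(0.0, params.radius_jitter_sd_mm * vf), -2, 2))
            radii = {"wm": head.radius("wm") + jit}
            radii["gm"] = radii["wm"] + _thickness_to_shell(th)
            head = build_head_model(
                radii=radii,
                conductivities={s.name: s.conductivity for s in head.shells},
                subject_id=f"{group}{i + 1:02d}",
                group=group,
            )
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = abs(rng.normal(0.0, np.deg2rad(params.atlas_rotation_sd_deg * vf)))
            subjects.append(
                Subject(
                    head=head,
                    cortical_thickness_mm=float(th),
                    roughness_amp_mm=params.roughness_amp_mm * vf,
                    normal_dispersion_deg=params.normal_dispersion_deg * vf,
                    mesh_seed=int(rng.integers(2**31 - 1)),
                    atlas_rotation=tuple(axis * angle),
                )
            )
    return subjects


def _roughness_field(
    nodes: np.ndarray, rng: np.random.Generator, n_bumps: int = 150, width_deg: float = 9.0
) -> np.ndarray:
    """Smooth zero-mean random field on the sphere, unit SD across nodes.

    The correlation length (bump width ~9 deg, about 1.2 cm on the cortical
    sphere) matches the spacing of cortical sulci, so the field perturbs
    sampling depth locally without shifting whole-region averages much.
    """
    centres = fibonacci_sphere(n_bumps)
    amp = rng.normal(size=n_bumps)
    ang = np.arccos(np.clip(nodes @ centres.T, -1.0, 1.0))
    g = np.exp(-(ang**2) / (2.0 * np.deg2rad(width_deg) ** 2))
    f = g @ amp
    s = f.std()
    return f / s if s > 0 else f


def subject_mesh(
    subject: Subject,
    base_mesh: CorticalMesh,
    atlas: "RegionAtlas | None" = None,
) -> CorticalMesh:
    """Per-subject sampling mesh: the canonical lattice with the subject's
    mid-GM radius, a smooth radius roughness field (clipped to stay inside
    the GM shell), and normals tilted by \\|N(0, dispersion)\\| about random
    tangent axes.  When an atlas is given, region labels are recomputed
    under the subject's parcellation rotation (cortex vs. scalp-electrode
    registration variability).  Deterministic given the subject's mesh seed.
    """
    rng = np.random.default_rng(subject.mesh_seed)
    head = subject.head
    nodes = base_mesh.nodes
    r_mid = head.mid_gm_radius
    r = r_mid + subject.roughness_amp_mm * _roughness_field(nodes, rng)
    margin = 0.3
    r = np.clip(r, head.radius("wm") + margin, head.radius("gm") - margin)
    ang = np.abs(rng.normal(0.0, np.deg2rad(subject.normal_dispersion_deg), len(nodes)))
    raw = rng.normal(size=nodes.shape)
    tan = raw - np.einsum("ij,ij->i", raw, nodes)[:, None] * nodes
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    normals = np.cos(ang)[:, None] * (-nodes) + np.sin(ang)[:, None] * tan
    region, hemi = base_mesh.region, base_mesh.hemisphere
    rot = np.asarray(subject.atlas_rotation)
    if atlas is not None and np.linalg.norm(rot) > 0:
        R = SpRotation.from_rotvec(rot).as_matrix()
        region, hemi = atlas.label_nodes(nodes @ R)  # nodes in the atlas frame
    return CorticalMesh(
        nodes=nodes,
        radii=r,
        inward_normal=normals,
        region=region,
        hemisphere=hemi,
        area_weight=np.full(len(nodes), 4.0 * np.pi * r_mid**2 / len(nodes)),
    )


@dataclass
class CohortDataset:
    """End-to-end simulation output: long-format metrics, focality, reports."""

    metrics: pd.DataFrame
    focality: pd.DataFrame
    optimizer_reports: dict[str, pd.DataFrame]
    selected_montage: dict[str, str | None]


def simulate_cohort_dataset(
    cohort: list[Subject],
    montages: list[MontageSpec] | None = None,
    n_nodes: int = 2000,
    n_max: int = 80,
    include_optimized: bool = False,
    points_per_pad: int = 32,
) -> CohortDataset:
    """Solve every subject x montage and tabulate the four indices.

    With ``include_optimized`` the per-subject two-rule optimizer runs over
    the standard candidate set and its winner is added under the montage id
    ``hd_optimized``.  Output has one row per subject x montage x frontal
    region x hemisphere; a solver failure aborts with the subject id.
    """
    if not cohort:
        raise ValueError("empty cohort")
    ref_head = cohort[0].head
    layout = layout_1020(ref_head)
    if montages is None:
        montages = montage_library(layout, points_per_pad=points_per_pad)
    atlas, base_mesh = build_atlas(ref_head, n_nodes=n_nodes)
    cands = candidate_set(layout) if include_optimized else None
    metric_frames, focality_frames = [], []
    reports: dict[str, pd.DataFrame] = {}
    chosen: dict[str, str | None] = {}
    for subj in cohort:
        mesh = subject_mesh(subj, base_mesh, atlas=atlas)
        todo = list(montages)
        opt_ids: dict[str, str] = {}
        if include_optimized:
            sel, rep = optimize_hd_montage(subj.head, cands, mesh, atlas, n_max=n_max)
            reports[subj.subject_id] = rep.table
            chosen[subj.subject_id] = rep.selected_id
            if sel is not None:
                todo.append(sel)
                opt_ids[sel.id] = "hd_optimized"
        fields = []
        for mont in todo:
            try:
                fld = solve_field(subj.head, mont, mesh, n_max=n_max)
            except Exception as exc:
                raise RuntimeError(
                    f"solver failed for subject {subj.subject_id}, "
                    f"montage {mont.id}: {exc}"
                ) from exc
            if mont.id in opt_ids:
                fld.montage_id = opt_ids[mont.id]
            fields.append(fld)
            metric_frames.append(region_summary(fld, mesh, group=subj.group))
        focality_frames.append(focality_table(fields, mesh))
    return CohortDataset(
        metrics=pd.concat(metric_frames, ignore_index=True),
        focality=pd.concat(focality_frames, ignore_index=True),
        optimizer_reports=reports,
        selected_montage=chosen,
    )


# ---------------------------------------------------------------------------
# Known-truth statistical simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthSpec:
    """Ground-truth hierarchical linear model for recovery experiments.

    ``levels`` maps factor name -> level tuple; ``coefficients`` maps
    design-column names (as produced by :func:`tdcsphere.inference.design_matrix`
    for the full interaction model over these factors, e.g. ``"group[AD]"``
    or ``"region[dlPFC]:group[AD]"``) to values; unnamed columns are zero.
    """

    levels: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "region": ("ACC", "dlPFC", "mPFC"),
            "hemisphere": ("L", "R"),
            "montage": ("bipolar_F3_F4", "hd_uniform_F3"),
            "group": ("control", "AD"),
        }
    )
    intercept: float = 0.15
    coefficients: dict[str, float] = field(default_factory=dict)
    random_intercept_sd: float = 0.01
    residual_sd: float = 0.02

    def __post_init__(self):
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("SDs must be >= 0")


def simulate_regression_dataset(
    truth: TruthSpec,
    n_subjects: int = 24,
    seed: int = 0,
    response: str = "mean_normal",
) -> pd.DataFrame:
    """Balanced long-format table drawn from the ground-truth model.

    Subjects alternate between the two group levels; every subject
    contributes one row per region x hemisphere x montage cell.
    """
    rng = np.random.default_rng(seed)
    glevels = truth.levels.get("group", ("control", "AD"))
    rows = []
    for s in range(n_subjects):
        grp = glevels[s % len(glevels)]
        for reg in truth.levels["region"]:
            for hemi in truth.levels["hemisphere"]:
                for mont in truth.levels["montage"]:
                    rows.append(
                        {
                            "subject": f"S{s + 1:03d}",
                            "group": grp,
                            "montage": mont,
                            "region": reg,
                            "hemisphere": hemi,
                        }
                    )
    data = pd.DataFrame(rows)
    spec = _inf.ModelSpec(response, tuple(truth.levels))
    X, names = _inf.design_matrix(data, spec)
    beta = np.zeros(len(names))
    beta[0] = truth.intercept
    for nm, val in truth.coefficients.items():
        if nm not in names:
            raise ValueError(
                f"unknown coefficient {nm!r}; valid names include e.g. {names[1:4]}"
            )
        beta[names.index(nm)] = val
    b = rng.normal(0.0, truth.random_intercept_sd, n_subjects)
    subj_idx = data["subject"].str.slice(1).astype(int).to_numpy() - 1
    y = X @ beta + b[subj_idx] + rng.normal(0.0, truth.residual_sd, len(data))
    data[response] = y
    return data
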
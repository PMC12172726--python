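"""Region-wise field summaries: means/SDs, coefficient of variation, focality.

Four indices are extracted from a solved field, per frontal region and
hemisphere: (1) mean and SD of the field strength \\|E\\| ("normfield");
(2) mean and SD of the normal component E . n_inward (positive = anodal,
current entering the cortex); (3) a target focality index, the share of
top-1% "hotspot" nodes falling in the left dlPFC; (4) the coefficient of
variation, 100 x SD(normal component) / mean(normfield).  Raw field values
are used throughout, without normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .geometry import CorticalMesh, FRONTAL_REGIONS
from .solver import FieldSolution

#: Long-format schema consumed by the statistics stage.
COHORT_TABLE_COLUMNS = (
    "subject", "group", "montage", "region", "hemisphere",
    "mean_normfield", "sd_normfield", "mean_normal", "sd_normal", "cv", "n_nodes",
)


def _weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    mean = float(np.average(values, weights=weights))
    var = float(np.average((values - mean) ** 2, weights=weights))
    return mean, float(np.sqrt(max(var, 0.0)))


def coefficient_of_variation(sd_normal: float, mean_normfield: float) -> float:
    """100 x SD(normal component) / mean(normfield); NaN when the mean
    field strength vanishes."""
    if not mean_normfield > 0:
        return float("nan")
    return 100.0 * sd_normal / mean_normfield


def region_summary(
    field: FieldSolution,
    mesh: CorticalMesh,
    group: str = "none",
    area_weighted: bool = True,
) -> pd.DataFrame:
    """Per-region x hemisphere summary of one solved field (20 frontal rows).

    Empty regions yield a row with ``n_nodes`` 0 and NaN statistics rather
    than being silently dropped.
    """
    rows = []
    for reg in FRONTAL_REGIONS:
        for hemi in ("L", "R"):
            m = mesh.is_region(reg, hemi)
            n = int(m.sum())
            if n == 0:
                stats = dict.fromkeys(
                    ("mean_normfield", "sd_normfield", "mean_normal", "sd_normal", "cv"),
                    float("nan"),
                )
            else:
                w = mesh.area_weight[m] if area_weighted else np.ones(n)
                mnf, snf = _weighted_mean_sd(field.normfield[m], w)
                mnc, snc = _weighted_mean_sd(field.normal_component[m], w)
                stats = {
                    "mean_normfield": mnf,
                    "sd_normfield": snf,
                    "mean_normal": mnc,
                    "sd_normal": snc,
                    "cv": coefficient_of_variation(snc, mnf),
                }
            rows.append(
                {
                    "subject": field.subject_id,
                    "group": group,
                    "montage": field.montage_id,
                    "region": reg,
                    "hemisphere": hemi,
                    **stats,
                    "n_nodes": n,
                }
            )
    return pd.DataFrame(rows, columns=COHORT_TABLE_COLUMNS)


@dataclass(frozen=True)
class FocalityResult:
    montage_id: str
    subject_id: str
    polarity: str
    fraction: float
    index: float  # percent of hotspot nodes inside the left dlPFC


def focality_index(
    field: FieldSolution,
    mesh: CorticalMesh,
    polarity: str = "anodal",
    fraction: float = 0.01,
) -> FocalityResult:
    """Share (percent) of hotspot nodes lying in the left dlPFC.

    Hotspots are the ceil(fraction x N) nodes with the largest normal
    component (anodal) or the most negative one (cathodal), over the whole
    cortex (all mesh nodes).  Node counts, not area weights, are used: the
    index is a node proportion.  Value ties break by node index.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if polarity not in ("anodal", "cathodal"):
        raise ValueError("polarity must be 'anodal' or 'cathodal'")
    nc = field.normal_component
    n_hot = ceil(fraction * len(nc))
    key = -nc if polarity == "anodal" else nc
    # stable sort on (value, node index): deterministic under ties
    order = np.argsort(key, kind="stable")
    hot = order[:n_hot]
    in_target = mesh.is_region("dlPFC", "L")[hot].sum()
    return FocalityResult(
        montage_id=field.montage_id,
        subject_id=field.subject_id,
        polarity=polarity,
        fraction=fraction,
        index=100.0 * float(in_target) / n_hot,
    )


def focality_table(
    fields: list[FieldSolution], mesh: CorticalMesh, fraction: float = 0.01
) -> pd.DataFrame:
    """Anodal and cathodal focality for a list of solved fields."""
    rows = [
        focality_index(f, mesh, pol, fraction)
        for f in fields
        for pol in ("anodal", "cathodal")
    ]
    return pd.DataFrame(
        {
            "subject": [r.subject_id for r in rows],
            "montage": [r.montage_id for r in rows],
            "polarity": [r.polarity for r in rows],
            "index": [r.index for r in rows],
        }
    )
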
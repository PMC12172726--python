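"""Quasi-static electric field of scalp current sources on a multi-shell sphere.

At DC the potential solves Laplace's equation inside each conductive shell,
so for a point current source on the scalp the potential is a Legendre
series V(r, gamma) = sum_n R_n(r) P_n(cos gamma), with gamma the angle from
the source axis.  Within shell j the radial factor is
A_j (r/R)^n + B_j (R/r)^(n+1); the coefficients follow from continuity of V
and of the radial current density sigma dV/dr at every interface, regularity
at the origin, and the injected current at the outer boundary.  The n = 0
term is absent: electrode montages are current-conserving, and every montage
is solved by superposition of its (zero-sum) point sources.

Units: radii mm, currents mA, conductivities S/m.  Because 1 mA / 1 mm
equals 1 A / 1 m, potentials come out in volts and fields in V/mm; fields
are scaled to V/m on output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CorticalMesh, HeadModel

V_PER_MM_TO_V_PER_M = 1000.0

DEFAULT_N_MAX = 80


class SolverError(RuntimeError):
    """Numerical failure in the series solution."""


class MontageError(ValueError):
    """Montage violates current conservation or electrode placement rules."""


@dataclass
class SeriesSolution:
    """Legendre-series coefficients of one point source on the scalp.

    ``A``/``B`` have shape (n_shells, n_max) and hold the radial-factor
    coefficients per shell for harmonic orders n = 1..n_max, already scaled
    to the injected current.
    """

    A: np.ndarray
    B: np.ndarray
    source_dir: np.ndarray
    current_mA: float
    head: HeadModel

    @property
    def n_max(self) -> int:
        return self.A.shape[1]

    def _shell_index(self, r: float) -> int:
        radii = self.head.radii()
        idx = int(np.searchsorted(radii, r, side="left"))
        if idx >= len(radii):
            raise ValueError(f"radius {r} outside the head (scalp {radii[-1]})")
        return idx

    def radial_factors(self, r: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """R_n(r) and R_n'(r) for all orders; r scalar or (m,) inside one shell
        per entry.  Returns arrays of shape (m, n_max)."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        R = self.head.scalp_radius
        ns = np.arange(1, self.n_max + 1, dtype=float)
        Rn = np.empty((len(r), self.n_max))
        Rpn = np.empty_like(Rn)
        shell_idx = np.array([self._shell_index(ri) for ri in r])
        for j in np.unique(shell_idx):
            m = shell_idx == j
            t = (r[m, None] / R)
            tp = t**ns
            tm = t ** (-(ns + 1.0))
            Rn[m] = self.A[j] * tp + self.B[j] * tm
            Rpn[m] = (self.A[j] * ns * tp - self.B[j] * (ns + 1.0) * tm) / r[m, None]
        return Rn, Rpn

    def potential(self, points: np.ndarray) -> np.ndarray:
        """Potential (V) at Cartesian points (m, 3) inside the head."""
        points = np.atleast_2d(points)
        r = np.linalg.norm(points, axis=1)
        x = (points / r[:, None]) @ self.source_dir
        Rn, _ = self.radial_factors(r)
        return _legendre_series(x, Rn)


def point_source_series(
    head: HeadModel,
    source_dir: np.ndarray,
    current_mA: float,
    n_max: int = DEFAULT_N_MAX,
) -> SeriesSolution:
    """Solve the shell transfer matrices for a unit point source on the scalp.

    The source sits at ``source_dir`` (unit vector) on the scalp surface and
    injects ``current_mA``; the rest of the scalp is insulating.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    d = np.asarray(source_dir, dtype=float)
    nrm = np.linalg.norm(d)
    if not np.isclose(nrm, 1.0, atol=1e-6):
        d = d / nrm
    radii = head.radii()
    sig = head.conductivities()
    R = radii[-1]
    ns = np.arange(1, n_max + 1, dtype=float)
    nsh = len(radii)
    A = np.zeros((nsh, n_max))
    B = np.zeros((nsh, n_max))
    A[0] = 1.0  # B[0] = 0: regular at the origin
    for j in range(nsh - 1):
        x = radii[j] / R
        s1, s2 = sig[j], sig[j + 1]
        xp = x**ns
        xm = x ** (-(ns + 1.0))
        v = A[j] * xp + B[j] * xm
        f = s1 * (ns * A[j] * xp - (ns + 1.0) * B[j] * xm) / radii[j]
        a11, a12 = xp, xm
        a21 = s2 * ns * xp / radii[j]
        a22 = -s2 * (ns + 1.0) * xm / radii[j]
        det = a11 * a22 - a12 * a21
        A[j + 1] = (v * a22 - a12 * f) / det
        B[j + 1] = (a11 * f - v * a21) / det
    # outer boundary: sigma_N dV/dr|_R = I (2n+1) / (4 pi R^2) per order
    denom = sig[-1] * (ns * A[-1] - (ns + 1.0) * B[-1]) / R
    if not np.all(np.isfinite(denom)) or np.any(denom == 0):
        raise SolverError(
            "degenerate transfer-matrix solution; conductivity ratios too extreme"
        )
    g = current_mA * (2.0 * ns + 1.0) / (4.0 * np.pi * R**2)
    c = g / denom
    A *= c
    B *= c
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise SolverError("non-finite series coefficients")
    return SeriesSolution(A=A, B=B, source_dir=d, current_mA=current_mA, head=head)


def _legendre_series(x: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """sum_n coef[:, n-1] * P_n(x) by upward recurrence (coef may be (m, N))."""
    x = np.asarray(x, dtype=float)
    P_nm1 = np.ones_like(x)
    P_n = x.copy()
    out = np.zeros_like(x)
    N = coef.shape[-1]
    for n in range(1, N + 1):
        out += coef[..., n - 1] * P_n
        P_np1 = ((2 * n + 1) * x * P_n - n * P_nm1) / (n + 1)
        P_nm1, P_n = P_n, P_np1
    return out


def _accumulate_field(
    nodes: np.ndarray,
    src_dir: np.ndarray,
    Rn: np.ndarray,
    Rpn: np.ndarray,
    radii: np.ndarray,
    E_out: np.ndarray,
) -> None:
    """Add the E field (V/mm) of one source to E_out, evaluated at unit node
    directions ``nodes`` with per-node sampling radii."""
    x = nodes @ src_dir
    m = len(x)
    P_nm1 = np.ones(m)
    P_n = x.copy()
    dP_nm1 = np.zeros(m)
    dP_n = np.ones(m)
    Sr = np.zeros(m)
    St = np.zeros(m)
    n_max = Rn.shape[1]
    for n in range(1, n_max + 1):
        Sr += Rpn[:, n - 1] * P_n
        St += Rn[:, n - 1] * dP_n
        P_np1 = ((2 * n + 1) * x * P_n - n * P_nm1) / (n + 1)
        dP_np1 = dP_nm1 + (2 * n + 1) * P_n
        P_nm1, P_n = P_n, P_np1
        dP_nm1, dP_n = dP_n, dP_np1
    # E = -grad V = -R' P_n r_hat + (1/r) sum R_n P_n'(x) (x r_hat - d_hat)
    E_out -= Sr[:, None] * nodes
    tang = St / radii
    E_out += tang[:, None] * (x[:, None] * nodes - src_dir[None, :])


@dataclass
class FieldSolution:
    """Electric field sampled at the mesh nodes for one subject x montage.

    ``E`` (m, 3) in V/m; ``normfield`` = \\|E\\|; ``normal_component`` =
    E . n_inward (positive = current entering the cortex, the anodal
    convention).
    """

    E: np.ndarray
    normfield: np.ndarray
    normal_component: np.ndarray
    montage_id: str
    subject_id: str

    def to_frame(self, mesh: CorticalMesh) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": np.arange(len(self.E)),
                "region": mesh.region,
                "hemisphere": mesh.hemisphere,
                "Ex": self.E[:, 0],
                "Ey": self.E[:, 1],
                "Ez": self.E[:, 2],
                "normfield": self.normfield,
                "normal_component": self.normal_component,
            }
        )


def solve_field(
    head: HeadModel,
    montage,
    mesh: CorticalMesh,
    n_max: int = DEFAULT_N_MAX,
) -> FieldSolution:
    """Field of a montage at the mesh nodes, by superposition of its
    discretized point sources.

    ``montage`` is a MontageSpec (see :mod:`tdcsphere.montages`); its pads
    are discretized into point sources on the scalp sphere.  Net current
    must vanish (Kirchhoff).
    """
    dirs, currents = montage.point_sources(head)
    total = float(np.sum(currents))
    if abs(total) > 1e-9:
        raise MontageError(
            f"montage {montage.id!r}: net current {total:.3e} mA is not zero"
        )
    E = np.zeros((mesh.n_nodes, 3))
    # the radial factors are direction-independent and linear in the
    # current, so solve once per head for unit current and scale per source
    unit = point_source_series(head, np.array([0.0, 0.0, 1.0]), 1.0, n_max=n_max)
    Rn_u, Rpn_u = unit.radial_factors(mesh.radii)
    for d, cur in zip(dirs, currents):
        dE = np.zeros_like(E)
        _accumulate_field(mesh.nodes, d, Rn_u, Rpn_u, mesh.radii, dE)
        E += float(cur) * dE
    E *= V_PER_MM_TO_V_PER_M
    normfield = np.linalg.norm(E, axis=1)
    normal = np.einsum("ij,ij->i", E, mesh.inward_normal)
    return FieldSolution(
        E=E,
        normfield=normfield,
        normal_component=normal,
        montage_id=montage.id,
        subject_id=head.subject_id,
    )
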
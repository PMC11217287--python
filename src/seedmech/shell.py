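"""Membrane stress on a pressurized closed shell.

The seed coat at early stages behaves as a thin pressurized shell: the
endosperm pushes on the coat, and the resulting in-plane (membrane) tension
pattern is set almost entirely by the organ's shape — a generalized Laplace
law.  This module solves the small-strain linear membrane problem on a
triangulated closed surface under uniform internal pressure and reports
per-cell principal stresses, principal-stress axes and a stress-anisotropy
scalar, together with closed-form spheroid oracles used for validation.

Because a closed convex membrane is statically determinate to leading
order, the computed stress directions and anisotropy are insensitive to the
elastic constants; only pressure, thickness and geometry matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .mesh import CellTessellation, EllipsoidSpec, SurfaceMesh, TopologyError

__all__ = [
    "ShellMaterial",
    "StressField",
    "RegionLabels",
    "inflate_shell",
    "solve_membrane_stress",
    "spheroid_stress_oracle",
    "classify_regions",
    "field_summary",
    "ConditioningError",
    "InconsistencyError",
    "CoverageError",
]


class ConditioningError(RuntimeError):
    """Raised when the constrained membrane system is numerically singular."""


class InconsistencyError(ValueError):
    """Raised when a mesh/tessellation does not match the stated ellipsoid."""


class CoverageError(ValueError):
    """Raised when region labels do not cover a field's cells."""


@dataclass(frozen=True)
class ShellMaterial:
    """Elastic shell parameters.

    young_modulus : MPa.  poisson_ratio : dimensionless, in [0, 0.5).
    thickness : wall thickness t in µm.  pressure : internal pressure p in
    MPa.  Stress outputs scale as p and 1/t; the elastic constants only set
    displacements, not the (statically determinate) stress pattern.
    """

    young_modulus: float = 100.0
    poisson_ratio: float = 0.3
    thickness: float = 1.0
    pressure: float = 0.2

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("young_modulus must be > 0")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if self.pressure <= 0:
            raise ValueError("pressure must be > 0")


@dataclass
class StressField:
    """Per-cell (or per-face) principal membrane stresses and axes.

    ``sigma1 >= sigma2`` (MPa); ``axis1``/``axis2`` are orthonormal tangent
    unit 3-vectors; ``anisotropy = (σ1−σ2)/(σ1+σ2)`` where σ1+σ2 > 0.
    """

    cell_ids: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    axis1: np.ndarray
    axis2: np.ndarray
    anisotropy: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "s1": self.sigma1,
                "s2": self.sigma2,
                "anisotropy": self.anisotropy,
                "axis1_x": self.axis1[:, 0],
                "axis1_y": self.axis1[:, 1],
                "axis1_z": self.axis1[:, 2],
                "axis2_x": self.axis2[:, 0],
                "axis2_y": self.axis2[:, 1],
                "axis2_z": self.axis2[:, 2],
            }
        )


@dataclass
class RegionLabels:
    """Per-cell region label: ``flat_face``, ``flank`` or ``tip``."""

    cell_ids: np.ndarray
    labels: np.ndarray

    REGIONS = ("flat_face", "flank", "tip")

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cell_ids, name="region")


def _tangent_basis(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent pairs (e1, e2) for an array of unit normals."""
    n = np.atleast_2d(normals)
    # seed with the global axis least aligned with each normal
    seed = np.zeros_like(n)
    seed[np.arange(len(n)), np.argmin(np.abs(n), axis=1)] = 1.0
    e1 = np.cross(n, seed)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(n, e1)
    return e1, e2


def solve_membrane_stress(
    mesh: SurfaceMesh,
    material: ShellMaterial,
    tess: Optional[CellTessellation] = None,
) -> StressField:
    """Linear membrane finite-element solve under uniform internal pressure.

    Constant-strain triangles in plane stress carry the in-plane stiffness;
    the pressure acts as a dead load along the outward face normals on the
    undeformed mesh.  Rigid-body modes are removed with six Lagrange
    constraints (zero mean translation and rotation) — the load on a closed
    surface is self-equilibrated, so the constraint choice only fixes the
    rigid motion and leaves stresses unchanged.

    With ``tess`` given, per-face stress tensors are area-averaged within
    each cell before eigen-decomposition; otherwise the field is per-face.
    """
    mesh.require_closed()
    V, F = mesh.vertices, mesh.faces
    nv, nf = mesh.n_vertices, mesh.n_faces
    E_mod, nu = material.young_modulus, material.poisson_ratio
    t, p = material.thickness, material.pressure

    normals = mesh.face_normals
    v0, v1, v2 = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    d1, d2 = v1 - v0, v2 - v0
    e1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
    e2 = np.cross(normals, e1)

    # local node coordinates: (0,0), (x2,0), (x3,y3)
    x2 = np.einsum("ij,ij->i", d1, e1)
    x3 = np.einsum("ij,ij->i", d2, e1)
    y3 = np.einsum("ij,ij->i", d2, e2)
    area = 0.5 * x2 * y3
    if np.any(area <= 0):
        raise TopologyError("degenerate (zero-area) face in mesh")

    # CST strain-displacement matrix B (3 x 6) per face
    b = np.stack([-y3, y3, np.zeros(nf)], axis=1)
    c = np.stack([x3 - x2, -x3, x2], axis=1)
    B = np.zeros((nf, 3, 6))
    inv2A = 1.0 / (2.0 * area)
    for i in range(3):
        B[:, 0, 2 * i] = b[:, i] * inv2A
        B[:, 1, 2 * i + 1] = c[:, i] * inv2A
        B[:, 2, 2 * i] = c[:, i] * inv2A
        B[:, 2, 2 * i + 1] = b[:, i] * inv2A

    D = (E_mod / (1 - nu**2)) * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1 - nu) / 2.0]]
    )

    # k_local = t * A * B^T D B  (6 x 6)
    k_loc = t * area[:, None, None] * np.einsum("fji,jk,fkl->fil", B, D, B)

    # T (6 x 9): local in-plane displacement of each node from global dofs
    T = np.zeros((nf, 6, 9))
    for i in range(3):
        T[:, 2 * i, 3 * i : 3 * i + 3] = e1
        T[:, 2 * i + 1, 3 * i : 3 * i + 3] = e2
    k_glob = np.einsum("fji,fjk,fkl->fil", T, k_loc, T)  # (f, 9, 9)

    dof = (3 * F[:, :, None] + np.arange(3)[None, None, :]).reshape(nf, 9)
    rows = np.repeat(dof, 9, axis=1).ravel()
    cols = np.tile(dof, (1, 9)).ravel()
    K = sparse.coo_matrix((k_glob.ravel(), (rows, cols)), shape=(3 * nv, 3 * nv)).tocsr()

    # dead pressure load, lumped to vertices
    fload = np.zeros((nv, 3))
    contrib = (p * area / 3.0)[:, None] * normals
    for i in range(3):
        np.add.at(fload, F[:, i], contrib)
    f = fload.ravel()

    # six rigid-body constraints via Lagrange multipliers
    r = V - V.mean(axis=0)
    G = np.zeros((6, 3 * nv))
    for k in range(3):
        G[k, k::3] = 1.0
    G[3, 1::3], G[3, 2::3] = -r[:, 2], r[:, 1]
    G[4, 0::3], G[4, 2::3] = r[:, 2], -r[:, 0]
    G[5, 0::3], G[5, 1::3] = -r[:, 1], r[:, 0]
    scale = K.diagonal().mean()
    Gs = sparse.csr_matrix(G * scale / np.abs(G).sum(axis=1, keepdims=True))

    A_aug = sparse.bmat([[K, Gs.T], [Gs, None]], format="csc")
    rhs = np.concatenate([f, np.zeros(6)])
    with np.errstate(all="ignore"):
        sol = spsolve(A_aug, rhs)
    if not np.all(np.isfinite(sol)):
        raise ConditioningError("singular membrane system after constraints")
    u = sol[: 3 * nv]

    # per-face stress in the local frame, then as a global 3x3 tensor
    u_e = u.reshape(nv, 3)[F].reshape(nf, 9)
    u_loc = np.einsum("fij,fj->fi", T, u_e)
    eps = np.einsum("fij,fj->fi", B, u_loc)
    sig = eps @ D.T  # (f, 3): s11, s22, s12 in local frame
    frame = np.stack([e1, e2], axis=2)  # (f, 3, 2)
    s2 = np.empty((nf, 2, 2))
    s2[:, 0, 0], s2[:, 1, 1] = sig[:, 0], sig[:, 1]
    s2[:, 0, 1] = s2[:, 1, 0] = sig[:, 2]
    sig3 = np.einsum("fik,fkl,fjl->fij", frame, s2, frame)  # (f, 3, 3)

    if tess is None:
        ids = np.arange(nf)
        agg_normals = normals
        agg_sig = sig3
    else:
        if tess.mesh is not mesh and tess.mesh.n_faces != nf:
            raise InconsistencyError("tessellation does not match the mesh")
        ids = tess.cell_ids
        idx = np.searchsorted(ids, tess.face_cell)
        w = mesh.face_areas
        agg_sig = np.zeros((len(ids), 3, 3))
        for i in range(3):
            for j in range(3):
                agg_sig[:, i, j] = np.bincount(
                    idx, weights=sig3[:, i, j] * w, minlength=len(ids)
                )
        agg_sig /= tess.cell_areas[:, None, None]
        agg_normals = tess.cell_normals

    return _principal_stress(ids, agg_sig, agg_normals)


def _principal_stress(ids: np.ndarray, sig3: np.ndarray, normals: np.ndarray) -> StressField:
    """Project 3x3 tensors to each tangent plane and eigen-decompose."""
    t1, t2 = _tangent_basis(normals)
    frame = np.stack([t1, t2], axis=2)
    M = np.einsum("fki,fkl,flj->fij", frame, sig3, frame)  # (n, 2, 2) symmetric
    M = 0.5 * (M + np.swapaxes(M, 1, 2))
    evals, evecs = np.linalg.eigh(M)  # ascending
    s1, s2v = evals[:, 1], evals[:, 0]
    a1_2d, a2_2d = evecs[:, :, 1], evecs[:, :, 0]
    axis1 = a1_2d[:, :1] * t1 + a1_2d[:, 1:] * t2
    axis2 = a2_2d[:, :1] * t1 + a2_2d[:, 1:] * t2
    axis1 /= np.linalg.norm(axis1, axis=1, keepdims=True)
    axis2 /= np.linalg.norm(axis2, axis=1, keepdims=True)
    total = s1 + s2v
    with np.errstate(invalid="ignore", divide="ignore"):
        aniso = np.where(total > 0, (s1 - s2v) / total, np.nan)
    return StressField(ids, s1, s2v, axis1, axis2, aniso)


def inflate_shell(
    mesh: SurfaceMesh,
    material: ShellMaterial,
    load_steps: int = 4,
    maxiter: int = 2000,
    gtol: float = 1e-8,
) -> SurfaceMesh:
    """Equilibrium shape of a pressurized hyperelastic membrane.

    The input mesh is the unloaded reference configuration.  A St. Venant–
    Kirchhoff membrane (plane stress) is inflated by minimizing the total
    potential  Π(x) = Σ_faces t·A_ref·Ψ(E) − p·V(x),  where E is the Green
    strain of each constant-strain triangle and V the enclosed volume (the
    exact potential of a uniform follower pressure).  Minimization uses
    L-BFGS with pressure ramped over ``load_steps`` increments.

    A flattened reference shape bulges under pressure: its cross-section
    rounds up, which is what makes the hoop direction the main stress
    direction over the flatter faces of an inflated seed-shaped shell.
    """
    mesh.require_closed()
    X = mesh.vertices
    Fc = mesh.faces
    nv = mesh.n_vertices
    E_mod, nu, t, p_full = (
        material.young_modulus,
        material.poisson_ratio,
        material.thickness,
        material.pressure,
    )
    lam_ps = E_mod * nu / (1.0 - nu**2)  # plane-stress Lamé parameter
    mu = E_mod / (2.0 * (1.0 + nu))

    # reference per-face 2D edge matrices and areas
    d1 = X[Fc[:, 1]] - X[Fc[:, 0]]
    d2 = X[Fc[:, 2]] - X[Fc[:, 0]]
    e1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
    nrm = np.cross(d1, d2)
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    e2 = np.cross(nrm, e1)
    Dm = np.zeros((len(Fc), 2, 2))
    Dm[:, 0, 0] = np.einsum("ij,ij->i", d1, e1)
    Dm[:, 0, 1] = np.einsum("ij,ij->i", d2, e1)
    Dm[:, 1, 1] = np.einsum("ij,ij->i", d2, e2)
    A_ref = 0.5 * Dm[:, 0, 0] * Dm[:, 1, 1]
    Bm = np.linalg.inv(Dm)
    wgt = (t * A_ref)[:, None, None]

    i0, i1, i2 = Fc[:, 0], Fc[:, 1], Fc[:, 2]

    def energy_grad(xflat: np.ndarray, p: float) -> tuple[float, np.ndarray]:
        x = xflat.reshape(nv, 3)
        Ds = np.stack([x[i1] - x[i0], x[i2] - x[i0]], axis=2)  # (f, 3, 2)
        Fm = Ds @ Bm  # (f, 3, 2)
        C = np.einsum("fki,fkj->fij", Fm, Fm)
        Eg = 0.5 * (C - np.eye(2))
        trE = Eg[:, 0, 0] + Eg[:, 1, 1]
        S = lam_ps * trE[:, None, None] * np.eye(2) + 2.0 * mu * Eg
        psi = 0.5 * lam_ps * trE**2 + mu * np.einsum("fij,fij->f", Eg, Eg)
        W = float((wgt[:, 0, 0] * psi).sum())
        G = wgt * np.einsum("fik,fkl,fjl->fij", Fm, S, Bm)  # dW/dDs, (f, 3, 2)
        grad = np.zeros((nv, 3))
        np.add.at(grad, i1, G[:, :, 0])
        np.add.at(grad, i2, G[:, :, 1])
        np.add.at(grad, i0, -G[:, :, 0] - G[:, :, 1])
        v0, v1, v2 = x[i0], x[i1], x[i2]
        vol = float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)
        np.add.at(grad, i0, -p * np.cross(v1, v2) / 6.0)
        np.add.at(grad, i1, -p * np.cross(v2, v0) / 6.0)
        np.add.at(grad, i2, -p * np.cross(v0, v1) / 6.0)
        return W - p * vol, grad.ravel()

    from scipy.optimize import minimize

    x = X.ravel().copy()
    for step in range(1, load_steps + 1):
        p = p_full * step / load_steps
        res = minimize(
            energy_grad,
            x,
            args=(p,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "maxcor": 30},
        )
        x = res.x
    return SurfaceMesh(x.reshape(nv, 3), Fc.copy())


def spheroid_stress_oracle(
    a: float, b: float, material: ShellMaterial, latitude: float
) -> tuple[float, float]:
    """Closed-form membrane stresses on a pressurized spheroid of revolution.

    The spheroid has semi-axis ``a`` along the rotation axis and equatorial
    semi-axis ``b``.  ``latitude`` is the parametric latitude in degrees (0
    at the equator, ±90 at the poles).  Static equilibrium of a membrane of
    revolution gives

        σ_m = p·R2 / (2t),      σ_h = (p·R2/t) · (1 − R2/(2·R1)),

    with R1 the meridional and R2 the normal-section curvature radius.  At
    the poles R1 = R2 = b²/a and both stresses equal p·b²/(2·t·a).

    Returns ``(sigma_meridional, sigma_hoop)`` in MPa.
    """
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    if abs(latitude) > 90:
        raise ValueError(f"latitude must be within [-90, 90], got {latitude}")
    p, t = material.pressure, material.thickness
    u = np.deg2rad(latitude)
    w = np.hypot(a * np.cos(u), b * np.sin(u))
    R1 = w**3 / (a * b)
    R2 = b * w / a
    sigma_m = p * R2 / (2.0 * t)
    sigma_h = (p * R2 / t) * (1.0 - R2 / (2.0 * R1))
    return float(sigma_m), float(sigma_h)


def classify_regions(
    mesh: SurfaceMesh,
    tess: CellTessellation,
    spec: EllipsoidSpec,
    tip_fraction: float = 0.15,
    flank_angle_deg: float = 45.0,
) -> RegionLabels:
    """Split cells into tips, flanks and flat faces of an ellipsoidal seed.

    A cell is a ``tip`` when its (radially projected) centroid satisfies
    |x| > (1 − tip_fraction)·a; a non-tip cell is a ``flank`` when its mean
    outward normal is within ``flank_angle_deg`` of the ±y (width) axis,
    and a ``flat_face`` otherwise (normals near ±z on a flattened seed).
    """
    if not (0 < tip_fraction < 0.5):
        raise ValueError("tip_fraction must be in (0, 0.5)")
    if not (0 < flank_angle_deg < 90):
        raise ValueError("flank_angle_deg must be in (0, 90)")

    # consistency: faces must lie on the stated ellipsoid (within resolution)
    radial = np.sqrt(spec.implicit(mesh.face_centroids))
    if np.any(np.abs(radial - 1.0) > 0.01):
        raise InconsistencyError("mesh faces deviate from the stated ellipsoid by > 1%")

    cent = tess.cell_centroids
    cent_proj = cent / np.sqrt(spec.implicit(cent))[:, None]
    normals = tess.cell_normals

    labels = np.full(tess.n_cells, "flat_face", dtype="<U9")
    flank = np.abs(normals[:, 1]) > np.cos(np.deg2rad(flank_angle_deg))
    labels[flank] = "flank"
    tip = np.abs(cent_proj[:, 0]) > (1.0 - tip_fraction) * spec.a
    labels[tip] = "tip"
    return RegionLabels(tess.cell_ids.copy(), labels)


def field_summary(field, labels: RegionLabels) -> pd.DataFrame:
    """Region-wise summary of an anisotropy field.

    Works for :class:`StressField` and for curvature fields exposing
    ``cell_ids``, ``anisotropy`` and a major axis (``axis1`` or
    ``axis_max``).  Reports per-region count, mean/median/SD of anisotropy
    (NaN cells excluded and counted in ``n_excluded``) and the mean axial
    angle of the major axis to the organ long (x) axis.
    """
    from .curvature import axis_angles

    ids = np.asarray(field.cell_ids)
    missing = np.setdiff1d(ids, labels.cell_ids)
    if len(missing):
        raise CoverageError(f"labels missing for cells: {missing[:10].tolist()}")
    lab = labels.to_series().reindex(ids).to_numpy()

    aniso = np.asarray(field.anisotropy, dtype=float)
    major = getattr(field, "axis1", None)
    if major is None:
        major = field.axis_max
    long_axis = np.tile(np.array([1.0, 0.0, 0.0]), (len(ids), 1))
    angle = axis_angles(major, long_axis)

    rows = []
    for region in RegionLabels.REGIONS:
        sel = lab == region
        vals = aniso[sel]
        ok = np.isfinite(vals)
        n, n_ex = int(sel.sum()), int((~ok).sum())
        if n - n_ex > 0:
            rows.append(
                {
                    "region": region,
                    "n": n,
                    "n_excluded": n_ex,
                    "mean_anisotropy": float(np.mean(vals[ok])),
                    "median_anisotropy": float(np.median(vals[ok])),
                    "sd_anisotropy": float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else np.nan,
                    "mean_axis_angle_to_long_deg": float(np.mean(angle[sel][ok])),
                }
            )
        else:
            rows.append(
                {
                    "region": region,
                    "n": n,
                    "n_excluded": n_ex,
                    "mean_anisotropy": np.nan,
                    "median_anisotropy": np.nan,
                    "sd_anisotropy": np.nan,
                    "mean_axis_angle_to_long_deg": np.nan,
                }
            )
    return pd.DataFrame(rows).set_index("region")
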
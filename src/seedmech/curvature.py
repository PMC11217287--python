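"""Per-cell surface curvature and CMT–curvature angle statistics.

Curvature tensors are estimated per cell by least-squares quadric fitting
over a geodesic neighbourhood of the cell centroid (the "neighboring"
radius convention of cell-resolution curvature heatmaps: 30 µm for a young
seed, 60 µm once cells have enlarged).  The correlation between cortical
microtubule (CMT) orientation and the direction of maximum curvature is
summarized by the axial angle

    θ = arccos(|v_Mt · v_Mc|)  ∈ [0°, 90°],

computed between the per-cell mean CMT axis and the per-cell maximum
curvature axis, both tangent unit vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .mesh import CellTessellation, EllipsoidSpec, SurfaceMesh

__all__ = [
    "CurvatureField",
    "OrientationField",
    "AngleDistribution",
    "PrincipalCurvature",
    "estimate_curvature",
    "ellipsoid_curvature_oracle",
    "axis_angle",
    "axis_angles",
    "correlate_orientation_with_curvature",
    "orientation_relative_to_point",
    "UnderdeterminedFitError",
    "UndefinedOrientationError",
    "EmptyJoinError",
    "ProjectionError",
    "IncompleteFieldError",
]


class UnderdeterminedFitError(ValueError):
    """Too few mesh vertices in a curvature neighbourhood."""


class UndefinedOrientationError(ValueError):
    """Zero or badly scaled vector where a unit axis is required."""


class EmptyJoinError(ValueError):
    """Two per-cell fields share no cell ids."""


class ProjectionError(ValueError):
    """A point expected on a surface is not on it."""


class IncompleteFieldError(ValueError):
    """A field lacks a required per-cell quantity."""


@dataclass
class CurvatureField:
    """Per-cell principal curvatures (1/µm) and axes.

    ``kappa_max >= kappa_min``; curvature is positive for a convex surface
    with outward normals (a sphere has κ = +1/R).  ``anisotropy`` is
    (κ_max−κ_min)/(|κ_max|+|κ_min|) where the denominator is positive.
    """

    cell_ids: np.ndarray
    kappa_max: np.ndarray
    kappa_min: np.ndarray
    axis_max: np.ndarray
    axis_min: np.ndarray
    anisotropy: np.ndarray
    neighborhood_radius: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "kappa_max": self.kappa_max,
                "kappa_min": self.kappa_min,
                "anisotropy": self.anisotropy,
                "axis_max_x": self.axis_max[:, 0],
                "axis_max_y": self.axis_max[:, 1],
                "axis_max_z": self.axis_max[:, 2],
                "axis_min_x": self.axis_min[:, 0],
                "axis_min_y": self.axis_min[:, 1],
                "axis_min_z": self.axis_min[:, 2],
            }
        )


@dataclass
class OrientationField:
    """Per-cell axial (sign-free) tangent unit CMT orientation.

    ``vectors[i]`` and ``−vectors[i]`` are equivalent; ``score`` is an
    organization score in [0, 1].
    """

    cell_ids: np.ndarray
    vectors: np.ndarray
    score: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "x_mt": self.vectors[:, 0],
                "y_mt": self.vectors[:, 1],
                "z_mt": self.vectors[:, 2],
                "score": self.score,
            }
        )


@dataclass
class AngleDistribution:
    """Distribution of per-cell axial angles θ ∈ [0°, 90°]."""

    theta: pd.Series  # indexed by cell_id
    bin_edges: np.ndarray
    counts: np.ndarray
    n_excluded: int

    @property
    def median(self) -> float:
        return float(self.theta.median())

    @property
    def mean(self) -> float:
        return float(self.theta.mean())

    @property
    def fraction_below_30(self) -> float:
        return float((self.theta < 30.0).mean())


@dataclass
class PrincipalCurvature:
    kappa_max: float
    kappa_min: float
    axis_max: np.ndarray
    axis_min: np.ndarray


def _unit_or_raise(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise UndefinedOrientationError(f"{name} is a zero vector")
    if abs(nrm - 1.0) > 0.01:
        raise UndefinedOrientationError(f"{name} is not unit-norm (|v| = {nrm:.4f})")
    return v / nrm


def axis_angle(v_mt: np.ndarray, v_mc: np.ndarray) -> float:
    """Axial angle θ = arccos(|v_mt · v_mc|) in degrees, in [0, 90].

    Symmetric in its arguments and invariant to a sign flip of either axis.
    Inputs must be unit vectors within 1% (normalized internally).
    """
    u = _unit_or_raise(v_mt, "v_mt")
    w = _unit_or_raise(v_mc, "v_mc")
    return float(np.degrees(np.arccos(np.clip(abs(float(u @ w)), 0.0, 1.0))))


def axis_angles(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorized :func:`axis_angle` over rows (no strict norm check: rows
    are normalized; zero rows yield NaN)."""
    u = np.atleast_2d(np.asarray(u, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(np.einsum("ij,ij->i", u, v)) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))


def estimate_curvature(
    mesh: SurfaceMesh,
    tess: CellTessellation,
    neighborhood_radius: float,
    metric: str = "geodesic",
) -> CurvatureField:
    """Per-cell curvature by quadric fitting over a surface neighbourhood.

    For each cell, all mesh vertices within ``neighborhood_radius`` (µm) of
    the cell centroid — distances measured along the surface by shortest
    paths on the edge graph (``metric="geodesic"``) or straight-line
    (``metric="euclidean"``) — are fitted with a quadric
    h = ½(Aξ² + 2Bξη + Cη²) + Dξ + Eη + h0 in the cell's tangent frame.
    The shape operator of the fitted patch yields principal curvatures and
    directions at the cell centroid.
    """
    if metric not in ("geodesic", "euclidean"):
        raise ValueError("metric must be 'geodesic' or 'euclidean'")
    if neighborhood_radius <= 2.0 * mesh.mean_edge_length:
        raise ValueError(
            f"neighborhood_radius ({neighborhood_radius:g} µm) must exceed twice the "
            f"mean edge length ({mesh.mean_edge_length:g} µm)"
        )

    cent = tess.cell_centroids
    normals = tess.cell_normals
    tree = cKDTree(mesh.vertices)

    if metric == "geodesic":
        _, sources = tree.query(cent)
        dist = dijkstra(mesh.vertex_graph(), indices=sources, limit=neighborhood_radius)
        neighborhoods = [np.flatnonzero(np.isfinite(dist[i])) for i in range(len(cent))]
    else:
        neighborhoods = tree.query_ball_point(cent, neighborhood_radius)

    n_cells = tess.n_cells
    kmax = np.empty(n_cells)
    kmin = np.empty(n_cells)
    amax = np.empty((n_cells, 3))
    amin = np.empty((n_cells, 3))
    for i in range(n_cells):
        sel = np.asarray(neighborhoods[i])
        if len(sel) < 6:
            raise UnderdeterminedFitError(
                f"cell {tess.cell_ids[i]}: only {len(sel)} vertices within "
                f"{neighborhood_radius:g} µm (need >= 6)"
            )
        n = normals[i]
        seed = np.zeros(3)
        seed[np.argmin(np.abs(n))] = 1.0
        e1 = np.cross(n, seed)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)

        rel = mesh.vertices[sel] - cent[i]
        xi, eta = rel @ e1, rel @ e2
        h = rel @ n
        A_design = np.column_stack(
            [0.5 * xi**2, xi * eta, 0.5 * eta**2, xi, eta, np.ones_like(xi)]
        )
        coef, *_ = np.linalg.lstsq(A_design, h, rcond=None)
        Aq, Bq, Cq, Dq, Eq = coef[:5]
        H = np.array([[Aq, Bq], [Bq, Cq]])
        g = np.array([Dq, Eq])
        W = np.eye(2) + np.outer(g, g)
        s = np.sqrt(1.0 + g @ g)
        # shape operator S = W⁻¹ H / s; sign flipped for the outward-normal
        # convention (sphere: κ = +1/R)
        evals, evecs = linalg.eigh(H, W)
        kappas = -evals / s
        # dirs3[j]: 3D direction of eigenvector j of the shape operator
        dirs3 = evecs[0, :, None] * e1[None, :] + evecs[1, :, None] * e2[None, :]
        order = np.argsort(kappas)[::-1]
        kmax[i], kmin[i] = kappas[order[0]], kappas[order[1]]
        a1 = dirs3[order[0]]
        a1 = a1 - (a1 @ n) * n
        a1 /= np.linalg.norm(a1)
        a2 = np.cross(n, a1)
        amax[i], amin[i] = a1, a2

    denom = np.abs(kmax) + np.abs(kmin)
    with np.errstate(invalid="ignore", divide="ignore"):
        aniso = np.where(denom > 0, (kmax - kmin) / denom, np.nan)
    return CurvatureField(
        tess.cell_ids.copy(), kmax, kmin, amax, amin, aniso, float(neighborhood_radius)
    )


def ellipsoid_curvature_oracle(spec: EllipsoidSpec, point: np.ndarray) -> PrincipalCurvature:
    """Exact principal curvatures/directions of a triaxial ellipsoid.

    From the second fundamental form of the implicit surface
    (x/a)² + (y/b)² + (z/c)² = 1: the shape operator restricted to the
    tangent plane is Eᵀ·H·E / |∇F| with H = diag(2/a², 2/b², 2/c²).
    Positive curvature for the convex surface with outward normals.
    """
    p = np.asarray(point, dtype=float)
    F = float(spec.implicit(p)[0])
    if abs(F - 1.0) > 1e-6:
        raise ProjectionError(f"point is not on the ellipsoid (implicit value {F:.8f})")
    axes2 = spec.semi_axes**2
    grad = 2.0 * p / axes2
    gn = np.linalg.norm(grad)
    n = grad / gn
    seed = np.zeros(3)
    seed[np.argmin(np.abs(n))] = 1.0
    e1 = np.cross(n, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    E = np.column_stack([e1, e2])
    H = np.diag(2.0 / axes2)
    B2 = E.T @ H @ E / gn
    evals, evecs = np.linalg.eigh(B2)  # ascending
    d_min = E @ evecs[:, 0]
    d_max = E @ evecs[:, 1]
    return PrincipalCurvature(
        kappa_max=float(evals[1]),
        kappa_min=float(evals[0]),
        axis_max=d_max / np.linalg.norm(d_max),
        axis_min=d_min / np.linalg.norm(d_min),
    )


def correlate_orientation_with_curvature(
    orient: OrientationField, curv: CurvatureField, bins: int = 18
) -> AngleDistribution:
    """θ per cell between the CMT axis and the maximum-curvature axis.

    Cells present in only one field, or carrying non-finite vectors, are
    excluded and counted in ``n_excluded``.  The histogram uses ``bins``
    equal-width bins on [0°, 90°].
    """
    oi = np.asarray(orient.cell_ids)
    ci = np.asarray(curv.cell_ids)
    shared, o_idx, c_idx = np.intersect1d(oi, ci, return_indices=True)
    if len(shared) == 0:
        raise EmptyJoinError("orientation and curvature fields share no cells")
    v_mt = orient.vectors[o_idx]
    v_mc = curv.axis_max[c_idx]
    ok = np.isfinite(v_mt).all(axis=1) & np.isfinite(v_mc).all(axis=1)
    n_excluded = (len(oi) - len(shared)) + (len(ci) - len(shared)) + int((~ok).sum())
    theta = axis_angles(v_mt[ok], v_mc[ok])
    counts, edges = np.histogram(theta, bins=bins, range=(0.0, 90.0))
    return AngleDistribution(
        theta=pd.Series(theta, index=shared[ok], name="theta_deg"),
        bin_edges=edges,
        counts=counts,
        n_excluded=n_excluded,
    )


def orientation_relative_to_point(
    orientations_deg: np.ndarray,
    centroids: np.ndarray,
    focus: np.ndarray,
) -> np.ndarray:
    """Axial deviation of 2D CMT axes from the circumferential direction
    around a focus point (e.g. an ablation site).

    0° means the axis is tangent to the circle through the cell centered on
    the focus (circumferential); 90° means it points at the focus (radial).
    """
    ang = np.asarray(orientations_deg, dtype=float)
    cent = np.atleast_2d(np.asarray(centroids, dtype=float))
    fc = np.asarray(focus, dtype=float)
    r = cent - fc
    dist = np.linalg.norm(r, axis=1)
    if np.any(dist == 0):
        bad = np.flatnonzero(dist == 0)
        raise UndefinedOrientationError(
            f"centroid(s) {bad.tolist()} coincide with the focus; direction undefined"
        )
    circ = np.degrees(np.arctan2(r[:, 1], r[:, 0])) + 90.0
    dev = np.abs((ang - circ + 90.0) % 180.0 - 90.0)
    return dev
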
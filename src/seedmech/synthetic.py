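"""Synthetic inputs with known ground truth for every pipeline stage.

Generates flattened-ellipsoid seed surfaces, cell tessellations on them,
oriented fibril textures, curvature-correlated CMT orientation fields,
seed silhouettes and noisy daily growth series.  Every generator is
deterministic given its ``rng_seed`` and records the ground truth that its
downstream analyzer is expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.special import i0e, i1e

from .curvature import CurvatureField, IncompleteFieldError, OrientationField
from .mesh import CellTessellation, EllipsoidSpec, InvalidSpecError, SurfaceMesh

__all__ = [
    "FibrilImage",
    "SilhouetteSpec",
    "CapacityError",
    "make_ellipsoid_mesh",
    "make_sheet_mesh",
    "tessellate_surface",
    "make_fibril_image",
    "sample_cmt_field",
    "make_silhouette_image",
    "make_growth_observations",
    "summarize_growth_observations",
    "make_paired_tessellation",
]


class CapacityError(ValueError):
    """More cells requested than the mesh can host."""


# ---------------------------------------------------------------------------
# meshes


def make_ellipsoid_mesh(spec: EllipsoidSpec, refinement: int) -> SurfaceMesh:
    """Triaxial ellipsoid mesh by icosahedral subdivision.

    An icosphere (subdivision level ``refinement`` >= 1, face count
    20·4^refinement) is mapped radially onto the ellipsoid, giving
    near-uniform triangles without pole artifacts.  Vertices satisfy
    (x/a)² + (y/b)² + (z/c)² = 1 to machine precision.
    """
    if not isinstance(spec, EllipsoidSpec):
        spec = EllipsoidSpec(*spec)
    if refinement < 1:
        raise InvalidSpecError("refinement must be >= 1")
    ico = trimesh.creation.icosphere(subdivisions=int(refinement), radius=1.0)
    unit = np.asarray(ico.vertices)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    return SurfaceMesh(unit * spec.semi_axes, np.asarray(ico.faces))


def make_sheet_mesh(width: float, height: float, divisions: int = 20) -> SurfaceMesh:
    """Planar triangulated rectangle in the z = 0 plane (normals +z).

    An open test surface for operations that do not require closure, e.g.
    the paired-tessellation cell-growth generator.
    """
    nx = ny = int(divisions) + 1
    xs = np.linspace(0.0, width, nx)
    ys = np.linspace(0.0, height, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v10 = (i + 1) * ny + j
            faces.append([v00, v10, v10 + 1])
            faces.append([v00, v10 + 1, v00 + 1])
    return SurfaceMesh(verts, np.asarray(faces))


def tessellate_surface(
    mesh: SurfaceMesh,
    n_cells: int,
    rng_seed: int,
    relax_iters: int = 25,
) -> CellTessellation:
    """Voronoi-like cell tessellation of a surface mesh.

    Seed points drawn from the face centroids are relaxed by Lloyd
    iterations (assignment of faces to the nearest seed by Euclidean
    distance, which approximates geodesic distance at cell scale; seeds
    re-projected onto the surface each iteration).  Each resulting cell is
    made face-connected and the tessellation has exactly ``n_cells``
    non-empty cells.  Deterministic for a fixed ``rng_seed``.
    """
    if n_cells < 1:
        raise InvalidSpecError("n_cells must be >= 1")
    if n_cells > mesh.n_faces:
        raise CapacityError(f"n_cells ({n_cells}) exceeds face count ({mesh.n_faces})")
    if relax_iters < 0:
        raise InvalidSpecError("relax_iters must be >= 0")

    rng = np.random.default_rng(rng_seed)
    fc = mesh.face_centroids
    fa = mesh.face_areas
    seeds = fc[rng.choice(mesh.n_faces, size=n_cells, replace=False)]

    labels = np.zeros(mesh.n_faces, dtype=np.int64)
    for _ in range(relax_iters + 1):
        _, labels = cKDTree(seeds).query(fc)
        labels = _fill_empty_cells(labels, fc, seeds, n_cells)
        # Lloyd update: area-weighted centroid, projected back to the surface
        new = np.zeros((n_cells, 3))
        wsum = np.bincount(labels, weights=fa, minlength=n_cells)
        for k in range(3):
            new[:, k] = np.bincount(labels, weights=fc[:, k] * fa, minlength=n_cells)
        new /= wsum[:, None]
        _, proj = cKDTree(fc).query(new)
        seeds = fc[proj]

    labels = _enforce_connectivity(mesh, labels, n_cells)
    return CellTessellation(mesh, labels)


def _fill_empty_cells(labels, fc, seeds, n_cells):
    """Give any empty cell the face farthest from its current seed."""
    for _ in range(n_cells):
        counts = np.bincount(labels, minlength=n_cells)
        empty = np.flatnonzero(counts == 0)
        if len(empty) == 0:
            break
        d = np.linalg.norm(fc - seeds[labels], axis=1)
        # only steal from cells with more than one face
        d[counts[labels] <= 1] = -1.0
        labels = labels.copy()
        labels[int(np.argmax(d))] = empty[0]
    return labels


def _enforce_connectivity(mesh: SurfaceMesh, labels: np.ndarray, n_cells: int) -> np.ndarray:
    """Reassign minority components of each cell to a neighbouring cell."""
    adj = mesh.face_adjacency().tocoo()
    pairs = np.column_stack([adj.row, adj.col])
    for _ in range(100):
        moved = False
        for cell in range(n_cells):
            faces = np.flatnonzero(labels == cell)
            if len(faces) <= 1:
                continue
            sub = mesh.face_adjacency()[np.ix_(faces, faces)]
            ncomp, comp = connected_components(sub, directed=False)
            if ncomp == 1:
                continue
            sizes = np.bincount(comp)
            keep = int(np.argmax(sizes))
            for ci in range(ncomp):
                if ci == keep:
                    continue
                comp_faces = faces[comp == ci]
                in_comp = np.isin(pairs[:, 0], comp_faces)
                nb = pairs[in_comp, 1]
                nb_labels = labels[nb]
                nb_labels = nb_labels[nb_labels != cell]
                if len(nb_labels) == 0:
                    continue  # island with no outside neighbour; leave as is
                target = int(np.bincount(nb_labels).argmax())
                labels[comp_faces] = target
                moved = True
        if not moved:
            break
    return labels


# ---------------------------------------------------------------------------
# fibril textures


@dataclass
class FibrilImage:
    """2D grayscale raster (float, arbitrary units) with optional truth.

    When generated synthetically, ``truth_orientation_deg`` (axial, in
    [0, 180)) and ``truth_anisotropy`` (in [0, 1]) record the ground truth.
    """

    data: np.ndarray
    pixel_size_um: float = 0.2
    truth_orientation_deg: Optional[float] = None
    truth_anisotropy: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or min(self.data.shape) < 16:
            raise InvalidSpecError("fibril image must be 2D and at least 16x16 px")
        if not np.all(np.isfinite(self.data)):
            raise InvalidSpecError("fibril image must contain finite values")


def make_fibril_image(
    size_px: tuple[int, int],
    orientation_deg: float,
    anisotropy_level: float,
    rng_seed: int,
    wavelength_px: float = 20.0,
    coherence_px: float = 10.0,
    bandwidth_px: float = 8.0,
    pixel_size_um: float = 0.2,
) -> FibrilImage:
    """Oriented fibril-like texture of controlled anisotropy.

    White noise is band-pass filtered in the Fourier domain with a Gabor-like
    transfer function whose pass band sits at spatial frequency
    1/``wavelength_px`` perpendicular to the fibril axis: the result is a
    streaky texture elongated along ``orientation_deg``.  The final image
    blends this oriented pattern (weight ``anisotropy_level``) with
    isotropic noise band-limited to the same spectral ring (weight
    1 − ``anisotropy_level``), both normalized to unit variance, so the
    blend varies angular order at a fixed fibril spacing.  Angles use image
    coordinates (x = columns, y = rows).
    """
    if not (0.0 <= orientation_deg < 180.0):
        raise InvalidSpecError("orientation_deg must be in [0, 180)")
    if not (0.0 <= anisotropy_level <= 1.0):
        raise InvalidSpecError("anisotropy_level must be in [0, 1]")
    h, w = int(size_px[0]), int(size_px[1])
    if min(h, w) < 16:
        raise InvalidSpecError("image must be at least 16x16 px")

    rng = np.random.default_rng(rng_seed)
    theta = np.deg2rad(orientation_deg)
    ky = np.fft.fftfreq(h)[:, None]
    kx = np.fft.fftfreq(w)[None, :]
    om_par = 2.0 * np.pi * (kx * np.cos(theta) + ky * np.sin(theta))
    om_perp = 2.0 * np.pi * (-kx * np.sin(theta) + ky * np.cos(theta))
    om0 = 2.0 * np.pi / wavelength_px
    transfer = np.exp(-0.5 * (coherence_px * om_par) ** 2) * np.exp(
        -0.5 * (bandwidth_px * (np.abs(om_perp) - om0)) ** 2
    )
    noise = rng.standard_normal((h, w))
    pattern = np.real(np.fft.ifft2(np.fft.fft2(noise) * transfer))
    std = pattern.std()
    if std > 0:
        pattern = (pattern - pattern.mean()) / std

    # isotropic component: same spectral ring, no angular preference
    om_mag = np.hypot(om_par, om_perp)
    ring = np.exp(-0.5 * (bandwidth_px * (om_mag - om0)) ** 2)
    iso = np.real(np.fft.ifft2(np.fft.fft2(rng.standard_normal((h, w))) * ring))
    iso = (iso - iso.mean()) / iso.std()

    data = anisotropy_level * pattern + (1.0 - anisotropy_level) * iso
    return FibrilImage(
        data,
        pixel_size_um=pixel_size_um,
        truth_orientation_deg=float(orientation_deg),
        truth_anisotropy=float(anisotropy_level),
    )


# ---------------------------------------------------------------------------
# CMT orientation fields


def sample_cmt_field(
    curvature: CurvatureField,
    kappa: float,
    offset_deg: float,
    rng_seed: int,
) -> OrientationField:
    """Axially distributed CMT field correlated with curvature directions.

    Per cell, an axial deviation is drawn from a von Mises distribution on
    doubled angles (the standard axial-statistics device: 2δ ~ VM(0, κ))
    around the maximum-curvature axis rotated by ``offset_deg`` within the
    tangent plane.  ``kappa = 0`` gives a uniform axial field; large κ
    concentrates the CMT axes on the (rotated) curvature axis.  The
    organization score reported per cell is the axial mean resultant
    I1(κ)/I0(κ).
    """
    if kappa < 0:
        raise InvalidSpecError("kappa must be >= 0")
    a1 = np.asarray(curvature.axis_max, dtype=float)
    a2 = np.asarray(curvature.axis_min, dtype=float)
    if not (np.all(np.isfinite(a1)) and np.all(np.isfinite(a2))):
        raise IncompleteFieldError("curvature field lacks finite principal axes")
    n = np.cross(a1, a2)
    n /= np.linalg.norm(n, axis=1, keepdims=True)

    phi = np.deg2rad(offset_deg)
    base = np.cos(phi) * a1 + np.sin(phi) * np.cross(n, a1)
    base /= np.linalg.norm(base, axis=1, keepdims=True)
    perp = np.cross(n, base)

    rng = np.random.default_rng(rng_seed)
    delta = rng.vonmises(0.0, kappa, size=len(base)) / 2.0
    vec = np.cos(delta)[:, None] * base + np.sin(delta)[:, None] * perp
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    score = float(i1e(kappa) / i0e(kappa))
    return OrientationField(
        cell_ids=np.asarray(curvature.cell_ids).copy(),
        vectors=vec,
        score=np.full(len(base), score),
    )


# ---------------------------------------------------------------------------
# silhouettes


@dataclass
class SilhouetteSpec:
    """One or more elliptical seed silhouettes on a raster canvas.

    ``centers`` are (x, y) pixel positions; all seeds share half-axes
    ``half_length >= half_width > 0`` (px) and may be individually rotated
    by ``angles_deg``.  ``boundary_noise`` is the relative amplitude of a
    smooth random perturbation of the outline radius.
    """

    half_length: float
    half_width: float
    image_size: tuple[int, int] = (512, 512)
    centers: Sequence[tuple[float, float]] = ()
    angles_deg: Optional[Sequence[float]] = None
    boundary_noise: float = 0.0

    def __post_init__(self) -> None:
        if not (self.half_length >= self.half_width > 0):
            raise InvalidSpecError("require half_length >= half_width > 0")
        if self.boundary_noise < 0:
            raise InvalidSpecError("boundary_noise must be >= 0")
        if self.angles_deg is not None and len(self.angles_deg) != len(self.centers):
            raise InvalidSpecError("angles_deg must match centers")


def make_silhouette_image(
    spec: SilhouetteSpec,
    rng_seed: int,
    max_overlap_fraction: float = 0.05,
    foreground: float = 0.75,
    background: float = 0.25,
    intensity_noise: float = 0.02,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Grayscale image of seed silhouettes plus a ground-truth table.

    Foreground/background intensities are separated well beyond the added
    Gaussian intensity noise, so thresholding can recover the outlines.
    Seeds may touch, but masks overlapping by more than
    ``max_overlap_fraction`` of the smaller seed raise an error, as does a
    seed extending beyond the canvas.  Returns ``(image, truth)`` where
    ``truth`` has one row per seed (center, half-axes, angle, pixel area).
    """
    rng = np.random.default_rng(rng_seed)
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    angles = spec.angles_deg if spec.angles_deg is not None else [0.0] * len(spec.centers)

    margin = spec.half_length * (1.0 + 3.0 * spec.boundary_noise)
    masks = []
    records = []
    for (cx, cy), ang in zip(spec.centers, angles):
        if cx - margin < 0 or cx + margin > w or cy - margin < 0 or cy + margin > h:
            raise InvalidSpecError(f"seed at ({cx}, {cy}) does not fit inside the image")
        t = np.deg2rad(ang)
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(t) + dy * np.sin(t)
        v = -dx * np.sin(t) + dy * np.cos(t)
        rho2 = (u / spec.half_length) ** 2 + (v / spec.half_width) ** 2
        if spec.boundary_noise > 0:
            phi = np.arctan2(v, u)
            scale = np.ones_like(phi)
            for k in range(2, 6):
                ak, bk = rng.normal(0.0, 1.0, 2) / k
                scale += spec.boundary_noise * (ak * np.cos(k * phi) + bk * np.sin(k * phi))
            mask = rho2 <= scale**2
        else:
            mask = rho2 <= 1.0
        masks.append(mask)
        records.append(
            {
                "center_x": cx,
                "center_y": cy,
                "half_length": spec.half_length,
                "half_width": spec.half_width,
                "angle_deg": ang,
                "area_px": int(mask.sum()),
            }
        )

    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            inter = int((masks[i] & masks[j]).sum())
            smaller = min(masks[i].sum(), masks[j].sum())
            if smaller and inter / smaller > max_overlap_fraction:
                raise InvalidSpecError(
                    f"seeds {i} and {j} overlap by {inter / smaller:.1%} "
                    f"(limit {max_overlap_fraction:.1%})"
                )

    union = np.zeros((h, w), dtype=bool)
    for m in masks:
        union |= m
    image = np.where(union, foreground, background) + rng.normal(0.0, intensity_noise, (h, w))
    return image, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# growth series


def make_growth_observations(
    daily_mean_area: Sequence[float],
    daily_mean_ar: Sequence[float],
    cv: float,
    n_seeds: int,
    rng_seed: int,
) -> pd.DataFrame:
    """Per-seed daily area / aspect-ratio observations around given means.

    Values are lognormally scattered about the daily means with coefficient
    of variation ``cv`` (cv = 0 reproduces the means exactly).  Returns a
    tidy table with columns ``seed``, ``day``, ``area``, ``aspect_ratio``.
    """
    area = np.asarray(daily_mean_area, dtype=float)
    ar = np.asarray(daily_mean_ar, dtype=float)
    if len(area) != len(ar):
        raise InvalidSpecError("daily series must have the same length")
    if len(area) < 2:
        raise InvalidSpecError("need at least 2 days")
    if cv < 0:
        raise InvalidSpecError("cv must be >= 0")
    if n_seeds < 1:
        raise InvalidSpecError("n_seeds must be >= 1 (empty table)")
    if np.any(area <= 0) or np.any(ar <= 0):
        raise InvalidSpecError("daily means must be positive")

    rng = np.random.default_rng(rng_seed)
    s = np.sqrt(np.log1p(cv**2))
    n_days = len(area)
    rows = []
    for seed_i in range(n_seeds):
        za = rng.normal(0.0, 1.0, n_days)
        zr = rng.normal(0.0, 1.0, n_days)
        a_obs = area * np.exp(s * za - 0.5 * s**2)
        r_obs = ar * np.exp(s * zr - 0.5 * s**2)
        for d in range(n_days):
            rows.append(
                {"seed": seed_i, "day": d, "area": a_obs[d], "aspect_ratio": r_obs[d]}
            )
    return pd.DataFrame(rows)


def summarize_growth_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Per-day mean and SD of area and aspect ratio (input to the growth
    derivative formulas)."""
    g = obs.groupby("day")
    out = pd.DataFrame(
        {
            "mean_area": g["area"].mean(),
            "sd_area": g["area"].std(ddof=1),
            "mean_ar": g["aspect_ratio"].mean(),
            "sd_ar": g["aspect_ratio"].std(ddof=1),
        }
    )
    return out


# ---------------------------------------------------------------------------
# paired tessellations (cell growth ground truth)


def make_paired_tessellation(
    tess: CellTessellation,
    stretch_x: float,
    stretch_y: float,
    division_prob: float,
    rng_seed: int,
) -> tuple[CellTessellation, dict[int, frozenset[int]]]:
    """Deformed + divided copy of a tessellation with recorded lineage.

    The later tessellation lives on the same mesh mapped by the in-plane
    affine stretch diag(stretch_x, stretch_y, 1).  Each cell with at least
    two faces divides with probability ``division_prob`` into two offspring
    split by a median cut along a random tangent direction (both halves
    non-empty).  Offspring receive fresh cell ids; the returned lineage
    maps each parent id to its offspring ids.
    """
    if stretch_x <= 0 or stretch_y <= 0:
        raise InvalidSpecError("stretch factors must be positive")
    if not (0.0 <= division_prob <= 1.0):
        raise InvalidSpecError("division_prob must be in [0, 1]")

    rng = np.random.default_rng(rng_seed)
    mesh1 = SurfaceMesh(
        tess.mesh.vertices * np.array([stretch_x, stretch_y, 1.0]), tess.mesh.faces
    )
    face_cell1 = np.empty(tess.mesh.n_faces, dtype=np.int64)
    lineage: dict[int, frozenset[int]] = {}
    next_id = 0
    fc0 = tess.mesh.face_centroids
    normals = tess.cell_normals
    centroids = tess.cell_centroids

    for pos, parent in enumerate(tess.cell_ids):
        faces = tess.cell_faces(int(parent))
        divide = len(faces) >= 2 and rng.random() < division_prob
        if divide:
            n = normals[pos]
            seed = np.zeros(3)
            seed[np.argmin(np.abs(n))] = 1.0
            e1 = np.cross(n, seed)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(n, e1)
            ang = rng.uniform(0.0, np.pi)
            direction = np.cos(ang) * e1 + np.sin(ang) * e2
            scores = (fc0[faces] - centroids[pos]) @ direction
            order = np.argsort(scores, kind="stable")
            half = len(faces) // 2
            ids = (next_id, next_id + 1)
            face_cell1[faces[order[:half]]] = ids[0]
            face_cell1[faces[order[half:]]] = ids[1]
            lineage[int(parent)] = frozenset(ids)
            next_id += 2
        else:
            face_cell1[faces] = next_id
            lineage[int(parent)] = frozenset({next_id})
            next_id += 1

    tess1 = CellTessellation(mesh1, face_cell1, lineage=lineage)
    return tess1, lineage
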
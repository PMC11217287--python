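"""Organ- and cell-scale seed morphometry.

Seed silhouettes are segmented by Huang minimum-fuzziness thresholding
followed by a distance-transform watershed (separating touching seeds);
shape is measured either by moment-matched ellipse fitting (mature seeds)
or by principal-axis chords (developing seeds).  Daily growth series are
differentiated with the organ-scale formulas

    growth_rate(n→n+1) = (mean_{n+1} − mean_n) / mean_n
    sd_rate(n→n+1)     = sqrt((sd_{n+1}/mean_{n+1})² + (sd_n/mean_n)²)

applied to seed area (growth rate) and to aspect ratio (growth
anisotropy).  Cell-scale growth maps fit the best linear map between
matched tessellations, and the pricking statistic summarizes per-cell
dimension changes by their per-seed median (robust to segmentation
outliers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .mesh import CellTessellation

__all__ = [
    "SeedShape",
    "threshold_huang",
    "segment_seeds",
    "measure_seed",
    "growth_derivative_series",
    "cell_growth_map",
    "dimension_change_stats",
    "AmbiguityError",
    "DomainError",
    "LineageError",
    "JoinError",
]


class AmbiguityError(ValueError):
    """Measurement requested on a multi-object mask."""


class DomainError(ValueError):
    """Input outside the mathematical domain of a formula."""


class LineageError(ValueError):
    """Lineage map does not consistently connect two tessellations."""


class JoinError(ValueError):
    """Tables cannot be joined on their shared keys."""


@dataclass
class SeedShape:
    """Seed size and shape: area, length L, width W, aspect ratio L/W."""

    area: float
    length: float
    width: float
    aspect_ratio: float
    mode: str


def threshold_huang(image: np.ndarray, nbins: int = 256) -> float:
    """Huang & Wang minimum-fuzziness threshold.

    For each candidate threshold, pixels are given a fuzzy membership to
    their class (foreground/background) based on distance to the class
    mean, and the Shannon entropy of the memberships is minimized.
    Matches the ImageJ "Huang" auto-threshold on the same histogram.
    """
    data = np.asarray(image, dtype=float).ravel()
    if np.ptp(data) == 0:
        raise ValueError("cannot threshold a constant image")
    hist, edges = np.histogram(data, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    first = int(np.flatnonzero(hist)[0])
    last = int(np.flatnonzero(hist)[-1])
    if first == last:
        return float(centers[first])

    # cumulative sums for class means
    w = np.cumsum(hist)
    s = np.cumsum(hist * centers)
    w_total, s_total = w[-1], s[-1]
    C = centers[last] - centers[first]

    best_t, best_entropy = first, np.inf
    for t in range(first, last):
        w0 = w[t]
        if w0 == 0 or w0 == w_total:
            continue
        mu0 = s[t] / w0
        mu1 = (s_total - s[t]) / (w_total - w0)
        mu = np.where(np.arange(nbins) <= t, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(centers - mu) / C)  # membership in (0.5, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            ent = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
        ent = np.where(np.isfinite(ent), ent, 0.0)
        total = float((hist * ent).sum())
        if total < best_entropy:
            best_entropy, best_t = total, t
    return float(centers[best_t])


def segment_seeds(
    image: np.ndarray,
    min_area: int = 100,
    min_solidity: float = 0.8,
    peak_min_distance: int | None = None,
    min_contrast_sigma: float = 3.0,
) -> np.ndarray:
    """Segment seed silhouettes from a grayscale image.

    Huang threshold → binary mask → Euclidean distance transform →
    watershed seeded at the distance maxima (separating touching seeds).
    Objects below ``min_area`` px² are discarded; objects with solidity
    below ``min_solidity`` are kept but flagged with a warning (the manual
    curation step of a silhouette-measurement macro).  Returns a labelled
    mask; an image with no foreground yields zero labels and a warning.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("image is constant; nothing to segment")
    thr = threshold_huang(img)
    binary = img > thr
    # reject a spurious split of a foreground-free image: the class
    # separation must exceed the background scatter
    if binary.any() and not binary.all():
        separation = img[binary].mean() - img[~binary].mean()
        scatter = img[~binary].std()
        if scatter > 0 and separation < min_contrast_sigma * scatter:
            binary[:] = False
    binary = ndimage.binary_fill_holes(binary)
    binary = remove_small_objects(binary, max_size=min_area - 1)
    if not binary.any():
        warnings.warn("no foreground after thresholding", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)

    dist = ndimage.distance_transform_edt(binary)
    smooth = ndimage.gaussian_filter(dist, 2.0)
    if peak_min_distance is None:
        peak_min_distance = max(5, int(0.7 * dist.max()))
    coords = peak_local_max(
        smooth, min_distance=peak_min_distance, labels=sk_label(binary), exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-smooth, markers, mask=binary)

    # drop small fragments, relabel sequentially
    out = np.zeros_like(labels)
    next_label = 1
    for prop in regionprops(labels):
        if prop.area < min_area:
            continue
        if prop.solidity < min_solidity:
            warnings.warn(
                f"object {prop.label} has solidity {prop.solidity:.2f} < {min_solidity}; "
                "check segmentation",
                stacklevel=2,
            )
        out[labels == prop.label] = next_label
        next_label += 1
    return out


def measure_seed(mask: np.ndarray, mode: str = "ellipse", pixel_size: float = 1.0) -> SeedShape:
    """Length, width, aspect ratio and area of a single segmented seed.

    ``mode="ellipse"``: L and W are the major/minor axes of the ellipse with
    the same second moments as the object (mature-seed convention).
    ``mode="axes"``: L is the longest chord along the principal axis and W
    the perpendicular extent through its midpoint (automated proxy for the
    hand-drawn length/width lines used on developing seeds).
    """
    if mode not in ("ellipse", "axes"):
        raise ValueError("mode must be 'ellipse' or 'axes'")
    m = np.asarray(mask)
    binary = m > 0
    if not binary.any():
        raise ValueError("empty mask")
    lab = sk_label(binary)
    if lab.max() != 1:
        raise AmbiguityError(f"mask contains {lab.max()} connected objects; expected 1")
    prop = regionprops(lab)[0]
    area = float(prop.area) * pixel_size**2

    if mode == "ellipse":
        L = float(prop.axis_major_length) * pixel_size
        W = float(prop.axis_minor_length) * pixel_size
    else:
        coords = prop.coords.astype(float)  # (row, col)
        c = coords.mean(axis=0)
        # principal axis from the orientation of the inertia tensor
        ang = prop.orientation  # angle of major axis vs row axis
        axis = np.array([-np.cos(ang), np.sin(ang)])  # (row, col) direction
        perp = np.array([axis[1], -axis[0]])
        proj = (coords - c) @ axis
        L = (proj.max() - proj.min() + 1.0) * pixel_size
        mid = 0.5 * (proj.max() + proj.min())
        band = np.abs(proj - mid) <= 0.5
        if not band.any():
            band = np.abs(proj - mid) <= 1.0
        pproj = (coords[band] - c) @ perp
        W = (pproj.max() - pproj.min() + 1.0) * pixel_size

    return SeedShape(area=area, length=L, width=W, aspect_ratio=L / W, mode=mode)


def growth_derivative_series(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-interval growth rate and growth anisotropy with propagated SD.

    ``daily`` must have one row per day with columns ``mean_area``,
    ``sd_area``, ``mean_ar``, ``sd_ar``.  For each consecutive day pair the
    relative-change formula and its SD propagation (see module docstring)
    are applied to area (growth rate) and aspect ratio (growth anisotropy).
    """
    df = pd.DataFrame(daily)
    required = ["mean_area", "sd_area", "mean_ar", "sd_ar"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"daily table lacks columns: {missing}")
    if len(df) < 2:
        raise DomainError("need at least 2 days")
    if (df["mean_area"] <= 0).any() or (df["mean_ar"] <= 0).any():
        raise DomainError("daily means must be positive")

    mA, sA = df["mean_area"].to_numpy(float), df["sd_area"].to_numpy(float)
    mR, sR = df["mean_ar"].to_numpy(float), df["sd_ar"].to_numpy(float)
    days = df.index.to_numpy()

    rate = (mA[1:] - mA[:-1]) / mA[:-1]
    sd_rate = np.sqrt((sA[1:] / mA[1:]) ** 2 + (sA[:-1] / mA[:-1]) ** 2)
    anis = (mR[1:] - mR[:-1]) / mR[:-1]
    sd_anis = np.sqrt((sR[1:] / mR[1:]) ** 2 + (sR[:-1] / mR[:-1]) ** 2)

    return pd.DataFrame(
        {
            "day_from": days[:-1],
            "day_to": days[1:],
            "growth_rate": rate,
            "sd_growth_rate": sd_rate,
            "growth_anisotropy": anis,
            "sd_growth_anisotropy": sd_anis,
        }
    )


def cell_growth_map(
    t0: CellTessellation,
    t1: CellTessellation,
    lineage: dict[int, frozenset[int]] | None = None,
) -> pd.DataFrame:
    """Per-cell areal growth, growth anisotropy and division count.

    ``t0`` and ``t1`` must label the same face indexing (the later mesh is
    the deformed copy of the earlier one, as produced by the paired
    tessellation generator or by lineage-tracked segmentations sharing a
    mesh).  Per parent cell: areal_growth = Σ offspring areas / parent area
    − 1; the best-fit linear map between the parent's face centroids at t0
    and t1 — projected to the parent tangent plane after aligning the two
    cell normals — gives principal stretches λ1 ≥ λ2, the anisotropy λ1/λ2
    and the main-axis angle (axial, degrees from the in-plane x direction).
    """
    lineage = lineage if lineage is not None else t1.lineage
    if lineage is None:
        raise LineageError("no lineage map provided")
    if t0.mesh.n_faces != t1.mesh.n_faces:
        raise LineageError("tessellations must share face indexing")
    missing = [int(c) for c in t0.cell_ids if int(c) not in lineage]
    if missing:
        raise LineageError(f"lineage lacks parents: {missing[:10]}")

    fc0 = t0.mesh.face_centroids
    fc1 = t1.mesh.face_centroids
    areas1 = {int(c): a for c, a in zip(t1.cell_ids, t1.cell_areas)}
    rows = []
    for pos, parent in enumerate(t0.cell_ids):
        parent = int(parent)
        offspring = sorted(lineage[parent])
        faces0 = t0.cell_faces(parent)
        faces1 = np.concatenate([t1.cell_faces(c) for c in offspring])
        if set(faces0) != set(faces1):
            raise LineageError(f"offspring of cell {parent} do not cover its faces")

        area0 = float(t0.cell_areas[pos])
        area1 = float(sum(areas1[c] for c in offspring))
        flag = ""
        if area0 <= 1e-12:
            rows.append(
                {
                    "cell_id": parent,
                    "areal_growth": np.nan,
                    "anisotropy": np.nan,
                    "main_axis_deg": np.nan,
                    "n_offspring": len(offspring),
                    "flag": "degenerate",
                }
            )
            continue
        areal = area1 / area0 - 1.0

        n0 = t0.cell_normals[pos]
        p = fc0[faces0]
        q = fc1[faces0]
        # align the offspring mean normal with the parent normal
        w1 = t1.mesh.face_areas[faces0]
        n1 = (t1.mesh.face_normals[faces0] * w1[:, None]).sum(axis=0)
        n1 /= np.linalg.norm(n1)
        q = _rotate_points(q, n1, n0)

        # in-plane frame: e1 = global x projected to the tangent plane
        e1 = np.array([1.0, 0.0, 0.0]) - n0[0] * n0
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.array([0.0, 1.0, 0.0]) - n0[1] * n0
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n0, e1)
        E = np.column_stack([e1, e2])
        P = (p - p.mean(axis=0)) @ E
        Q = (q - q.mean(axis=0)) @ E

        if len(faces0) < 3 or np.linalg.matrix_rank(P) < 2:
            rows.append(
                {
                    "cell_id": parent,
                    "areal_growth": areal,
                    "anisotropy": np.nan,
                    "main_axis_deg": np.nan,
                    "n_offspring": len(offspring),
                    "flag": "degenerate",
                }
            )
            continue

        At, *_ = np.linalg.lstsq(P, Q, rcond=None)  # Q ≈ P @ At
        A = At.T
        _, svals, Vt = np.linalg.svd(A)
        lam1, lam2 = float(svals[0]), float(svals[1])
        v1 = Vt[0]  # most-stretched direction in the t0 plane
        angle = float(np.degrees(np.arctan2(v1[1], v1[0])) % 180.0)
        rows.append(
            {
                "cell_id": parent,
                "areal_growth": areal,
                "anisotropy": lam1 / lam2 if lam2 > 0 else np.nan,
                "main_axis_deg": angle,
                "n_offspring": len(offspring),
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def _rotate_points(points: np.ndarray, n_from: np.ndarray, n_to: np.ndarray) -> np.ndarray:
    """Rotate points by the minimal rotation taking n_from onto n_to."""
    c = float(np.clip(n_from @ n_to, -1.0, 1.0))
    axis = np.cross(n_from, n_to)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        return points if c > 0 else -points
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    center = points.mean(axis=0)
    return (points - center) @ R.T + center


def dimension_change_stats(
    before: pd.DataFrame, after: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent change in cell length/width/thickness between paired tables.

    ``before`` and ``after`` need columns ``cell_id``, ``length``,
    ``width``, ``thickness`` and optionally ``seed_id``.  Returns
    ``(per_cell, per_seed)``: per-cell percent changes, and their per-seed
    medians (the median, not the mean, summarizes each seed — robust to the
    occasional mis-segmented cell).
    """
    required = ["cell_id", "length", "width", "thickness"]
    for name, df in (("before", before), ("after", after)):
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table lacks columns: {missing}")

    keys = ["cell_id"] + (["seed_id"] if "seed_id" in before.columns else [])
    merged = before.merge(after, on=keys, suffixes=("_before", "_after"), how="outer", indicator=True)
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        raise JoinError(
            f"cell ids present in only one table: {unmatched['cell_id'].tolist()[:10]}"
        )
    if len(merged) == 0:
        raise JoinError("no shared cell ids")

    per_cell = merged[keys].copy()
    for dim in ("length", "width", "thickness"):
        per_cell[f"pct_change_{dim}"] = 100.0 * (
            merged[f"{dim}_after"] - merged[f"{dim}_before"]
        ) / merged[f"{dim}_before"]

    group = per_cell.groupby("seed_id") if "seed_id" in per_cell.columns else per_cell.assign(seed_id="all").groupby("seed_id")
    per_seed = group[[f"pct_change_{d}" for d in ("length", "width", "thickness")]].median()
    per_seed.columns = [c.replace("pct_change", "median_pct_change") for c in per_seed.columns]
    return per_cell, per_seed.reset_index()
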
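"""Geometric morphometrics: Procrustes superimposition, shape PCA,
inter-landmark distances, and allometric (Reist) size adjustment.

The superimposition is partial generalized Procrustes analysis (GPA):
every configuration is centred, scaled to unit centroid size, and rotated
(rotation only, determinant +1 — all photos are same-side lateral views, so
reflections are disallowed) onto the running mean shape, iterating until the
summed squared Procrustes distance stabilises.  Shape variation is then
summarised by PCA of the flattened Procrustes coordinates.

Size adjustment of the nine linear measurements follows the standard
allometric standardization to a common body length,

    Y_i = log10(M_i) + b * (log10(L_m) - log10(L_i)),

with b the pooled ordinary-least-squares slope of log10(M) on log10(L)
(fork length) and L_m the alignment length (default: mean fork length of
the retained fish).  Adjusted values are in log10(mm) units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmarks import LandmarkConfiguration

#: measurement name -> (landmark index, landmark index).  The landmark-pair
#: identities for the nine distances are a documented configuration with
#: this shipped default, consistent with the measurement names and the
#: synthetic template in :mod:`codniche.synthetic`.
DEFAULT_PAIR_MAP: dict[str, tuple[int, int]] = {
    "CP": (12, 14),    # caudal peduncle depth
    "BDP": (11, 15),   # body depth posterior
    "BDA": (8, 18),    # body depth anterior
    "PPFL": (18, 13),  # postpelvic fin length
    "HD": (3, 7),      # head depth
    "HL": (0, 5),      # head length (snout tip -> posterior operculum)
    "SL": (0, 1),      # snout length
    "EW": (1, 2),      # eye width
    "ML": (0, 4),      # maxilla length
}

#: snout tip -> posterior end of the caudal peduncle (fork length)
FORK_LENGTH_PAIR: tuple[int, int] = (0, 13)

MEASUREMENTS = tuple(DEFAULT_PAIR_MAP)


class DegenerateShapeError(ValueError):
    pass


def centroid_size(coords: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances from the centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1 or len(coords) < 2:
        raise DegenerateShapeError("need at least 2 landmarks")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        raise DegenerateShapeError("all landmarks coincident")
    return cs


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||source @ R - target||_F, both centred."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    # force a proper rotation: flip the singular direction with least weight
    flip = np.diag([1.0, d])
    return u @ flip @ vt


@dataclass
class AlignedShapes:
    """Result of GPA: unit-centroid-size shape coordinates and their mean."""

    procrustes_coords: np.ndarray  # (n, k, 2), dimensionless
    mean_shape: np.ndarray         # (k, 2)
    centroid_sizes: np.ndarray     # (n,), original units (mm)
    iterations_used: int
    converged: bool

    @property
    def n_specimens(self) -> int:
        return len(self.procrustes_coords)


def gpa(
    configs: list[LandmarkConfiguration] | list[np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 100,
    tangent_project: bool = True,
) -> AlignedShapes:
    """Partial generalized Procrustes analysis.

    Iteratively centres, unit-scales and rotates every configuration onto
    the running mean shape (itself re-standardized each pass) until the
    change in summed squared Procrustes distance is below ``tol``.
    Non-convergence within ``max_iter`` is flagged, not fatal.  With
    ``tangent_project`` the aligned shapes are orthogonally projected onto
    the tangent plane at the mean.
    """
    arrays = [
        np.asarray(c.coords if isinstance(c, LandmarkConfiguration) else c, dtype=float)
        for c in configs
    ]
    if not arrays:
        raise ValueError("no configurations to align")
    k = arrays[0].shape[0]
    if any(a.shape != (k, 2) for a in arrays):
        raise ValueError("all configurations must share the same landmark count")

    sizes = np.array([centroid_size(a) for a in arrays])
    shapes = np.stack([(a - a.mean(axis=0)) / s for a, s in zip(arrays, sizes)])

    def standardize(shape: np.ndarray) -> np.ndarray:
        shape = shape - shape.mean(axis=0)
        return shape / np.sqrt(np.sum(shape**2))

    mean = standardize(shapes[0])
    prev_ss = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(shapes)):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], mean)
        mean = standardize(shapes.mean(axis=0))
        ss = float(np.sum((shapes - mean) ** 2))
        if abs(prev_ss - ss) < tol:
            converged = True
            break
        prev_ss = ss

    if tangent_project:
        m = mean.ravel()  # unit norm by construction
        flat = shapes.reshape(len(shapes), -1)
        coefs = flat @ m
        flat = flat - np.outer(coefs - 1.0, m)
        shapes = flat.reshape(shapes.shape)
        mean = standardize(shapes.mean(axis=0))

    return AlignedShapes(
        procrustes_coords=shapes,
        mean_shape=mean,
        centroid_sizes=sizes,
        iterations_used=iterations,
        converged=converged,
    )


@dataclass
class ShapePCA:
    scores: np.ndarray           # (n, n_pc)
    eigenvalues: np.ndarray      # (n_pc,)
    percent_variance: np.ndarray  # sums to 100
    eigenvectors: np.ndarray     # (n_pc, 2k) rows
    mean_flat: np.ndarray        # (2k,)
    extreme_shapes: list[dict]   # per PC: min/max shapes + displacements


def shape_pca(aligned: AlignedShapes) -> ShapePCA:
    """Centred PCA of the flattened Procrustes coordinates.

    For each component the extreme shapes (mean +/- the observed score
    range along that component) are reported as per-landmark displacement
    vectors, which is the numeric content of a deformation display.
    """
    n = aligned.n_specimens
    if n < 3:
        raise ValueError(f"shape PCA needs >= 3 specimens, got {n}")
    flat = aligned.procrustes_coords.reshape(n, -1)
    mean_flat = flat.mean(axis=0)
    centered = flat - mean_flat
    # SVD of the centred data = eigendecomposition of the covariance
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    percent = (
        100.0 * eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    )
    scores = centered @ vt.T

    k = aligned.mean_shape.shape[0]
    extremes = []
    for j in range(len(eigenvalues)):
        lo, hi = scores[:, j].min(), scores[:, j].max()
        shape_min = (mean_flat + lo * vt[j]).reshape(k, 2)
        shape_max = (mean_flat + hi * vt[j]).reshape(k, 2)
        extremes.append(
            {
                "pc": j + 1,
                "shape_min": shape_min,
                "shape_max": shape_max,
                "displacement_min": shape_min - aligned.mean_shape,
                "displacement_max": shape_max - aligned.mean_shape,
            }
        )
    return ShapePCA(scores, eigenvalues, percent, vt, mean_flat, extremes)


def interlandmark_distances(
    config: LandmarkConfiguration | np.ndarray,
    pair_map: dict[str, tuple[int, int]] | None = None,
) -> dict[str, float]:
    """The nine named Euclidean distances plus fork length, in mm.

    The configuration must already be in mm (photo scale applied).
    """
    coords = np.asarray(
        config.coords if isinstance(config, LandmarkConfiguration) else config,
        dtype=float,
    )
    pair_map = dict(pair_map or DEFAULT_PAIR_MAP)
    out: dict[str, float] = {}
    for name, (i, j) in {**pair_map, "fork_length_mm": FORK_LENGTH_PAIR}.items():
        if not (0 <= i < len(coords) and 0 <= j < len(coords)):
            raise IndexError(f"{name}: landmark pair ({i}, {j}) out of range for {len(coords)} landmarks")
        out[name] = float(np.linalg.norm(coords[i] - coords[j]))
    return out


def measurement_table(
    configs: list[LandmarkConfiguration],
    pair_map: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Raw measurement table: one row per specimen, distances in mm."""
    rows = []
    for cfg in configs:
        d = interlandmark_distances(cfg, pair_map)
        d["specimen_id"] = cfg.specimen_id
        if cfg.year is not None:
            d["year"] = cfg.year
        rows.append(d)
    df = pd.DataFrame(rows)
    front = ["specimen_id", "fork_length_mm"]
    return df[front + [c for c in df.columns if c not in front]]


def reist_adjust(
    table: pd.DataFrame,
    measurements: tuple[str, ...] = MEASUREMENTS,
    length_col: str = "fork_length_mm",
    l_m: float | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Allometric size adjustment of linear measurements to a common length.

    Per measurement, fits the pooled OLS slope b of log10(M) on log10(L)
    across all fish and returns adjusted values
    ``Y = log10(M) + b (log10(L_m) - log10(L))`` in new ``<name>_adj``
    columns (log10(mm) units), along with the slope per measurement.
    ``l_m`` defaults to the mean fork length of the fish in ``table``;
    pass an override (e.g. 368.1) to align to an external length.
    """
    if len(table) < 3:
        raise ValueError("slope estimation needs >= 3 specimens")
    L = table[length_col].to_numpy(dtype=float)
    if np.any(L <= 0):
        raise ValueError("fork lengths must be positive")
    logL = np.log10(L)
    if l_m is None:
        l_m = float(L.mean())
    log_lm = np.log10(l_m)
    degenerate = np.ptp(logL) == 0
    if degenerate and not np.isclose(l_m, L[0]):
        # correction term nonzero but the slope is unidentifiable
        raise ValueError("zero variance in log10 fork length; slope undefined")

    out = table.copy()
    slopes = {}
    for m in measurements:
        M = table[m].to_numpy(dtype=float)
        if np.any(M <= 0):
            raise ValueError(f"{m}: measurements must be positive")
        logM = np.log10(M)
        # all fish already at the alignment length: correction is exactly 0
        b = 0.0 if degenerate else float(np.polyfit(logL, logM, 1)[0])
        slopes[m] = b
        out[f"{m}_adj"] = logM + b * (log_lm - logL)
    out.attrs["l_m_mm"] = l_m
    out.attrs["adjusted_units"] = "log10(mm)"
    return out, pd.Series(slopes, name="slope_b")
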
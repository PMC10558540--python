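"""Procrustes machinery for 3D landmark configurations.

Centroid size, ordinary Procrustes alignment (OPA) onto a fixed reference,
generalized Procrustes analysis (GPA) across a sample, bilateral
symmetrization, thin-plate-spline warping and per-vertex area-change maps.

Rotations are always proper (determinant +1): reflections are corrected by
the usual sign fix on the smallest singular value of the cross-covariance
matrix, so a mirrored configuration keeps a positive residual rather than
being silently flipped.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import RBFInterpolator

from .datatypes import (
    LandmarkConfiguration,
    ProcrustesResult,
    SpecimenSet,
    Triangulation,
)
from .errors import (
    ConfigurationError,
    ConvergenceWarning,
    DimensionError,
    SingularGeometryError,
    SingularSystemError,
    UndefinedRatioError,
)

__all__ = [
    "centroid_size",
    "opa_align",
    "gpa",
    "symmetrize",
    "tps_warp",
    "area_change_map",
]


# ---------------------------------------------------------------- centroid size

def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared distances of points to their centroid.

    Accepts a LandmarkConfiguration or a bare (n, 3) array. Returns 0 only
    when all points coincide.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise DimensionError("centroid_size needs a non-empty (n, d) array")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered ** 2)))


def _centroid_sizes(stack: np.ndarray) -> np.ndarray:
    """Centroid sizes of a (s, n, 3) stack."""
    centered = stack - stack.mean(axis=1, keepdims=True)
    return np.sqrt(np.einsum("sij,sij->s", centered, centered))


# ------------------------------------------------------------------------- OPA

def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||source @ R - target||, both pre-centered."""
    h = source.T @ target
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if d < 0:
        u = u.copy()
        u[:, -1] *= -1.0
        s = s.copy()
        s[-1] *= -1.0
    return u @ vt, s


def _batched_rotations(sources: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotations aligning each (n,3) block of a (s,n,3) stack to target."""
    h = np.einsum("sni,nj->sij", sources, target)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("sij,sjk->sik", u, vt)))
    u = u.copy()
    u[:, :, -1] *= d[:, None]
    return np.einsum("sij,sjk->sik", u, vt)


def opa_align(config, reference: np.ndarray, allow_scaling: bool = False):
    """Ordinary Procrustes superimposition of one configuration onto a reference.

    Translates the configuration into the reference's centroid frame,
    optionally scales, and rotates (proper rotation only) to minimize the
    summed squared distance to the reference.

    Returns ``(aligned, residual)`` where residual is the root summed squared
    distance after the fit.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if coords.shape != reference.shape:
        raise DimensionError(
            f"configuration shape {coords.shape} != reference shape {reference.shape}"
        )
    a = coords - coords.mean(axis=0)
    ref_centroid = reference.mean(axis=0)
    b = reference - ref_centroid
    if np.linalg.matrix_rank(a, tol=1e-10 * max(1.0, np.abs(a).max())) < 2:
        raise SingularGeometryError("configuration is rank-deficient; cannot align")
    rot, s = _optimal_rotation(a, b)
    if allow_scaling:
        denom = np.sum(a ** 2)
        scale = float(np.sum(s)) / denom
    else:
        scale = 1.0
    aligned = scale * (a @ rot) + ref_centroid
    residual = float(np.sqrt(np.sum((aligned - reference) ** 2)))
    return aligned, residual


# ------------------------------------------------------------------------- GPA

def _gpa_array(
    stack: np.ndarray,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
):
    """GPA on a raw (s, n, 3) stack; core routine shared with the mapping loop.

    Returns (aligned, centroid_sizes, consensus, n_iterations, final_change).
    Raises SingularGeometryError if any specimen has (near-)zero size.
    """
    stack = np.asarray(stack, dtype=float)
    s, n, _ = stack.shape
    centered = stack - stack.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.einsum("sij,sij->s", centered, centered))
    if np.any(sizes <= 1e-12):
        bad = int(np.argmin(sizes))
        raise SingularGeometryError(f"specimen {bad} has zero centroid size")
    work = centered / sizes[:, None, None] if scale else centered
    consensus = work.mean(axis=0)
    if scale:
        cs = np.sqrt(np.sum(consensus ** 2))
        if cs <= 1e-12:
            raise SingularGeometryError("degenerate consensus (zero size)")
        consensus = consensus / cs
    final_change = np.inf
    n_iter = 0
    aligned = work
    for n_iter in range(1, max_iter + 1):
        rots = _batched_rotations(work, consensus)
        aligned = np.einsum("snj,sjk->snk", work, rots)
        new_consensus = aligned.mean(axis=0)
        if scale:
            cs = np.sqrt(np.sum(new_consensus ** 2))
            new_consensus = new_consensus / cs
        final_change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if final_change < tol:
            break
    return aligned, sizes, aligned.mean(axis=0), n_iter, final_change


def gpa(
    specimens: SpecimenSet,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes analysis of a specimen set.

    Iteratively centers, optionally scales to unit centroid size, and rotates
    every specimen to the running consensus until the root-mean-square change
    of the consensus falls below ``tol``. Original centroid sizes (mm) are
    stored regardless of scaling. Emits a ConvergenceWarning if ``max_iter``
    is reached first.
    """
    if specimens.n_specimens < 2:
        raise DimensionError("GPA needs at least 2 specimens")
    for i in range(specimens.n_specimens):
        c = specimens.coords[i] - specimens.coords[i].mean(axis=0)
        if np.linalg.matrix_rank(c, tol=1e-10 * max(1.0, np.abs(c).max())) < 2:
            raise SingularGeometryError(
                f"specimen {specimens.specimen_ids[i]!r} is degenerate (rank < 2)"
            )
    aligned, sizes, consensus, n_iter, change = _gpa_array(
        specimens.coords, scale=scale, tol=tol, max_iter=max_iter
    )
    if change >= tol:
        warnings.warn(
            f"GPA stopped at max_iter={max_iter} with consensus change {change:.3e}",
            ConvergenceWarning,
        )
    return ProcrustesResult(
        aligned=aligned,
        centroid_sizes=sizes,
        consensus=consensus,
        scaled=scale,
        n_iterations=n_iter,
        final_change=change,
    )


# --------------------------------------------------------------- symmetrization

def _reflect_relabel(coords: np.ndarray, pairs, midline) -> np.ndarray:
    """Mirror about the first axis and swap left/right labels."""
    out = coords * np.array([-1.0, 1.0, 1.0])
    relabeled = out.copy()
    for left, right in pairs:
        relabeled[left] = out[right]
        relabeled[right] = out[left]
    return relabeled


def symmetrize_configuration(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Remove the asymmetric shape component from one configuration.

    The reflected, pair-relabeled copy is OPA-aligned (no scaling) to the
    original and the two are averaged. The result is exactly invariant under
    reflect-and-relabel: the cross-covariance of the mirrored copy with the
    original is F @ S with S symmetric (F = diag(-1,1,1)), which forces the
    optimal rotation R to satisfy F R' F = R, and that identity makes the
    average a fixed point of the reflection.
    """
    if not config.pairs and not config.midline:
        raise ConfigurationError("symmetrize requires a bilateral pairing table")
    mirrored = _reflect_relabel(config.coords, config.pairs, config.midline)
    aligned, _ = opa_align(mirrored, config.coords, allow_scaling=False)
    return config.with_coords(0.5 * (config.coords + aligned))


def symmetrize(specimens: SpecimenSet) -> SpecimenSet:
    """Symmetrize every specimen in a set (see symmetrize_configuration)."""
    if not specimens.pairs and not specimens.midline:
        raise ConfigurationError("symmetrize requires a bilateral pairing table")
    out = np.empty_like(specimens.coords)
    for i in range(specimens.n_specimens):
        coords = specimens.coords[i]
        mirrored = _reflect_relabel(coords, specimens.pairs, specimens.midline)
        aligned, _ = opa_align(mirrored, coords, allow_scaling=False)
        out[i] = 0.5 * (coords + aligned)
    return specimens.with_coords(out)


# ------------------------------------------------------------------- TPS warp

def tps_warp(source_pts: np.ndarray, target_pts: np.ndarray, query_pts: np.ndarray) -> np.ndarray:
    """3D thin-plate-spline warp: exact interpolant source -> target at queries.

    Uses the 3D biharmonic radial kernel U(r) = r plus an affine term, fitted
    with scipy's RBF machinery (kernel sign conventions are absorbed by the
    fitted coefficients). Exactly reproduces the targets on the source points.
    """
    source = np.asarray(source_pts, dtype=float)
    target = np.asarray(target_pts, dtype=float)
    query = np.asarray(query_pts, dtype=float)
    if source.shape != target.shape:
        raise DimensionError("source and target must have the same shape")
    if source.shape[0] < 4:
        raise DimensionError("TPS in 3D needs at least 4 source points")
    try:
        interp = RBFInterpolator(source, target, kernel="linear", degree=1)
        return interp(query)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise SingularSystemError(f"TPS system is singular: {exc}") from exc


# ------------------------------------------------------------- area-change map

def _vertex_areas(coords: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex area: one third of the summed areas of incident triangles."""
    v0, v1, v2 = coords[faces[:, 0]], coords[faces[:, 1]], coords[faces[:, 2]]
    tri_areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    vert = np.zeros(coords.shape[0])
    for col in range(3):
        np.add.at(vert, faces[:, col], tri_areas / 3.0)
    return vert


def area_change_map(
    reference: LandmarkConfiguration | np.ndarray,
    target: LandmarkConfiguration | np.ndarray,
    faces: Triangulation,
) -> np.ndarray:
    """Per-vertex area-change ratio of a target shape against a reference.

    1 means unchanged, >1 locally expanded, <1 locally contracted. Raises if
    any vertex has no incident face (its ratio would be 0/0).
    """
    ref = reference.coords if isinstance(reference, LandmarkConfiguration) else np.asarray(reference, dtype=float)
    tgt = target.coords if isinstance(target, LandmarkConfiguration) else np.asarray(target, dtype=float)
    if ref.shape != tgt.shape:
        raise DimensionError("reference and target must share a point scheme")
    faces.validate_against(ref.shape[0])
    incident = np.zeros(ref.shape[0], dtype=int)
    np.add.at(incident, faces.faces.ravel(), 1)
    orphans = np.nonzero(incident == 0)[0]
    if orphans.size:
        raise UndefinedRatioError(f"vertices with no incident face: {orphans.tolist()}")
    return _vertex_areas(tgt, faces.faces) / _vertex_areas(ref, faces.faces)
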
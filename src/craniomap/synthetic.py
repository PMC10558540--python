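"""Synthetic landmark datasets with known ground truth.

The generator emulates the statistical structure of a cranial sexual-
dimorphism study: a smooth base 3D shape sampled quasi-uniformly (an
ellipsoid stands in for the cranial vault), a localized mean-shape
difference between two groups (F/M), group size dimorphism on the centroid-
size scale, a shared or diverging allometric shape-size regression, and
isotropic digitization noise applied in the specimen's own frame after a
random rigid motion. Every planted parameter is recorded so that pipeline
stages can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .datatypes import LandmarkConfiguration, SpecimenSet, Triangulation
from .errors import DimensionError, SchemaError, SingularGeometryError

__all__ = [
    "SyntheticSpec",
    "make_base_shape",
    "simulate",
    "patch_indices",
    "similarity_complement_basis",
    "vectors_at_angle",
    "planted_variance_dataset",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


# ------------------------------------------------------------------ base shape

def make_base_shape(
    n_points: int,
    semi_axes: tuple[float, float, float] = (60.0, 75.0, 55.0),
    seed: int = 0,
) -> tuple[LandmarkConfiguration, Triangulation]:
    """Quasi-uniform, exactly bilaterally symmetric points on an ellipsoid.

    A deterministic spiral lattice covers the x > 0 hemisphere; its mirror
    image across the x = 0 plane supplies the left side, and an evenly
    spaced ring on the x = 0 ellipse supplies the midline, so the
    configuration is exactly invariant under reflect-and-relabel. Faces come
    from the convex hull (the ellipsoid is convex). The centroid is moved to
    the origin; semi-axes are in mm.
    """
    if n_points < 16:
        raise DimensionError("base shape needs >= 16 points")
    a, b, c = (float(v) for v in semi_axes)
    n_mid = 8 + (n_points % 2)
    n_pairs = (n_points - n_mid) // 2
    # hemisphere spiral lattice, all x > 0
    i = np.arange(n_pairs)
    x = 1.0 - (i + 0.5) / n_pairs          # in (0, 1)
    r = np.sqrt(1.0 - x ** 2)
    psi = i * GOLDEN_ANGLE
    right = np.column_stack([x, r * np.cos(psi), r * np.sin(psi)])
    left = right * np.array([-1.0, 1.0, 1.0])
    theta = 2.0 * np.pi * (np.arange(n_mid) + 0.5) / n_mid
    mid = np.column_stack([np.zeros(n_mid), np.cos(theta), np.sin(theta)])
    unit = np.vstack([right, left, mid])
    # re-center on the unit sphere: alternate mean-shift and radial
    # reprojection (both preserve the x-mirror pairing: a point and its
    # mirror share y, z and norm, midline points keep x = 0)
    for _ in range(100):
        centroid = unit.mean(axis=0)
        centroid[0] = 0.0  # exact: x-sums cancel by construction
        if np.abs(centroid).max() <= 1e-14:
            break
        unit = unit - centroid
        unit = unit / np.linalg.norm(unit, axis=1, keepdims=True)
    coords = unit * np.array([a, b, c])
    pairs = tuple((n_pairs + j, j) for j in range(n_pairs))  # (left, right)
    midline = tuple(range(2 * n_pairs, 2 * n_pairs + n_mid))
    point_ids = (
        [f"R{j:03d}" for j in range(n_pairs)]
        + [f"L{j:03d}" for j in range(n_pairs)]
        + [f"MID{j:03d}" for j in range(n_mid)]
    )
    config = LandmarkConfiguration(
        point_ids=tuple(point_ids), coords=coords, pairs=pairs, midline=midline
    )
    hull = ConvexHull(coords)
    faces = Triangulation(faces=hull.simplices)
    return config, faces


def _vertex_normals(coords: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Outward vertex normals: area-weighted mean of incident face normals."""
    v0, v1, v2 = coords[faces[:, 0]], coords[faces[:, 1]], coords[faces[:, 2]]
    fn = np.cross(v1 - v0, v2 - v0)  # length = 2x area
    # orient every face normal outward (centroid at origin for the base shape)
    centers = (v0 + v1 + v2) / 3.0
    flip = np.sign(np.einsum("ij,ij->i", fn, centers - coords.mean(axis=0)))
    flip[flip == 0] = 1.0
    fn = fn * flip[:, None]
    normals = np.zeros_like(coords)
    for col in range(3):
        np.add.at(normals, faces[:, col], fn)
    norms = np.linalg.norm(normals, axis=1)
    if np.any(norms <= 1e-12):
        raise SingularGeometryError("degenerate vertex: outward normal undefined")
    return normals / norms[:, None]


def mean_nearest_neighbor_distance(coords: np.ndarray) -> float:
    """Mean distance of each point to its nearest neighbor (the inter-point
    spacing used to scale planted effect sizes)."""
    from scipy.spatial.distance import cdist

    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def patch_indices(config: LandmarkConfiguration, center_index: int, n: int) -> np.ndarray:
    """The n points nearest to a center point (inclusive): a contiguous patch."""
    d = np.linalg.norm(config.coords - config.coords[center_index], axis=1)
    order = np.lexsort((np.arange(len(d)), d))
    return np.sort(order[:n])


# --------------------------------------------------- allometry vector helpers

def similarity_complement_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity tangent space at a shape.

    Columns span translations (3), infinitesimal rotations (3) and uniform
    scaling (1) of the flattened (3n) coordinate space. Planted allometric
    displacement vectors are projected off this 7-dim space so that GPA
    (which quotients out exactly these transformations) preserves their
    directions and mutual angles to first order.
    """
    x = np.asarray(base, dtype=float)
    n = x.shape[0]
    centered = x - x.mean(axis=0)
    vecs = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = 1.0
        vecs.append(t.ravel())
    gens = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], dtype=float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
    ]
    for g in gens:
        vecs.append((centered @ g.T).ravel())
    vecs.append(centered.ravel())
    basis, _ = np.linalg.qr(np.column_stack(vecs))
    return basis


def _project_off(v: np.ndarray, basis: np.ndarray) -> np.ndarray:
    return v - basis @ (basis.T @ v)


def vectors_at_angle(
    base: np.ndarray, angle_deg: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit displacement fields at an exact mutual angle, orthogonal to the
    similarity tangent space of ``base``. Returned flattened (3n,)."""
    rng = np.random.default_rng(seed)
    basis = similarity_complement_basis(np.asarray(base, dtype=float))
    dim = basis.shape[0]
    v = _project_off(rng.standard_normal(dim), basis)
    v /= np.linalg.norm(v)
    w = _project_off(rng.standard_normal(dim), basis)
    w -= v * (v @ w)
    w /= np.linalg.norm(w)
    theta = np.radians(angle_deg)
    u = np.cos(theta) * v + np.sin(theta) * w
    return v, u


# -------------------------------------------------------------------- simulate

@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated dimorphism study.

    Defaults encode the study conditions used throughout the test-bench:
    150 points on a skull-proportioned ellipsoid, 60 specimens per sex,
    male-biased centroid-size dimorphism of about 5% (log-normal sizes), a
    weak shared allometry, and 0.3 mm isotropic digitization noise.
    ``effect_size`` is the planted group mean-shape displacement as a
    fraction of the mean nearest-neighbor spacing, applied to group M at
    ``effect_indices`` along ``effect_direction`` ('normal' = outward vertex
    normal, or a fixed 3-vector).
    """

    n_points: int = 150
    n_per_group: tuple[int, int] = (60, 60)   # (n_F, n_M)
    semi_axes: tuple[float, float, float] = (60.0, 75.0, 55.0)
    effect_indices: tuple[int, ...] = ()
    effect_size: float = 0.0
    effect_direction: str | tuple[float, float, float] = "normal"
    size_means: tuple[float, float] = (760.0, 800.0)  # centroid size, mm
    size_sds: tuple[float, float] = (30.0, 30.0)
    allometry_strength: float = 0.0
    allometry_angle_deg: float = 0.0          # divergence between F and M vectors
    noise_sd: float = 0.3                     # digitization error, mm per coordinate
    individual_sd: float = 0.0                # biological inter-individual shape
                                              # variation, mm per coordinate
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group[0] < 1 or self.n_per_group[1] < 1:
            raise SchemaError("both groups must be non-empty")
        if min(self.size_sds) < 0 or self.noise_sd < 0:
            raise SchemaError("standard deviations must be >= 0")
        for idx in self.effect_indices:
            if not 0 <= idx < self.n_points:
                raise SchemaError(f"effect index {idx} out of range")


def simulate(spec: SyntheticSpec) -> tuple[SpecimenSet, dict]:
    """Draw a SpecimenSet from a SyntheticSpec; returns (specimens, ground_truth).

    Per specimen: start from the unit-size base shape; displace group-M
    points in ``effect_indices`` by the planted effect; draw log centroid
    size from the group's log-normal; add the allometric displacement
    allometry_strength * (log size - mean log size) * group vector; scale to
    the drawn size; optionally add the individual's own anatomical deviation
    (sd = individual_sd, shared by its replicates); apply a random rotation
    and translation; add isotropic digitization noise. With
    ``n_replicates > 1`` each specimen is re-digitized r times (one
    underlying configuration, fresh noise) for repeatability studies.
    """
    rng = np.random.default_rng(spec.seed)
    base_config, faces = make_base_shape(spec.n_points, spec.semi_axes, seed=spec.seed)
    base = base_config.coords
    n_actual = base.shape[0]
    cs = np.sqrt(np.sum((base - base.mean(axis=0)) ** 2))
    unit = base / cs
    spacing = mean_nearest_neighbor_distance(unit)

    # planted group-M displacement field (on the unit-size shape)
    effect_field = np.zeros_like(unit)
    eff_idx = np.asarray(spec.effect_indices, dtype=int)
    if eff_idx.size and spec.effect_size != 0.0:
        if spec.effect_direction == "normal":
            normals = _vertex_normals(unit, faces.faces)
            dirs = normals[eff_idx]
        else:
            vec = np.asarray(spec.effect_direction, dtype=float)
            dirs = np.tile(vec / np.linalg.norm(vec), (eff_idx.size, 1))
        effect_field[eff_idx] = spec.effect_size * spacing * dirs

    # per-group allometry fields, orthogonal to the similarity tangent space
    v_f, v_m = vectors_at_angle(unit, spec.allometry_angle_deg, seed=spec.seed)
    allo = {"F": v_f.reshape(n_actual, 3), "M": v_m.reshape(n_actual, 3)}

    # log-normal sizes: ln S ~ N(ln mean, sd/mean) per group (delta method)
    mu = {g: np.log(m) for g, m in zip("FM", spec.size_means)}
    sig = {g: s / m for g, (s, m) in zip("FM", zip(spec.size_sds, spec.size_means))}

    n_f, n_m = spec.n_per_group
    labels = ["F"] * n_f + ["M"] * n_m
    log_sizes = np.concatenate(
        [rng.normal(mu["F"], sig["F"], n_f), rng.normal(mu["M"], sig["M"], n_m)]
    )
    mean_log = log_sizes.mean()

    coords_out, ids, sexes, reps = [], [], [], []
    for i, (g, ls) in enumerate(zip(labels, log_sizes)):
        shape = unit.copy()
        if g == "M":
            shape = shape + effect_field
        shape = shape + spec.allometry_strength * (ls - mean_log) * allo[g]
        shape = shape * np.exp(ls)
        if spec.individual_sd > 0:
            # the individual's own anatomy, shared by all its replicates
            shape = shape + rng.normal(0.0, spec.individual_sd, size=shape.shape)
        # one random rigid motion per individual; replicates re-noise it
        rot = _random_rotation(rng)
        trans = rng.normal(0.0, 50.0, size=3)
        placed = shape @ rot.T + trans
        for r in range(spec.n_replicates):
            noisy = placed + rng.normal(0.0, spec.noise_sd, size=placed.shape)
            coords_out.append(noisy)
            if spec.n_replicates > 1:
                ids.append(f"S{i:03d}_r{r}")
                reps.append(f"S{i:03d}")
            else:
                ids.append(f"S{i:03d}")
                reps.append(None)
            sexes.append(g)

    specimens = SpecimenSet(
        coords=np.stack(coords_out),
        specimen_ids=tuple(ids),
        sex=tuple(sexes),
        replicate_of=tuple(reps),
        point_ids=base_config.point_ids,
        roles=base_config.roles,
        pairs=base_config.pairs,
        midline=base_config.midline,
    )
    ground_truth = {
        "spec": spec,
        "base_config": base_config,
        "faces": faces,
        "effect_indices": eff_idx.copy(),
        "effect_field": effect_field,
        "allometry_vectors": {g: allo[g].ravel().copy() for g in allo},
        "allometry_angle_deg": spec.allometry_angle_deg,
        "log_sizes": log_sizes,
        "mean_nn_spacing_unit": spacing,
    }
    return specimens, ground_truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


# ------------------------------------------------- planted variance-fraction data

def planted_variance_dataset(
    n: int,
    n_vars: int,
    frac_size: float,
    frac_sex: float,
    seed: int = 0,
):
    """Response matrix with exact expected variance fractions for size and sex.

    Builds Y = sqrt(frac_size) * z * v1 + sqrt(frac_sex) * s * v2 + E where
    z is a standardized size, s a balanced -1/+1 sex code, v1 _|_ v2 unit
    vectors, and E isotropic noise carrying the residual variance budget.
    Returns (Y, size_values, sex_labels).
    """
    if frac_size + frac_sex >= 1.0:
        raise ValueError("variance fractions must sum to < 1")
    rng = np.random.default_rng(seed)
    v1 = np.zeros(n_vars)
    v1[0] = 1.0
    v2 = np.zeros(n_vars)
    v2[1] = 1.0
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std()
    sex = np.array(["F", "M"] * (n // 2) + ["F"] * (n % 2), dtype=object)
    s = np.where(sex == "M", 1.0, -1.0)
    s = s - s.mean()
    s = s / np.sqrt(np.mean(s ** 2))
    resid_var = (1.0 - frac_size - frac_sex) / n_vars
    e = rng.normal(0.0, np.sqrt(resid_var), size=(n, n_vars))
    y = (
        np.sqrt(frac_size) * np.outer(z, v1)
        + np.sqrt(frac_sex) * np.outer(s, v2)
        + e
    )
    return y, z, sex
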
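"""Core in-memory containers for landmark data and analysis results.

A *landmark configuration* is an ordered set of named 3D points digitized on
one specimen; points are either fixed anatomical landmarks or surface
semilandmarks, and bilateral structures carry a left/right pairing plus a set
of midline (midsagittal) points. A *specimen set* stacks configurations that
share one point scheme together with per-specimen metadata (sex, population,
replicate structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DimensionError, SchemaError, SingularGeometryError

ROLE_LANDMARK = "landmark"
ROLE_SEMILANDMARK = "semilandmark"


def _as_coords(coords) -> np.ndarray:
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise DimensionError(f"coordinates must be (n_points, 3), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise SchemaError("non-finite coordinate encountered")
    return arr


@dataclass(frozen=True)
class Triangulation:
    """Triangle faces over a point scheme, as (m, 3) integer vertex indices."""

    faces: np.ndarray

    def __post_init__(self):
        faces = np.asarray(self.faces, dtype=int)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise DimensionError(f"faces must be (m, 3), got {faces.shape}")
        if np.any(faces < 0):
            raise SchemaError("negative vertex index in faces")
        for f in faces:
            if len(set(f.tolist())) != 3:
                raise SchemaError(f"face {f.tolist()} has repeated vertices")
        object.__setattr__(self, "faces", faces)

    def validate_against(self, n_points: int) -> None:
        if self.faces.size and self.faces.max() >= n_points:
            raise SchemaError(
                f"face index {int(self.faces.max())} out of range for {n_points} points"
            )


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's ordered 3D point set (mm) with roles and bilateral pairing.

    ``pairs`` lists (left_index, right_index) bilateral pairs; ``midline``
    indexes points lying on the midsagittal plane. Every point may appear in
    at most one pair or in the midline set. Indices are 0-based.
    """

    point_ids: tuple[str, ...]
    coords: np.ndarray
    roles: tuple[str, ...] = ()
    pairs: tuple[tuple[int, int], ...] = ()
    midline: tuple[int, ...] = ()

    def __post_init__(self):
        coords = _as_coords(self.coords)
        n = coords.shape[0]
        if n < 4:
            raise DimensionError(f"a configuration needs >= 4 points, got {n}")
        point_ids = tuple(str(p) for p in self.point_ids)
        if len(point_ids) != n:
            raise SchemaError(f"{len(point_ids)} point ids for {n} points")
        roles = tuple(self.roles) if self.roles else (ROLE_SEMILANDMARK,) * n
        if len(roles) != n:
            raise SchemaError(f"{len(roles)} roles for {n} points")
        for r in roles:
            if r not in (ROLE_LANDMARK, ROLE_SEMILANDMARK):
                raise SchemaError(f"unknown point role {r!r}")
        # collinearity: centered coordinates must span at least a plane... rank>=2
        centered = coords - coords.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(centered).max())) < 2:
            raise SingularGeometryError("all points are collinear or coincident")
        seen: set[int] = set()
        pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        for left, right in pairs:
            if not (0 <= left < n and 0 <= right < n):
                raise SchemaError(f"pair ({left}, {right}) out of range")
            if left == right:
                raise SchemaError(f"pair ({left}, {right}) has left == right")
            for idx in (left, right):
                if idx in seen:
                    raise SchemaError(f"point {idx} appears in more than one pair")
                seen.add(idx)
        midline = tuple(int(i) for i in self.midline)
        for idx in midline:
            if not 0 <= idx < n:
                raise SchemaError(f"midline index {idx} out of range")
            if idx in seen:
                raise SchemaError(f"point {idx} is both paired and midline")
            seen.add(idx)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "point_ids", point_ids)
        object.__setattr__(self, "roles", roles)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "midline", midline)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass(frozen=True)
class SpecimenSet:
    """Stacked landmark configurations sharing one point scheme, plus metadata.

    ``coords`` is (n_specimens, n_points, 3) in mm. ``sex`` holds 'F'/'M' (or
    None when unknown); ``replicate_of`` links repeated digitizations of the
    same individual for repeatability studies.
    """

    coords: np.ndarray
    specimen_ids: tuple[str, ...]
    sex: tuple[str | None, ...]
    point_ids: tuple[str, ...]
    population: tuple[str | None, ...] = ()
    replicate_of: tuple[str | None, ...] = ()
    roles: tuple[str, ...] = ()
    pairs: tuple[tuple[int, int], ...] = ()
    midline: tuple[int, ...] = ()

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise DimensionError(f"coords must be (n_specimens, n_points, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise SchemaError("non-finite coordinate encountered")
        s, n = coords.shape[0], coords.shape[1]
        ids = tuple(str(i) for i in self.specimen_ids)
        if len(ids) != s:
            raise SchemaError(f"{len(ids)} specimen ids for {s} specimens")
        sex = tuple(self.sex)
        if len(sex) != s:
            raise SchemaError(f"{len(sex)} sex labels for {s} specimens")
        for lab in sex:
            if lab is not None and lab not in ("F", "M"):
                raise SchemaError(f"sex label must be 'F', 'M' or None, got {lab!r}")
        pop = tuple(self.population) if self.population else (None,) * s
        if len(pop) != s:
            raise SchemaError("population length mismatch")
        rep = tuple(self.replicate_of) if self.replicate_of else (None,) * s
        if len(rep) != s:
            raise SchemaError("replicate_of length mismatch")
        # specimen ids unique except that replicates share replicate_of
        non_rep = [i for i, r in zip(ids, rep) if r is None]
        if len(set(non_rep)) != len(non_rep):
            dup = sorted({i for i in non_rep if non_rep.count(i) > 1})
            raise SchemaError(f"duplicate specimen ids: {dup}")
        pids = tuple(str(p) for p in self.point_ids)
        if len(pids) != n:
            raise SchemaError(f"{len(pids)} point ids for {n} points")
        roles = tuple(self.roles) if self.roles else (ROLE_SEMILANDMARK,) * n
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "specimen_ids", ids)
        object.__setattr__(self, "sex", sex)
        object.__setattr__(self, "population", pop)
        object.__setattr__(self, "replicate_of", rep)
        object.__setattr__(self, "point_ids", pids)
        object.__setattr__(self, "roles", roles)
        object.__setattr__(self, "pairs", tuple((int(a), int(b)) for a, b in self.pairs))
        object.__setattr__(self, "midline", tuple(int(i) for i in self.midline))

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    def configuration(self, index: int) -> LandmarkConfiguration:
        return LandmarkConfiguration(
            point_ids=self.point_ids,
            coords=self.coords[index],
            roles=self.roles,
            pairs=self.pairs,
            midline=self.midline,
        )

    def require_sex_labels(self) -> np.ndarray:
        """Return sex labels as an array, erroring on missing values."""
        missing = [i for i, s in zip(self.specimen_ids, self.sex) if s is None]
        if missing:
            raise ConfigurationError(f"specimens without sex label: {missing}")
        return np.asarray(self.sex, dtype=object)

    def with_coords(self, coords: np.ndarray) -> "SpecimenSet":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def subset(self, indices: Sequence[int]) -> "SpecimenSet":
        idx = list(indices)
        return SpecimenSet(
            coords=self.coords[idx],
            specimen_ids=tuple(self.specimen_ids[i] for i in idx),
            sex=tuple(self.sex[i] for i in idx),
            population=tuple(self.population[i] for i in idx),
            replicate_of=tuple(self.replicate_of[i] for i in idx),
            point_ids=self.point_ids,
            roles=self.roles,
            pairs=self.pairs,
            midline=self.midline,
        )

    @staticmethod
    def from_configurations(
        configs: Iterable[LandmarkConfiguration],
        specimen_ids: Sequence[str],
        sex: Sequence[str | None],
        population: Sequence[str | None] | None = None,
        replicate_of: Sequence[str | None] | None = None,
    ) -> "SpecimenSet":
        configs = list(configs)
        if not configs:
            raise SchemaError("empty specimen list")
        first = configs[0]
        for sid, c in zip(specimen_ids, configs):
            if c.point_ids != first.point_ids or c.roles != first.roles or \
                    c.pairs != first.pairs or c.midline != first.midline:
                raise SchemaError(f"specimen {sid!r} does not share the common point scheme")
        return SpecimenSet(
            coords=np.stack([c.coords for c in configs]),
            specimen_ids=tuple(specimen_ids),
            sex=tuple(sex),
            population=tuple(population) if population is not None else (),
            replicate_of=tuple(replicate_of) if replicate_of is not None else (),
            point_ids=first.point_ids,
            roles=first.roles,
            pairs=first.pairs,
            midline=first.midline,
        )


@dataclass(frozen=True)
class ProcrustesResult:
    """Output of generalized Procrustes alignment.

    ``aligned`` is (n_specimens, n_points, 3) with every centroid at the
    origin (and unit centroid size when ``scaled``); ``centroid_sizes`` are
    the pre-scaling sizes in mm; ``consensus`` is the arithmetic mean of the
    aligned coordinates.
    """

    aligned: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    scaled: bool
    n_iterations: int
    final_change: float


@dataclass(frozen=True)
class PCAResult:
    mean_vector: np.ndarray
    components: np.ndarray          # (k, p) orthonormal rows
    eigenvalues: np.ndarray         # score-column variances (ddof=1)
    scores: np.ndarray              # (n, k)
    variance_fractions: np.ndarray  # sums to 1 over non-null components
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Project new observations through this PCA's mean and axes."""
        return (np.asarray(data, dtype=float) - self.mean_vector) @ self.components.T


@dataclass(frozen=True)
class AccuracyResult:
    """Cross-validated classification accuracy, averaged over random splits."""

    acc_total: float
    acc_F: float
    acc_M: float
    sd_total: float
    sd_F: float
    sd_M: float
    n_perm: int
    train_fraction: float
    variance_threshold: float


@dataclass(frozen=True)
class AccuracyMap:
    """Per-point mean classification accuracy for one feature space."""

    space: str                      # 'shape' | 'form' | 'size'
    k: int
    n_perm: int
    acc_total: np.ndarray
    acc_F: np.ndarray
    acc_M: np.ndarray
    seed: int
    point_ids: tuple[str, ...] = ()
    n_skipped: np.ndarray | None = None

    def __post_init__(self):
        if self.space not in ("shape", "form", "size"):
            raise SchemaError(f"unknown space {self.space!r}")

    @property
    def n_points(self) -> int:
        return len(self.acc_total)


@dataclass(frozen=True)
class AllometryGroupFit:
    """Per-group multivariate regression of shape on (log) centroid size."""

    coefficients: np.ndarray        # slope per shape variable, length 3*n_points
    intercepts: np.ndarray
    r_squared: float
    predictor_min: float
    predictor_max: float
    predicted_min_shape: np.ndarray  # (n_points, 3)
    predicted_max_shape: np.ndarray


@dataclass(frozen=True)
class AllometryModel:
    predictor: np.ndarray
    log_predictor: bool
    groups: dict[str, AllometryGroupFit] = field(default_factory=dict)

    def group(self, name: str) -> AllometryGroupFit:
        return self.groups[name]


@dataclass(frozen=True)
class Neighborhood:
    """A focal point together with its k-1 nearest neighbors on the consensus."""

    focal_index: int
    member_indices: np.ndarray

    def __post_init__(self):
        members = np.asarray(self.member_indices, dtype=int)
        if len(set(members.tolist())) != len(members):
            raise SchemaError("neighborhood members must be distinct")
        if self.focal_index not in members:
            raise SchemaError("focal point must be a neighborhood member")
        object.__setattr__(self, "member_indices", members)

    @property
    def k(self) -> int:
        return len(self.member_indices)
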
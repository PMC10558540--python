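"""Local mapping of a binary signal onto a landmark configuration.

The core procedure: around every landmark/semilandmark a small neighborhood
of k points is defined on the sample consensus; for each neighborhood the
classification accuracy of the binary label (sex) is estimated by repeated
stratified 70/30 train/test splits, with a fresh Procrustes superimposition
of the *training* neighborhood at every split, PCA truncation at a variance
threshold, and a pooled-covariance linear discriminant. Test specimens are
projected into the training space by ordinary Procrustes alignment to the
training consensus (never refit), so no information leaks from the test
set. Per-point mean accuracies form a 3D accuracy map in shape space, form
space (shape + log local centroid size) or size-only space.

Determinism: the train/test split at (point, permutation) is derived by
hashing (seed, point_index, permutation_index, specimen_id), so maps are
reproducible, parallelizable, and independent of specimen storage order.
"""

from __future__ import annotations

import hashlib

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .datatypes import AccuracyMap, AccuracyResult, Neighborhood, SpecimenSet
from .errors import DimensionError, SchemaError, SingularGeometryError
from .geometry import _gpa_array, gpa
from .stats import _TwoClassLDA, n_components_for_variance, pca

__all__ = [
    "build_neighborhoods",
    "map_signal",
    "combined_module_accuracy",
    "extract_top_modules",
    "compare_maps",
]


# -------------------------------------------------------------- neighborhoods

def build_neighborhoods(
    consensus: np.ndarray, k: int, k_excludes_focal: bool = False
) -> list[Neighborhood]:
    """One neighborhood per point: the focal point plus its nearest neighbors.

    Distances are Euclidean on the consensus shape; ties are broken by lower
    point index. By default k counts the focal point (focal + k-1
    neighbors); with ``k_excludes_focal`` the neighborhood has k+1 members
    (focal + k neighbors).
    """
    consensus = np.asarray(consensus, dtype=float)
    n = consensus.shape[0]
    size = k + 1 if k_excludes_focal else k
    if k < 4:
        raise DimensionError("neighborhoods need k >= 4 for a stable Procrustes fit")
    if size > n:
        raise DimensionError(f"neighborhood size {size} exceeds {n} points")
    d = cdist(consensus, consensus)
    out = []
    idx = np.arange(n)
    for focal in range(n):
        order = np.lexsort((idx, d[focal]))  # distance, then lower index
        out.append(Neighborhood(focal_index=focal, member_indices=order[:size]))
    return out


# ---------------------------------------------------------- deterministic splits

_SM1 = np.uint64(0x9E3779B97F4A7C15)
_SM2 = np.uint64(0xBF58476D1CE4E5B9)
_SM3 = np.uint64(0x94D049BB133111EB)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    # modular 2^64 arithmetic: overflow wraparound is the point
    with np.errstate(over="ignore"):
        x = (x + _SM1).astype(np.uint64)
        x = ((x ^ (x >> np.uint64(30))) * _SM2).astype(np.uint64)
        x = ((x ^ (x >> np.uint64(27))) * _SM3).astype(np.uint64)
        return x ^ (x >> np.uint64(31))


def _id_hashes(specimen_ids) -> np.ndarray:
    """Stable 64-bit hash per specimen id (independent of storage order)."""
    return np.array(
        [
            int.from_bytes(
                hashlib.blake2b(s.encode("utf-8"), digest_size=8).digest(), "little"
            )
            for s in specimen_ids
        ],
        dtype=np.uint64,
    )


def _split_uniforms(id_hashes: np.ndarray, seed: int, point: int, perm: int) -> np.ndarray:
    """Uniform(0,1) per specimen, keyed by (seed, point, perm, specimen id)."""
    with np.errstate(over="ignore"):
        key = _splitmix64(
            np.uint64(seed) * np.uint64(0x5851F42D4C957F2D)
            + np.uint64(point + 1) * np.uint64(0x14057B7EF767814F)
            + np.uint64(perm + 1) * np.uint64(0x2545F4914F6CDD1D)
        )
    mixed = _splitmix64(id_hashes ^ key)
    return mixed / np.float64(2 ** 64)


def _stratified_split_by_hash(
    y: np.ndarray, id_rank: np.ndarray, u: np.ndarray, train_fraction: float
):
    """Canonical stratified split: smallest uniforms train, ties by id rank.

    Returns (train_idx, test_idx), each in canonical (uniform, id) order so
    downstream floating-point reductions are storage-order invariant.
    """
    train_parts, test_parts = [], []
    for cls in (False, True):
        idx = np.nonzero(y == cls)[0]
        order = idx[np.lexsort((id_rank[idx], u[idx]))]
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_parts.append(order[:n_train])
        test_parts.append(order[n_train:])
    return np.concatenate(train_parts), np.concatenate(test_parts)


# ----------------------------------------------------------- core per-module fit

def _batched_opa_to(stack: np.ndarray, target: np.ndarray, scaling: bool) -> np.ndarray:
    """OPA-align each centered (n,3) block of a (s,n,3) stack to a centered
    target, optionally with scaling."""
    centered = stack - stack.mean(axis=1, keepdims=True)
    h = np.einsum("sni,nj->sij", centered, target)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("sij,sjk->sik", u, vt)))
    u = u.copy()
    u[:, :, -1] *= d[:, None]
    s = s.copy()
    s[:, -1] *= d
    rots = np.einsum("sij,sjk->sik", u, vt)
    aligned = np.einsum("snj,sjk->snk", centered, rots)
    if scaling:
        denom = np.einsum("sij,sij->s", centered, centered)
        aligned = aligned * (s.sum(axis=1) / denom)[:, None, None]
    return aligned


def _module_accuracy_once(
    coords_mod: np.ndarray,
    log_cs: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    space: str,
    variance_threshold: float,
    priors: str,
    gpa_tol: float = 1e-9,
    gpa_max_iter: int = 50,
):
    """One train/test evaluation of one point module.

    coords_mod: (n_specimens, k, 3) raw coordinates of the module's points;
    log_cs: per-specimen log centroid size of those points (raw scale).
    Returns (acc_total, acc_F, acc_M, n_test_F, n_test_M).
    """
    y_train, y_test = y[train_idx], y[test_idx]
    if space == "size":
        z_train = log_cs[train_idx, None]
        z_test = log_cs[test_idx, None]
    else:
        aligned_tr, _, consensus, _, _ = _gpa_array(
            coords_mod[train_idx], scale=True, tol=gpa_tol, max_iter=gpa_max_iter
        )
        aligned_te = _batched_opa_to(coords_mod[test_idx], consensus, scaling=True)
        feats_tr = aligned_tr.reshape(len(train_idx), -1)
        feats_te = aligned_te.reshape(len(test_idx), -1)
        if space == "form":
            feats_tr = np.hstack([feats_tr, log_cs[train_idx, None]])
            feats_te = np.hstack([feats_te, log_cs[test_idx, None]])
        p = pca(feats_tr)
        if p.degenerate:
            raise SingularGeometryError("degenerate training features")
        ncomp = n_components_for_variance(p, variance_threshold)
        z_train = p.scores[:, :ncomp]
        z_test = (feats_te - p.mean_vector) @ p.components[:ncomp].T
    model = _TwoClassLDA(priors=priors).fit(z_train, y_train)
    pred = model.predict(z_test)
    correct = pred == y_test
    n_f = int(np.sum(~y_test))
    n_m = int(np.sum(y_test))
    acc_f = float(correct[~y_test].mean()) if n_f else np.nan
    acc_m = float(correct[y_test].mean()) if n_m else np.nan
    return float(correct.mean()), acc_f, acc_m, n_f, n_m


def _module_accuracy(
    specimens: SpecimenSet,
    member_indices: np.ndarray,
    point_key: int,
    space: str,
    n_perm: int,
    train_fraction: float,
    variance_threshold: float,
    seed: int,
    priors: str,
    id_hashes: np.ndarray,
    id_rank: np.ndarray,
    y: np.ndarray,
    collect: list | None = None,
):
    """Mean (total, F, M) accuracy of one module over n_perm random splits.

    Degenerate permutations are skipped; returns NaNs when more than half of
    the permutations were skipped.
    """
    coords_mod = np.ascontiguousarray(specimens.coords[:, member_indices, :])
    centered = coords_mod - coords_mod.mean(axis=1, keepdims=True)
    sq = np.einsum("sij,sij->s", centered, centered)
    if np.any(sq <= 1e-300):
        raise SingularGeometryError("module has zero centroid size for some specimen")
    log_cs = 0.5 * np.log(sq)
    tots = np.full(n_perm, np.nan)
    fs = np.full(n_perm, np.nan)
    ms = np.full(n_perm, np.nan)
    skipped = 0
    for perm in range(n_perm):
        u = _split_uniforms(id_hashes, seed, point_key, perm)
        train_idx, test_idx = _stratified_split_by_hash(y, id_rank, u, train_fraction)
        try:
            t, f, m, n_f, n_m = _module_accuracy_once(
                coords_mod, log_cs, y, train_idx, test_idx, space,
                variance_threshold, priors,
            )
        except (SingularGeometryError, np.linalg.LinAlgError):
            skipped += 1
            continue
        tots[perm], fs[perm], ms[perm] = t, f, m
        if collect is not None:
            collect.append(
                {"perm": perm, "acc_total": t, "acc_F": f, "acc_M": m,
                 "n_test_F": n_f, "n_test_M": n_m}
            )
    if skipped > n_perm / 2:
        return np.nan, np.nan, np.nan, skipped
    return (
        float(np.nanmean(tots)),
        float(np.nanmean(fs)),
        float(np.nanmean(ms)),
        skipped,
    )


# -------------------------------------------------------------------- map_signal

def map_signal(
    specimens: SpecimenSet,
    space: str = "shape",
    k: int = 10,
    n_perm: int = 100,
    train_fraction: float = 0.7,
    variance_threshold: float = 0.9,
    seed: int = 0,
    k_excludes_focal: bool = False,
    priors: str = "frequency",
    neighborhoods: list[Neighborhood] | None = None,
    collect_permutations: dict | None = None,
) -> AccuracyMap:
    """Per-point accuracy map of the sex signal in one feature space.

    Neighborhoods are fixed once from the full-sample GPA consensus. Then,
    per point and per permutation, the module pipeline runs on that point's
    neighborhood (see module docstring). ``space`` selects the features:
    'shape' (local Procrustes coordinates), 'form' (those + log local
    centroid size) or 'size' (log local centroid size alone). At the scale
    of the original study this is n_points x n_perm independent discriminant
    analyses (1050 x 100 = 105 000).
    """
    if space not in ("shape", "form", "size"):
        raise SchemaError(f"unknown space {space!r}")
    y = specimens.require_sex_labels() == "M"
    n_f, n_m = int(np.sum(~y)), int(np.sum(y))
    if n_f < 4 or n_m < 4:
        raise DimensionError(f"both classes need >= 4 specimens (F={n_f}, M={n_m})")
    if neighborhoods is None:
        proc = gpa(specimens, scale=True)
        neighborhoods = build_neighborhoods(proc.consensus, k, k_excludes_focal)
    n_points = specimens.n_points
    if len(neighborhoods) != n_points:
        raise DimensionError("one neighborhood per point is required")
    id_hashes = _id_hashes(specimens.specimen_ids)
    id_rank = np.empty(len(id_hashes), dtype=int)
    id_rank[np.argsort(np.asarray(specimens.specimen_ids, dtype=object))] = np.arange(len(id_hashes))
    acc_t = np.empty(n_points)
    acc_f = np.empty(n_points)
    acc_m = np.empty(n_points)
    n_skip = np.zeros(n_points, dtype=int)
    for nb in neighborhoods:
        collect = [] if collect_permutations is not None else None
        t, f, m, skipped = _module_accuracy(
            specimens, nb.member_indices, nb.focal_index, space, n_perm,
            train_fraction, variance_threshold, seed, priors,
            id_hashes, id_rank, y, collect=collect,
        )
        acc_t[nb.focal_index] = t
        acc_f[nb.focal_index] = f
        acc_m[nb.focal_index] = m
        n_skip[nb.focal_index] = skipped
        if collect_permutations is not None:
            collect_permutations[nb.focal_index] = collect
    return AccuracyMap(
        space=space,
        k=k,
        n_perm=n_perm,
        acc_total=acc_t,
        acc_F=acc_f,
        acc_M=acc_m,
        seed=seed,
        point_ids=specimens.point_ids,
        n_skipped=n_skip,
    )


# ------------------------------------------------------ combined-module accuracy

def combined_module_accuracy(
    specimens: SpecimenSet,
    module_indices: list,
    space: str = "shape",
    n_perm: int = 1000,
    train_fraction: float = 0.7,
    variance_threshold: float = 0.9,
    seed: int = 0,
    priors: str = "frequency",
) -> AccuracyResult:
    """Classification accuracy of the union of point modules.

    The per-neighborhood pipeline is applied once to the union of the given
    index sets (local GPA on the training subset, OPA projection of the test
    set, PCA truncation, pooled-covariance LDA), with the module-level
    default of 1000 permutations.
    """
    union = sorted({int(i) for s in module_indices for i in np.asarray(list(s), dtype=int)})
    if not union:
        raise DimensionError("union of module indices is empty")
    if max(union) >= specimens.n_points or min(union) < 0:
        raise SchemaError("module index out of range")
    y = specimens.require_sex_labels() == "M"
    id_hashes = _id_hashes(specimens.specimen_ids)
    id_rank = np.empty(len(id_hashes), dtype=int)
    id_rank[np.argsort(np.asarray(specimens.specimen_ids, dtype=object))] = np.arange(len(id_hashes))
    collect: list = []
    t, f, m, skipped = _module_accuracy(
        specimens, np.asarray(union), specimens.n_points, space, n_perm,
        train_fraction, variance_threshold, seed, priors,
        id_hashes, id_rank, y, collect=collect,
    )
    tots = np.array([c["acc_total"] for c in collect])
    accf = np.array([c["acc_F"] for c in collect])
    accm = np.array([c["acc_M"] for c in collect])
    return AccuracyResult(
        acc_total=t,
        acc_F=f,
        acc_M=m,
        sd_total=float(np.nanstd(tots)) if len(tots) else np.nan,
        sd_F=float(np.nanstd(accf)) if len(accf) else np.nan,
        sd_M=float(np.nanstd(accm)) if len(accm) else np.nan,
        n_perm=n_perm,
        train_fraction=train_fraction,
        variance_threshold=variance_threshold,
    )


# ----------------------------------------------------------- module extraction

def extract_top_modules(
    accuracy_map: AccuracyMap,
    neighborhoods: list[Neighborhood],
    cutoff: float | None = None,
    top_quantile: float | None = None,
) -> list[np.ndarray]:
    """High-accuracy point modules: thresholded map split into connected parts.

    Points with accuracy >= the cutoff (given directly or as a quantile of
    the map) are partitioned into connected components of the neighborhood
    graph (two points are adjacent when either belongs to the other's
    neighborhood); components are returned sorted by their peak accuracy,
    highest first. An empty selection returns an empty list.
    """
    acc = np.asarray(accuracy_map.acc_total, dtype=float)
    if cutoff is None:
        if top_quantile is None:
            raise ValueError("provide cutoff or top_quantile")
        cutoff = float(np.nanquantile(acc, top_quantile))
    selected = set(np.nonzero(acc >= cutoff)[0].tolist())
    if not selected:
        return []
    adj: dict[int, set[int]] = {i: set() for i in selected}
    for nb in neighborhoods:
        for j in nb.member_indices:
            j = int(j)
            if nb.focal_index in selected and j in selected and j != nb.focal_index:
                adj[nb.focal_index].add(j)
                adj[j].add(nb.focal_index)
    components = []
    todo = set(selected)
    while todo:
        start = todo.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for nxt in adj[node]:
                if nxt not in comp:
                    comp.add(nxt)
                    frontier.append(nxt)
        todo -= comp
        components.append(np.array(sorted(comp)))
    components.sort(key=lambda c: -np.nanmax(acc[c]))
    return components


# --------------------------------------------------------------- map comparison

def compare_maps(
    map_a: AccuracyMap, map_b: AccuracyMap, subset_quantile: float | None = None
) -> dict:
    """Pearson correlation between two accuracy maps' per-point values.

    With ``subset_quantile`` (e.g. 0.75 for the third quartile) the
    correlation is additionally recomputed on the points where map_a's
    accuracy reaches that quantile of map_a (linear-interpolation quantile
    convention).
    """
    a = np.asarray(map_a.acc_total, dtype=float)
    b = np.asarray(map_b.acc_total, dtype=float)
    if a.shape != b.shape:
        raise DimensionError("maps must cover the same points")
    if map_a.space != map_b.space:
        raise SchemaError(f"maps are in different spaces: {map_a.space} vs {map_b.space}")
    result: dict = {"n_points": int(a.size)}
    if np.nanstd(a) <= 1e-300 or np.nanstd(b) <= 1e-300:
        result.update({"r": np.nan, "p_value": np.nan, "undefined": True})
        return result
    ok = np.isfinite(a) & np.isfinite(b)
    r, p = pearsonr(a[ok], b[ok])
    result.update({"r": float(r), "p_value": float(p), "undefined": False})
    if subset_quantile is not None:
        threshold = float(np.nanquantile(a, subset_quantile))
        mask = ok & (a >= threshold)
        result["subset_threshold"] = threshold
        result["n_subset"] = int(mask.sum())
        if mask.sum() >= 3 and np.nanstd(a[mask]) > 1e-300 and np.nanstd(b[mask]) > 1e-300:
            rs, ps = pearsonr(a[mask], b[mask])
            result["r_subset"] = float(rs)
            result["p_subset"] = float(ps)
        else:
            result["r_subset"] = np.nan
            result["p_subset"] = np.nan
    return result
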
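"""Multivariate statistics on superimposed landmark data.

PCA of shape and form (shape + log centroid size) variables, cross-validated
LDA classification accuracy, Procrustes linear models with residual-
randomization permutation tests, digitization repeatability from Procrustes
ANOVA, and allometric trajectory comparison between groups.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla

from .datatypes import (
    AccuracyResult,
    AllometryGroupFit,
    AllometryModel,
    PCAResult,
    ProcrustesResult,
)
from .errors import (
    CollinearityError,
    ConfigurationError,
    DimensionError,
    SingularGeometryError,
    UnbalancedDesignError,
)

__all__ = [
    "pca",
    "form_matrix",
    "n_components_for_variance",
    "lda_accuracy",
    "procrustes_lm",
    "repeatability",
    "allometric_regression",
    "trajectory_angle",
    "angle_permutation_test",
]


# ------------------------------------------------------------------------- PCA

def pca(data_matrix: np.ndarray) -> PCAResult:
    """Principal component analysis by centered singular value decomposition.

    Keeps at most min(n_rows - 1, n_variables) components. Eigenvalues are
    the score-column variances (ddof=1). Component signs are fixed so each
    component's largest-magnitude loading is positive, making the result
    deterministic.
    """
    x = np.asarray(data_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DimensionError("PCA needs a 2D matrix with >= 2 rows")
    if not np.all(np.isfinite(x)):
        raise DimensionError("PCA input must be finite")
    n, p = x.shape
    mean = x.mean(axis=0)
    centered = x - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n - 1, p)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    eigenvalues = s ** 2 / (n - 1)
    total = eigenvalues.sum()
    degenerate = bool(total <= 1e-300)
    fractions = eigenvalues / total if not degenerate else np.zeros_like(eigenvalues)
    return PCAResult(
        mean_vector=mean,
        components=vt,
        eigenvalues=eigenvalues,
        scores=u * s,
        variance_fractions=fractions,
        degenerate=degenerate,
    )


def form_matrix(proc: ProcrustesResult) -> np.ndarray:
    """Form-space data matrix: flattened shape coordinates + ln centroid size.

    The natural log of each specimen's original centroid size is appended as
    one extra column to the flattened GPA-aligned coordinates, so size
    differences re-enter an otherwise size-free analysis.
    """
    if not proc.scaled:
        raise ConfigurationError("form space requires a scaled (unit-size) GPA")
    if proc.centroid_sizes is None or len(proc.centroid_sizes) == 0:
        raise ConfigurationError("missing centroid sizes")
    flat = proc.aligned.reshape(proc.aligned.shape[0], -1)
    return np.hstack([flat, np.log(proc.centroid_sizes)[:, None]])


def n_components_for_variance(p: PCAResult, threshold: float) -> int:
    """Smallest number of leading PCs whose cumulative variance >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    cum = np.cumsum(p.variance_fractions)
    idx = np.searchsorted(cum, threshold - 1e-12)
    return int(min(idx, len(cum) - 1) + 1)


# ------------------------------------------------------------------------- LDA

class _TwoClassLDA:
    """Two-class linear discriminant with pooled within-class covariance.

    Classifies x to class 1 when w'(x - (m0+m1)/2) > log(prior0/prior1),
    w = Sw^{-1}(m1 - m0). Falls back to a small ridge (1e-8 * trace/k on the
    diagonal) when the pooled covariance is singular.
    """

    def __init__(self, priors: str = "frequency"):
        self.priors = priors
        self.ridge_used = False

    def fit(self, x: np.ndarray, y: np.ndarray):
        # y is boolean: True = class 1
        x = np.atleast_2d(np.asarray(x, dtype=float))
        x0, x1 = x[~y], x[y]
        n0, n1 = len(x0), len(x1)
        self.m0, self.m1 = x0.mean(axis=0), x1.mean(axis=0)
        r0 = x0 - self.m0
        r1 = x1 - self.m1
        sw = (r0.T @ r0 + r1.T @ r1) / max(n0 + n1 - 2, 1)
        diff = self.m1 - self.m0
        k = sw.shape[0]
        try:
            c, low = sla.cho_factor(sw, check_finite=False)
            self.w = sla.cho_solve((c, low), diff, check_finite=False)
        except (sla.LinAlgError, ValueError):
            self.ridge_used = True
            sw = sw + np.eye(k) * (1e-8 * np.trace(sw) / k + 1e-300)
            self.w = np.linalg.solve(sw, diff)
        if self.priors == "frequency":
            self.bias = np.log(n0 / n1)
        else:
            self.bias = 0.0
        self.mid = 0.5 * (self.m0 + self.m1)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.mid) @ self.w > self.bias


def _stratified_split(labels01: np.ndarray, train_fraction: float, rng: np.random.Generator):
    """Per-class random train/test split; train gets round(frac * n_class)."""
    train = np.zeros(len(labels01), dtype=bool)
    for cls in (0, 1):
        idx = np.nonzero(labels01 == cls)[0]
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        chosen = rng.permutation(idx)[:n_train]
        train[chosen] = True
    return train


def _split_accuracies(pred1: np.ndarray, truth1: np.ndarray):
    """(acc_total, acc_class0, acc_class1) for boolean predictions/truths."""
    correct = pred1 == truth1
    acc_total = correct.mean()
    acc0 = correct[~truth1].mean() if np.any(~truth1) else np.nan
    acc1 = correct[truth1].mean() if np.any(truth1) else np.nan
    return acc_total, acc0, acc1


def lda_accuracy(
    features: np.ndarray,
    labels,
    train_fraction: float = 0.7,
    n_perm: int = 1000,
    variance_threshold: float = 0.9,
    seed: int = 0,
    priors: str = "frequency",
) -> AccuracyResult:
    """Cross-validated LDA accuracy of a binary ('F'/'M') classification.

    Per permutation: stratified random train/test split; PCA fitted on the
    training rows only; leading PCs retained up to ``variance_threshold`` of
    the training variance; pooled-covariance LDA fitted on the training
    scores; test rows projected through the *training* mean and axes and
    classified. Returns means and standard deviations (over permutations) of
    the total, female and male accuracies.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=object)
    y = labels == "M"
    if x.ndim == 1:
        x = x[:, None]
    n_f, n_m = int(np.sum(~y)), int(np.sum(y))
    if n_f < 2 or n_m < 2:
        raise DimensionError(f"both classes need >= 2 members (F={n_f}, M={n_m})")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    y01 = y.astype(int)
    tots, accfs, accms = [], [], []
    for _ in range(n_perm):
        train = _stratified_split(y01, train_fraction, rng)
        p = pca(x[train])
        k = n_components_for_variance(p, variance_threshold) if not p.degenerate else 1
        z_train = p.scores[:, :k]
        z_test = (x[~train] - p.mean_vector) @ p.components[:k].T
        model = _TwoClassLDA(priors=priors).fit(z_train, y[train])
        pred = model.predict(z_test)
        t, f, m = _split_accuracies(pred, y[~train])
        tots.append(t)
        accfs.append(f)
        accms.append(m)
    tots, accfs, accms = map(np.asarray, (tots, accfs, accms))
    return AccuracyResult(
        acc_total=float(np.mean(tots)),
        acc_F=float(np.nanmean(accfs)),
        acc_M=float(np.nanmean(accms)),
        sd_total=float(np.std(tots)),
        sd_F=float(np.nanstd(accfs)),
        sd_M=float(np.nanstd(accms)),
        n_perm=n_perm,
        train_fraction=train_fraction,
        variance_threshold=variance_threshold,
    )


# --------------------------------------------------------- Procrustes linear model

def _term_column(values) -> np.ndarray:
    """Numeric column for a model term: numbers pass through, two-level
    categorical labels are coded -1/+1 (sorted label order)."""
    values = np.asarray(values)
    if values.dtype.kind in "fiu":
        return values.astype(float)
    levels = sorted(set(values.tolist()))
    if len(levels) != 2:
        raise CollinearityError(
            f"categorical term must have exactly 2 levels, got {levels}"
        )
    return np.where(values == levels[1], 1.0, -1.0)


def procrustes_lm(
    shape_vars: np.ndarray,
    model_terms: list[tuple[str, np.ndarray]],
    n_perm: int = 999,
    seed: int = 0,
):
    """Sequential multivariate linear model on shape variables with RRPP.

    Terms enter the model in the given order (e.g. size, sex, size x sex);
    each term's variance fraction is its sequential sum of squares (summed
    across all shape variables) over the total sum of squares. Significance
    is assessed by residual randomization: for each term the residuals of
    the model *before* it are permuted, and the permuted F-ratio is compared
    with the observed one; p = (exceedances + 1) / (n_perm + 1).

    Returns a list of dicts (term, fraction, df, p_value) plus a residual row.
    """
    y = np.asarray(shape_vars, dtype=float)
    n = y.shape[0]
    cols = [("intercept", np.ones(n))]
    for name, values in model_terms:
        cols.append((name, _term_column(values)))
    if n < len(cols) + 1:
        raise DimensionError("too few observations for the requested model")
    x = np.column_stack([c for _, c in cols])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise CollinearityError(
            f"confounded model terms: {[name for name, _ in cols[1:]]}"
        )
    q, _ = np.linalg.qr(x)  # columns grouped: intercept, then one per term
    yc = y - y.mean(axis=0)
    total_ss = float(np.sum(yc ** 2))
    proj = q.T @ y                                  # (n_terms+1, p)
    term_ss = np.sum(proj[1:] ** 2, axis=1)         # sequential SS per term
    rss = max(float(np.sum(y ** 2) - np.sum(proj ** 2)), 0.0)
    n_terms = len(model_terms)
    df_res = n - (n_terms + 1)

    def f_ratio(ss, rss_val):
        denom = rss_val / df_res
        if denom <= 0:
            return np.inf if ss > 0 else 0.0
        return ss / denom

    f_obs = np.array([f_ratio(ss, rss) for ss in term_ss])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_terms)
    for k in range(n_terms):
        # reduced model: intercept + terms before k
        qk = q[:, : k + 1]
        fitted = qk @ (qk.T @ y)
        resid = y - fitted
        for _ in range(n_perm):
            perm = rng.permutation(n)
            y_star = fitted + resid[perm]
            proj_star = q.T @ y_star
            ss_k = float(np.sum(proj_star[k + 1] ** 2))
            rss_star = max(float(np.sum(y_star ** 2) - np.sum(proj_star ** 2)), 0.0)
            f_star = f_ratio(ss_k, rss_star)
            if f_star >= f_obs[k] * (1 - 1e-12) - 1e-12:
                exceed[k] += 1
    p_values = (exceed + 1) / (n_perm + 1)
    rows = [
        {
            "term": name,
            "fraction": float(ss / total_ss),
            "df": 1,
            "p_value": float(p),
        }
        for (name, _), ss, p in zip(model_terms, term_ss, p_values)
    ]
    rows.append(
        {"term": "residual", "fraction": float(rss / total_ss), "df": df_res, "p_value": np.nan}
    )
    return rows


# --------------------------------------------------------------- repeatability

def repeatability(shape_vars: np.ndarray, individual_ids, n_replicates: int) -> float:
    """Digitization repeatability (%) from a one-way Procrustes ANOVA.

    ``shape_vars`` holds the jointly superimposed coordinates of every
    digitization (flattened); ``individual_ids`` maps each row to its
    individual. With r replicates per individual,
    R = (MS_among - MS_within) / (MS_among + (r - 1) MS_within), where mean
    squares are summed over all coordinates; reported x100 and clamped to
    [0, 100].
    """
    y = np.asarray(shape_vars, dtype=float)
    ids = np.asarray(individual_ids)
    uniq, counts = np.unique(ids, return_counts=True)
    if len(uniq) < 2:
        raise DimensionError("repeatability needs >= 2 individuals")
    if np.any(counts != n_replicates) or n_replicates < 2:
        raise UnbalancedDesignError(
            f"balanced design required: expected {n_replicates} replicates each, got {dict(zip(uniq.tolist(), counts.tolist()))}"
        )
    g, r = len(uniq), n_replicates
    grand = y.mean(axis=0)
    ss_among = 0.0
    ss_within = 0.0
    for ind in uniq:
        block = y[ids == ind]
        mu = block.mean(axis=0)
        ss_among += r * float(np.sum((mu - grand) ** 2))
        ss_within += float(np.sum((block - mu) ** 2))
    ms_among = ss_among / (g - 1)
    ms_within = ss_within / (g * (r - 1))
    rep = (ms_among - ms_within) / (ms_among + (r - 1) * ms_within)
    return float(np.clip(rep * 100.0, 0.0, 100.0))


# ----------------------------------------------------------------- allometry

def _fit_group(flat: np.ndarray, pred: np.ndarray, n_points: int) -> AllometryGroupFit:
    if np.ptp(pred) <= 1e-12:
        raise SingularGeometryError("constant size predictor; allometric fit is singular")
    pc = pred - pred.mean()
    slopes = (pc @ (flat - flat.mean(axis=0))) / np.sum(pc ** 2)
    intercepts = flat.mean(axis=0) - slopes * pred.mean()
    fitted = np.outer(pred, slopes) + intercepts
    ss_tot = float(np.sum((flat - flat.mean(axis=0)) ** 2))
    ss_reg = float(np.sum((fitted - flat.mean(axis=0)) ** 2))
    r2 = ss_reg / ss_tot if ss_tot > 0 else 0.0
    lo, hi = float(pred.min()), float(pred.max())
    return AllometryGroupFit(
        coefficients=slopes,
        intercepts=intercepts,
        r_squared=r2,
        predictor_min=lo,
        predictor_max=hi,
        predicted_min_shape=(intercepts + slopes * lo).reshape(n_points, 3),
        predicted_max_shape=(intercepts + slopes * hi).reshape(n_points, 3),
    )


def allometric_regression(
    proc: ProcrustesResult,
    groups=None,
    log_predictor: bool = False,
) -> AllometryModel:
    """Multivariate regression of superimposed shape on centroid size.

    Each shape variable is regressed (OLS) on the specimen centroid size
    (natural log when ``log_predictor``); the slope vector over all
    3 x n_points variables is the group's allometric trajectory. R-squared
    is the regression sum of squares over the total, pooled across
    variables. Predicted shapes are evaluated at the group's observed
    extreme predictor values. With ``groups=None`` a single pooled fit is
    returned under the key 'all'.
    """
    flat = proc.aligned.reshape(proc.aligned.shape[0], -1)
    n_points = proc.aligned.shape[1]
    pred = np.log(proc.centroid_sizes) if log_predictor else np.asarray(proc.centroid_sizes, dtype=float)
    fits: dict[str, AllometryGroupFit] = {}
    if groups is None:
        if flat.shape[0] < 3:
            raise DimensionError("allometric regression needs >= 3 specimens")
        fits["all"] = _fit_group(flat, pred, n_points)
    else:
        groups = np.asarray(groups, dtype=object)
        for g in sorted(set(groups.tolist())):
            mask = groups == g
            if int(mask.sum()) < 3:
                raise DimensionError(f"group {g!r} needs >= 3 specimens")
            fits[str(g)] = _fit_group(flat[mask], pred[mask], n_points)
    return AllometryModel(predictor=pred, log_predictor=log_predictor, groups=fits)


def trajectory_angle(model_f: AllometryGroupFit | np.ndarray, model_m: AllometryGroupFit | np.ndarray) -> float:
    """Angle (degrees, [0, 180]) between two allometric trajectory vectors."""
    a = model_f.coefficients if isinstance(model_f, AllometryGroupFit) else np.asarray(model_f, dtype=float)
    b = model_m.coefficients if isinstance(model_m, AllometryGroupFit) else np.asarray(model_m, dtype=float)
    if a.shape != b.shape:
        raise DimensionError("trajectory vectors must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na <= 1e-300 or nb <= 1e-300:
        raise SingularGeometryError("zero-norm trajectory; angle undefined")
    cosang = float(np.clip(np.dot(a / na, b / nb), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def angle_permutation_test(
    proc: ProcrustesResult,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
    log_predictor: bool = False,
):
    """Permutation test of the angle between group allometric trajectories.

    The observed angle comes from group-wise allometric regressions; the null
    distribution shuffles the group labels (preserving group sizes) and
    recomputes the angle. p = (count of permuted angles >= observed + 1) /
    (n_perm + 1). Returns (observed_angle_deg, p_value).
    """
    labels = np.asarray(labels, dtype=object)
    model = allometric_regression(proc, groups=labels, log_predictor=log_predictor)
    names = sorted(model.groups)
    if len(names) != 2:
        raise DimensionError(f"exactly 2 groups required, got {names}")
    observed = trajectory_angle(model.groups[names[0]], model.groups[names[1]])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        shuffled = labels[rng.permutation(len(labels))]
        m = allometric_regression(proc, groups=shuffled, log_predictor=log_predictor)
        ang = trajectory_angle(m.groups[names[0]], m.groups[names[1]])
        if ang >= observed - 1e-12:
            count += 1
    return observed, (count + 1) / (n_perm + 1)
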
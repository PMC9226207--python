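"""Scaled-subprofile-model PCA: disease-pattern derivation and expression scoring.

The procedure derives a covariance pattern that discriminates patients from
controls from a two-group training cohort of masked images:

1. each subject image is restricted to the brain mask and stacked as a column
   of a voxels x subjects matrix;
2. each column is centred by its own mean over mask voxels, then the mean
   healthy-control (HC) column profile is subtracted from every column;
3. PCA is applied (via the subjects x subjects Gram matrix — efficient when
   voxels far outnumber subjects) and components are ordered by explained
   variance;
4. the minimal prefix of components jointly explaining at least the variance
   target (default 50%) is kept as the candidate pool;
5. a stepwise-forward logistic regression of group on the candidate subject
   scores, driven by the Akaike information criterion, picks the components;
6. the disease pattern (DP) is the coefficient-weighted sum of the selected
   component voxel patterns, unit-normalised and sign-fixed so that patients
   score higher than controls.

A subject's raw expression score is the inner product of their (centred,
HC-profile-subtracted) image with the DP.  For training subjects the
leave-one-out cross-validated (LOOCV) score is used to reduce bias, and all
scores are standardised to Z-scores using the mean and standard deviation of
the HC group's LOOCV scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AtlasDefinition, Cohort, GridMismatchError, ImageVolume

log = logging.getLogger(__name__)

#: Ridge strength used only when the unpenalised logistic fit diverges
#: (perfect separation is common with ~30 subjects and strong effects).
RIDGE_ALPHA = 1e-2


@dataclass
class DataMatrix:
    """Centred voxels x subjects data matrix with its centering bookkeeping."""

    values: np.ndarray  # (n_voxels, n_subjects), doubly centred
    subject_ids: list[str]
    groups: list[str]
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    subject_offsets: np.ndarray  # per-subject mask-mean removed first
    hc_mean_profile: np.ndarray  # HC mean column (after per-subject centering)
    log_transform: bool = False

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]


@dataclass
class PCADecomposition:
    """Principal components of a data matrix.

    ``component_patterns`` columns are unit-norm voxel loadings;
    ``subject_scores[j, k]`` is subject j's projection on component k;
    ``variance_fraction`` is nonincreasing and sums to <= 1.
    """

    component_patterns: np.ndarray  # (n_voxels, K)
    subject_scores: np.ndarray  # (n_subjects, K)
    variance_fraction: np.ndarray  # (K,)


@dataclass
class DiseasePattern:
    """A unit-norm voxel-weight map plus the bookkeeping that produced it."""

    weights: np.ndarray  # (n_voxels,) over mask, unit Euclidean norm
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    included_pcs: list[int]  # 0-based indices into the variance-ordered PCs
    logistic_coefficients: list[float]
    intercept: float
    dp_variance_explained: float  # percent: summed variance fractions of included PCs
    variance_fractions: np.ndarray
    training_hc_mean_profile: np.ndarray
    log_transform: bool = False
    training_hc_score_mean: float = float("nan")  # from LOOCV HC scores
    training_hc_score_sd: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def weights_volume(self) -> ImageVolume:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.weights
        return ImageVolume(vol, self.voxel_size)


def build_data_matrix(
    cohort: Cohort, mask: np.ndarray | None = None, log_transform: bool = False
) -> DataMatrix:
    """Mask, stack and doubly centre a cohort into a voxels x subjects matrix.

    Each column is centred by its own mask-mean; the HC column-mean profile is
    then subtracted from every column and stored (with the per-subject
    offsets) for prospective scoring.
    """
    if mask is None:
        mask = cohort.mask
    mask = np.asarray(mask, dtype=bool)
    if not any(g == "HC" for g in cohort.groups):
        raise ValueError("cohort contains no HC subjects; the HC mean is undefined")
    cols = []
    for s in cohort.subjects:
        v = s.image.data[mask]
        if not np.all(np.isfinite(v)):
            bad = np.flatnonzero(~np.isfinite(v))[:10]
            raise ValueError(
                f"subject {s.subject_id} has non-finite values inside the mask "
                f"at mask-voxel indices {bad.tolist()}"
            )
        if log_transform:
            if np.any(v <= 0):
                raise ValueError(
                    f"subject {s.subject_id} has non-positive values inside the "
                    "mask; log transform impossible"
                )
            v = np.log(v)
        cols.append(v)
    X = np.column_stack(cols)
    offsets = X.mean(axis=0)
    X = X - offsets
    hc = np.array([g == "HC" for g in cohort.groups])
    hc_profile = X[:, hc].mean(axis=1)
    X = X - hc_profile[:, None]
    return DataMatrix(
        values=X,
        subject_ids=list(cohort.ids),
        groups=list(cohort.groups),
        mask=mask,
        voxel_size=cohort.voxel_size,
        subject_offsets=offsets,
        hc_mean_profile=hc_profile,
        log_transform=log_transform,
    )


def pca_decompose(matrix: DataMatrix, tol: float = 1e-12) -> PCADecomposition:
    """PCA through the subjects x subjects Gram matrix.

    Equivalent to an SVD of the full voxels x subjects matrix but O(n^2)
    in subjects.  Component signs are fixed by making each component's
    largest-|loading| voxel positive.  Near-null components (relative
    eigenvalue below ``tol``) are dropped; an all-null matrix is an error.
    """
    X = matrix.values
    gram = X.T @ X
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    if eigval[0] <= 0 or not np.isfinite(eigval[0]):
        raise ValueError("degenerate cohort: data matrix has no variance to decompose")
    keep = eigval > tol * eigval[0]
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    patterns = X @ eigvec / np.sqrt(eigval)
    # sign convention: largest-|loading| voxel positive
    flip = patterns[np.abs(patterns).argmax(axis=0), np.arange(patterns.shape[1])] < 0
    patterns[:, flip] *= -1.0
    scores = X.T @ patterns
    return PCADecomposition(
        component_patterns=patterns,
        subject_scores=scores,
        variance_fraction=eigval / eigval.sum(),
    )


def select_variance_prefix(variance_fraction: np.ndarray, target: float = 0.50) -> list[int]:
    """Minimal prefix of variance-ordered PCs whose cumulative fraction >= target."""
    cum = np.cumsum(variance_fraction)
    n = int(np.searchsorted(cum, target - 1e-12) + 1)
    n = min(n, len(variance_fraction))
    return list(range(n))


def _logit_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Logistic fit returning (coefficients incl. intercept, AIC, ridged?).

    Tries the unpenalised maximum-likelihood fit; on divergence or perfect
    separation falls back to a small fixed ridge on the slopes, with the AIC
    computed from the *unpenalised* log-likelihood at the converged
    coefficients.
    """
    import statsmodels.api as sm
    from scipy.optimize import minimize

    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    ridged = False
    beta = None
    if p == 0:
        phat = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        beta = np.array([np.log(phat / (1 - phat))])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, design).fit(disp=0, maxiter=200)
                if res.mle_retvals.get("converged", False) and np.all(
                    np.abs(res.params) < 1e3
                ):
                    beta = np.asarray(res.params)
            except Exception:  # noqa: BLE001 — separation raises various types
                beta = None
    if beta is None:
        ridged = True
        log.warning("logistic fit diverged (separation?); using ridge alpha=%g", RIDGE_ALPHA)

        def objective(b):
            pen = 0.5 * RIDGE_ALPHA * np.sum(b[1:] ** 2)
            eta = design @ b
            mu = 1.0 / (1.0 + np.exp(-eta))
            nll = -_logit_loglik(b, design, y)
            grad = design.T @ (mu - y)
            grad[1:] += RIDGE_ALPHA * b[1:]
            return nll + pen, grad

        res = minimize(objective, np.zeros(design.shape[1]), jac=True, method="L-BFGS-B")
        beta = res.x
    ll = _logit_loglik(beta, design, y)
    aic = 2.0 * len(beta) - 2.0 * ll
    return beta, aic, ridged


def stepwise_forward_aic(
    scores: np.ndarray, y: np.ndarray, candidates: list[int]
) -> tuple[list[int], np.ndarray, float]:
    """Forward stepwise logistic selection by strictly decreasing AIC.

    Starts from the intercept-only model; at each step adds the candidate
    that lowers the AIC most (ties broken by lower PC index) and stops when
    no addition lowers it.  Returns (selected indices in inclusion order,
    coefficients incl. intercept, final AIC).
    """
    # columns are standardised for numerical stability; coefficients are
    # mapped back to the raw score scale (AIC is scale-invariant)
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = scores / sd
    selected: list[int] = []
    beta, best_aic, _ = _fit_logistic(Z[:, []], y)
    while True:
        trials = []
        for c in candidates:
            if c in selected:
                continue
            cols = selected + [c]
            b, aic, _ = _fit_logistic(Z[:, cols], y)
            trials.append((aic, c, b))
        if not trials:
            break
        trials.sort(key=lambda t: (t[0], t[1]))
        aic, c, b = trials[0]
        if aic < best_aic - 1e-10:
            selected.append(c)
            best_aic, beta = aic, b
        else:
            break
    # unstandardise slopes
    full_beta = np.zeros(1 + len(selected))
    full_beta[0] = beta[0]
    for j, c in enumerate(selected):
        full_beta[1 + j] = beta[1 + j] / sd[c]
    return selected, full_beta, best_aic


def derive_pattern(
    matrix: DataMatrix,
    labels: list[str] | None = None,
    variance_target: float = 0.50,
) -> tuple[DiseasePattern, PCADecomposition]:
    """Derive the disease pattern from a two-group (AD/HC) data matrix."""
    if labels is None:
        labels = matrix.groups
    labels = list(labels)
    bad = set(labels) - {"AD", "HC"}
    if bad:
        raise ValueError(f"pattern derivation needs AD/HC labels only, got {sorted(bad)}")
    y = np.array([1.0 if g == "AD" else 0.0 for g in labels])
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both AD and HC subjects are required")

    pca = pca_decompose(matrix)
    candidates = select_variance_prefix(pca.variance_fraction, variance_target)
    selected, beta, aic = stepwise_forward_aic(pca.subject_scores, y, candidates)
    if not selected:
        raise ValueError(
            "stepwise selection is empty: no principal component lowers the AIC "
            "below the intercept-only model"
        )
    w = pca.component_patterns[:, selected] @ beta[1:]
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("null pattern: selected-component combination vanished")
    w = w / norm
    raw = matrix.values.T @ w
    if raw[y == 1].mean() <= raw[y == 0].mean():
        w = -w
        beta = -beta
    included_sorted = sorted(selected)
    pattern = DiseasePattern(
        weights=w,
        mask=matrix.mask,
        voxel_size=matrix.voxel_size,
        included_pcs=included_sorted,
        logistic_coefficients=[float(beta[1 + selected.index(c)]) for c in included_sorted],
        intercept=float(beta[0]),
        dp_variance_explained=float(100.0 * pca.variance_fraction[included_sorted].sum()),
        variance_fractions=pca.variance_fraction.copy(),
        training_hc_mean_profile=matrix.hc_mean_profile.copy(),
        log_transform=matrix.log_transform,
        metadata={"aic": float(aic), "selection_order": [int(c) for c in selected]},
    )
    return pattern, pca


def score_subject(image: ImageVolume, pattern: DiseasePattern, mask: np.ndarray | None = None) -> float:
    """Raw pattern-expression score of one image.

    The image is masked, centred by its own mask-mean, the training HC mean
    profile is subtracted, and the inner product with the DP weights taken.
    A global additive shift therefore leaves the score unchanged.
    """
    if mask is None:
        mask = pattern.mask
    mask = np.asarray(mask, dtype=bool)
    if image.grid_shape != mask.shape:
        raise GridMismatchError(
            f"image grid {image.grid_shape} does not match the training grid {mask.shape}"
        )
    v = image.data[mask].astype(float)
    if pattern.log_transform:
        v = np.log(v)
    v = v - v.mean()
    v = v - pattern.training_hc_mean_profile
    return float(v @ pattern.weights)


def score_cohort(cohort: Cohort, pattern: DiseasePattern) -> pd.DataFrame:
    """In-sample/prospective raw scores for every subject of a cohort."""
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "raw_score": score_subject(s.image, pattern),
            "loocv_flag": False,
        }
        for s in cohort.subjects
    ]
    return pd.DataFrame(rows)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def loocv_scores(
    cohort: Cohort,
    variance_target: float = 0.50,
    log_transform: bool = False,
    full_pattern: DiseasePattern | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out cross-validated raw scores plus a stability report.

    Each fold re-derives a pattern on the remaining subjects (sign-aligned to
    the full-cohort DP) and scores the held-out subject against it.  The
    stability report carries each fold's DP cosine to the full-cohort DP.
    """
    groups = cohort.groups
    for cls in ("AD", "HC"):
        n_cls = sum(g == cls for g in groups)
        if n_cls < 3:
            raise ValueError(
                f"a fold would retain fewer than 2 {cls} subjects "
                f"({n_cls} in the cohort); LOOCV is not defined"
            )
    if full_pattern is None:
        full_pattern, _ = derive_pattern(build_data_matrix(cohort, log_transform=log_transform))
    rows, report = [], []
    for i, subject in enumerate(cohort.subjects):
        rest = [s for j, s in enumerate(cohort.subjects) if j != i]
        fold_cohort = Cohort(rest, cohort.mask, cohort.voxel_size)
        fold_matrix = build_data_matrix(fold_cohort, log_transform=log_transform)
        fold_pattern, _ = derive_pattern(fold_matrix, variance_target=variance_target)
        cos = _cosine(fold_pattern.weights, full_pattern.weights)
        if cos < 0:  # sign-align to the full-cohort DP
            fold_pattern.weights = -fold_pattern.weights
            cos = -cos
        rows.append(
            {
                "subject_id": subject.subject_id,
                "group": groups[i],
                "raw_score": score_subject(subject.image, fold_pattern),
                "loocv_flag": True,
            }
        )
        report.append({"left_out": subject.subject_id, "cosine_to_full_dp": cos})
    return pd.DataFrame(rows), pd.DataFrame(report)


def zscore_standardize(scores: pd.DataFrame, hc_loocv_scores: np.ndarray) -> pd.DataFrame:
    """Standardise raw scores to Z-scores against the HC LOOCV distribution.

    ``z = (raw - mean(HC LOOCV)) / sd(HC LOOCV)`` (sample SD); the HC LOOCV
    scores themselves standardise to mean 0, SD 1 by construction.
    """
    hc = np.asarray(hc_loocv_scores, dtype=float)
    if len(hc) < 2:
        raise ValueError("need >= 2 HC LOOCV scores to standardise")
    mu, sd = hc.mean(), hc.std(ddof=1)
    if sd == 0:
        raise ValueError("HC LOOCV scores have zero spread; Z-scores undefined")
    out = scores.copy()
    out["z_score"] = (out["raw_score"] - mu) / sd
    return out


def derive_pattern_with_loocv(
    cohort: Cohort,
    variance_target: float = 0.50,
    log_transform: bool = False,
) -> tuple[DiseasePattern, pd.DataFrame, pd.DataFrame, PCADecomposition]:
    """Full training pipeline on an AD/HC cohort.

    Returns the full-cohort DP (with the HC LOOCV score mean/SD recorded),
    the Z-standardised LOOCV score table, the LOOCV stability report and the
    PCA decomposition.
    """
    train = cohort.select(["AD", "HC"])
    matrix = build_data_matrix(train, log_transform=log_transform)
    pattern, pca = derive_pattern(matrix, variance_target=variance_target)
    loocv, report = loocv_scores(
        train, variance_target, log_transform=log_transform, full_pattern=pattern
    )
    hc_scores = loocv.loc[loocv["group"] == "HC", "raw_score"].to_numpy()
    pattern.training_hc_score_mean = float(hc_scores.mean())
    pattern.training_hc_score_sd = float(hc_scores.std(ddof=1))
    table = zscore_standardize(loocv, hc_scores)
    return pattern, table, report, pca


def score_table(
    cohort: Cohort, pattern: DiseasePattern, loocv_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Z-standardised scores for a whole cohort.

    Training subjects take their LOOCV score (bias reduction); others are
    scored prospectively against the full-cohort DP.  Requires the pattern's
    HC LOOCV mean/SD to be set.
    """
    if not np.isfinite(pattern.training_hc_score_sd):
        raise ValueError("pattern has no HC LOOCV statistics; run LOOCV first")
    rows = score_cohort(cohort, pattern)
    if loocv_table is not None:
        lut = dict(zip(loocv_table["subject_id"], loocv_table["raw_score"]))
        replace = rows["subject_id"].isin(lut)
        rows.loc[replace, "raw_score"] = rows.loc[replace, "subject_id"].map(lut)
        rows.loc[replace, "loocv_flag"] = True
    rows["z_score"] = (
        rows["raw_score"] - pattern.training_hc_score_mean
    ) / pattern.training_hc_score_sd
    return rows


def regional_summary(
    pattern: DiseasePattern, atlas: AtlasDefinition, mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Mean +/- SD of the DP weights per atlas region and per combined lobe.

    Volumes are voxel count x voxel volume in cm^3, counted inside the
    analysis mask.  Regions with no voxels inside the mask are reported as
    empty rows, not dropped.
    """
    if mask is None:
        mask = pattern.mask
    mask = np.asarray(mask, dtype=bool)
    if atlas.labels.shape != mask.shape:
        raise GridMismatchError("atlas grid does not match the pattern grid")
    vol = pattern.weights_volume().data
    vox_cm3 = float(np.prod(pattern.voxel_size)) / 1000.0
    rows = []

    def summarise(name: str, level: str, sel: np.ndarray, lobe: str | None):
        sel = sel & mask
        n = int(sel.sum())
        vals = vol[sel]
        rows.append(
            {
                "name": name,
                "level": level,
                "lobe": lobe if lobe is not None else name,
                "n_voxels": n,
                "volume_cm3": n * vox_cm3,
                "mean": float(vals.mean()) if n else np.nan,
                "sd": float(vals.std(ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan),
            }
        )

    for lab, name in sorted(atlas.region_names.items()):
        summarise(name, "region", atlas.labels == lab, atlas.lobe_map[name])
    for lobe in atlas.lobes:
        summarise(lobe, "lobe", atlas.lobe_mask(lobe), None)
    return pd.DataFrame(rows)
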
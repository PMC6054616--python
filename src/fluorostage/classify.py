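"""Pairwise PCA-LDA staging of lesion groups with ROC and confusion analysis.

Normalized spectra (310 intensities each) are reduced by mean-centered
PCA, retaining the smallest leading set of components reaching 95%
cumulative explained variance (minimum two).  For each lesion pair a
Fisher linear discriminant is fitted on the PC scores of the training
split; scores are shifted so the midpoint of the two class means is 0 and
classification uses the fixed cutoff 0, with the more advanced lesion of
the pair on the positive side.  Validation spectra are projected through
the training PCA and discriminant — never refitted.  Reported per pair:
sensitivity, specificity, confusion counts, the full ROC sweep with
trapezoidal AUC, and, over the whole dataset, a 2-D multiclass Fisher map
with per-group 2-SD confidence ellipses and a nearest-centroid confusion
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.decomposition import PCA

from .spectra_io import GROUPS, LabeledSpectraSet

#: Disease-severity rank used to pick each pair's positive class.
SEVERITY = {"control": 0, "reversal": 1, "mild": 2, "moderate": 3}

#: The four lesion pairs reported by the staging analysis.
DEFAULT_PAIRS = (
    ("control", "mild"),
    ("mild", "moderate"),
    ("moderate", "reversal"),
    ("mild", "reversal"),
)


class DegenerateDataError(ValueError):
    """Raised when the data carry no variance to decompose."""


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Mean-centered PCA restricted to the retained leading components."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (n_retained, n_wavelengths), orthonormal rows
    explained_variance_fractions: np.ndarray
    n_retained: int

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean_spectrum) @ self.loadings.T


def fit_pca(
    matrix: np.ndarray,
    variance_threshold: float = 0.95,
    min_components: int = 2,
) -> PCAModel:
    """Fit mean-centered PCA, retaining components to the variance rule.

    The significant components are the smallest leading set whose
    cumulative explained-variance fraction reaches ``variance_threshold``
    (never fewer than ``min_components``).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two spectra")
    if np.allclose(matrix, matrix[0], atol=1e-12):
        raise DegenerateDataError("all spectra identical: zero total variance")
    pca = PCA(svd_solver="full")
    pca.fit(matrix)
    fractions = pca.explained_variance_ratio_
    cumulative = np.cumsum(fractions)
    n_retained = int(np.searchsorted(cumulative, variance_threshold) + 1)
    n_retained = max(min_components, min(n_retained, fractions.size))
    keep = fractions > 0  # guard zero-variance trailing components
    n_retained = min(n_retained, int(keep.sum()))
    return PCAModel(
        mean_spectrum=pca.mean_,
        loadings=pca.components_[:n_retained],
        explained_variance_fractions=fractions[:n_retained],
        n_retained=n_retained,
    )


# ---------------------------------------------------------------------------
# Pairwise Fisher LDA
# ---------------------------------------------------------------------------

@dataclass
class PairwiseLDAModel:
    """1-D Fisher discriminant for one lesion pair, cutoff fixed at 0."""

    pair: tuple[str, str]
    positive_class: str
    weight_vector: np.ndarray
    offset: float
    cutoff: float = 0.0

    @property
    def negative_class(self) -> str:
        a, b = self.pair
        return a if b == self.positive_class else b

    def decision_scores(self, pc_scores: np.ndarray) -> np.ndarray:
        return np.asarray(pc_scores, dtype=float) @ self.weight_vector - self.offset


def fit_lda_pairwise(
    scores: np.ndarray,
    labels: np.ndarray,
    pair: tuple[str, str] | None = None,
) -> PairwiseLDAModel:
    """Fisher direction w ~ S_w^-1 (m_pos - m_neg) on PC scores.

    Scores are shifted so the midpoint of the two class mean scores is 0;
    the more advanced lesion of the pair lands on the positive side.  A
    singular pooled within-class scatter falls back to a ridge-regularized
    inverse with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels))
    if pair is None:
        if len(classes) != 2:
            raise ValueError(f"expected exactly two classes, got {classes}")
        pair = (classes[0], classes[1])
    a, b = pair
    positive = max(pair, key=lambda g: SEVERITY.get(g, -1))
    negative = a if positive == b else b
    groups = {}
    for cls in (negative, positive):
        members = scores[labels == cls]
        if members.shape[0] < 2:
            raise ValueError(f"class {cls!r} needs at least two members")
        groups[cls] = members
    m_neg = groups[negative].mean(axis=0)
    m_pos = groups[positive].mean(axis=0)
    s_w = sum(
        (g - g.mean(axis=0)).T @ (g - g.mean(axis=0)) for g in groups.values()
    )
    s_w = np.atleast_2d(s_w)
    delta = m_pos - m_neg
    try:
        cond = np.linalg.cond(s_w)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned within-class scatter")
        w = np.linalg.solve(s_w, delta)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * max(np.trace(s_w) / s_w.shape[0], 1.0)
        warnings.warn(
            "singular pooled within-class scatter; using ridge-regularized "
            f"inverse (lambda={ridge:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
        w = np.linalg.solve(s_w + ridge * np.eye(s_w.shape[0]), delta)
    offset = float(w @ (m_pos + m_neg) / 2.0)
    return PairwiseLDAModel(
        pair=pair, positive_class=positive, weight_vector=w, offset=offset
    )


# ---------------------------------------------------------------------------
# ROC and pair evaluation
# ---------------------------------------------------------------------------

def roc_curve(
    scores: np.ndarray, labels: np.ndarray, positive_class
) -> tuple[np.ndarray, float]:
    """Threshold sweep over all distinct scores; trapezoidal AUC.

    Returns ROC points as an array of (FPR, TPR) rows from (0, 0) to
    (1, 1).  The AUC equals the Mann-Whitney statistic (ties counted
    one-half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    is_pos = labels == positive_class
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_pos = is_pos[order]
    sorted_scores = scores[order]
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    n = scores.size
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            tp += bool(sorted_pos[j])
            fp += not sorted_pos[j]
            j += 1
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return points, auc


@dataclass
class ClassificationReport:
    """Sensitivity/specificity, confusion counts, ROC and AUC for a pair."""

    pair: tuple[str, str]
    positive_class: str
    dataset_role: str  # training | validation | overall
    tp: int
    fp: int
    tn: int
    fn: int
    roc_points: np.ndarray = field(repr=False)
    auc: float = float("nan")

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)


def evaluate_pair(
    model: PairwiseLDAModel,
    pc_scores: np.ndarray,
    labels: np.ndarray,
    role: str = "training",
) -> ClassificationReport:
    """Classify by sign at cutoff 0 and tally the confusion counts.

    A score of exactly 0 is assigned to the positive (diseased) class.
    """
    labels = np.asarray(labels, dtype=object)
    outside = set(labels) - set(model.pair)
    if outside:
        raise ValueError(f"labels outside the model's pair: {sorted(outside)}")
    scores = model.decision_scores(pc_scores)
    is_pos = labels == model.positive_class
    predicted_pos = scores >= model.cutoff
    tp = int(np.sum(predicted_pos & is_pos))
    fp = int(np.sum(predicted_pos & ~is_pos))
    tn = int(np.sum(~predicted_pos & ~is_pos))
    fn = int(np.sum(~predicted_pos & is_pos))
    points, auc = roc_curve(scores, labels, model.positive_class)
    return ClassificationReport(
        pair=model.pair,
        positive_class=model.positive_class,
        dataset_role=role,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        roc_points=points,
        auc=auc,
    )


# ---------------------------------------------------------------------------
# Multiclass map with confidence ellipses
# ---------------------------------------------------------------------------

@dataclass
class ClassEllipse:
    group: str
    centroid: np.ndarray
    covariance: np.ndarray
    semi_axes: np.ndarray  # at 2 standard deviations
    n_inside: int
    n_outside: int


@dataclass
class EllipseSummary:
    ellipses: dict[str, ClassEllipse]
    coordinates: np.ndarray  # (n, 2) discriminant coordinates
    labels: np.ndarray
    inside_own: np.ndarray  # bool per spectrum
    confusion_matrix: pd.DataFrame  # nearest-centroid assignment


def _mahalanobis_sq(points: np.ndarray, center: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = points - center
    return np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)


def confusion_ellipse_analysis(
    pc_scores: np.ndarray, labels: np.ndarray
) -> EllipseSummary:
    """Multiclass Fisher map to 2-D with 2-SD ellipses per group.

    Solves the generalized eigenproblem S_b v = lambda S_w v, keeps the
    two leading discriminant directions, and summarizes each group by its
    centroid, covariance and the ellipse at Mahalanobis distance 2.  A
    conventional nearest-centroid confusion matrix is reported alongside
    the ellipse-membership counts.
    """
    pc_scores = np.asarray(pc_scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes = [g for g in GROUPS if g in set(labels)]
    if len(classes) < 2:
        raise ValueError("need at least two groups")
    for cls in classes:
        if int(np.sum(labels == cls)) < 3:
            raise ValueError(f"group {cls!r} needs >= 3 members")
    overall_mean = pc_scores.mean(axis=0)
    dim = pc_scores.shape[1]
    s_w = np.zeros((dim, dim))
    s_b = np.zeros((dim, dim))
    for cls in classes:
        members = pc_scores[labels == cls]
        centered = members - members.mean(axis=0)
        s_w += centered.T @ centered
        gap = (members.mean(axis=0) - overall_mean)[:, None]
        s_b += members.shape[0] * (gap @ gap.T)
    # Guard a singular S_w with a tiny ridge (keeps eigh well posed).
    s_w = s_w + 1e-10 * np.trace(s_w) / dim * np.eye(dim)
    eigvals, eigvecs = eigh(s_b, s_w)
    directions = eigvecs[:, np.argsort(eigvals)[::-1][:2]]
    coords = (pc_scores - overall_mean) @ directions
    ellipses: dict[str, ClassEllipse] = {}
    inside_own = np.zeros(labels.size, dtype=bool)
    for cls in classes:
        mask = labels == cls
        members = coords[mask]
        centroid = members.mean(axis=0)
        cov = np.cov(members, rowvar=False)
        cov_vals = np.linalg.eigvalsh(cov)
        d2 = _mahalanobis_sq(members, centroid, cov)
        inside = d2 <= 4.0  # Mahalanobis distance <= 2 SD
        inside_own[mask] = inside
        ellipses[cls] = ClassEllipse(
            group=cls,
            centroid=centroid,
            covariance=cov,
            semi_axes=2.0 * np.sqrt(np.clip(cov_vals, 0.0, None))[::-1],
            n_inside=int(inside.sum()),
            n_outside=int((~inside).sum()),
        )
    centroids = np.vstack([ellipses[c].centroid for c in classes])
    dists = np.linalg.norm(coords[:, None, :] - centroids[None, :, :], axis=2)
    assigned = np.array([classes[i] for i in np.argmin(dists, axis=1)], dtype=object)
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for true, pred in zip(labels, assigned):
        confusion.loc[true, pred] += 1
    return EllipseSummary(
        ellipses=ellipses,
        coordinates=coords,
        labels=labels,
        inside_own=inside_own,
        confusion_matrix=confusion,
    )


# ---------------------------------------------------------------------------
# Train/validation split and full staging run
# ---------------------------------------------------------------------------

def train_validation_split(
    dataset: LabeledSpectraSet,
    n_train: int = 50,
    n_valid: int = 10,
    seed: int = 17,
) -> tuple[LabeledSpectraSet, LabeledSpectraSet]:
    """Seeded per-group random split without replacement."""
    rng = np.random.default_rng(seed)
    train, valid = [], []
    for group in GROUPS:
        members = [s for s in dataset if s.group == group]
        if len(members) < n_train + n_valid:
            raise ValueError(
                f"group {group!r} has {len(members)} spectra, need "
                f"{n_train + n_valid} for the split"
            )
        perm = rng.permutation(len(members))
        train.extend(members[i] for i in perm[:n_train])
        valid.extend(members[i] for i in perm[n_train : n_train + n_valid])
    return (
        LabeledSpectraSet(train, grid=dataset.grid),
        LabeledSpectraSet(valid, grid=dataset.grid),
    )


@dataclass
class PairResult:
    model: PairwiseLDAModel
    training: ClassificationReport
    validation: ClassificationReport
    overall: ClassificationReport
    merged_auc: float  # ROC over pooled training+validation scores
    merged_roc_points: np.ndarray


@dataclass
class StagingResult:
    pca: PCAModel
    pairs: dict[tuple[str, str], PairResult]
    ellipse_summary: EllipseSummary

    def report_table(self) -> pd.DataFrame:
        rows = []
        for pair, res in self.pairs.items():
            for report in (res.training, res.validation, res.overall):
                rows.append(
                    {
                        "pair": f"{pair[0]}-{pair[1]}",
                        "positive_class": report.positive_class,
                        "role": report.dataset_role,
                        "sensitivity_pct": report.sensitivity,
                        "specificity_pct": report.specificity,
                        "tp": report.tp,
                        "fp": report.fp,
                        "tn": report.tn,
                        "fn": report.fn,
                        "auc": report.auc,
                        "merged_auc": res.merged_auc,
                    }
                )
        return pd.DataFrame(rows)


def classify_dataset(
    dataset: LabeledSpectraSet,
    n_train: int = 50,
    n_valid: int = 10,
    seed: int = 17,
    variance_threshold: float = 0.95,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
) -> StagingResult:
    """Full staging analysis: split, PCA on training, pairwise LDA, ROC.

    PCA and every discriminant are fitted on the training split only;
    validation spectra are projected through the trained models.  The
    'overall' report pools training and validation spectra of the pair;
    the merged AUC is the ROC over those pooled discriminant scores.
    The multiclass ellipse map is computed on the full dataset projected
    through the training PCA.
    """
    train_set, valid_set = train_validation_split(dataset, n_train, n_valid, seed)
    pca = fit_pca(train_set.intensity_matrix(), variance_threshold)
    results: dict[tuple[str, str], PairResult] = {}
    for pair in pairs:
        tr = train_set.subset(pair)
        va = valid_set.subset(pair)
        tr_scores = pca.transform(tr.intensity_matrix())
        va_scores = pca.transform(va.intensity_matrix())
        model = fit_lda_pairwise(tr_scores, tr.labels(), pair=pair)
        training = evaluate_pair(model, tr_scores, tr.labels(), "training")
        validation = evaluate_pair(model, va_scores, va.labels(), "validation")
        pooled_scores = np.concatenate(
            [model.decision_scores(tr_scores), model.decision_scores(va_scores)]
        )
        pooled_labels = np.concatenate([tr.labels(), va.labels()])
        overall = evaluate_pair(
            model,
            np.vstack([tr_scores, va_scores]),
            pooled_labels,
            "overall",
        )
        merged_points, merged_auc = roc_curve(
            pooled_scores, pooled_labels, model.positive_class
        )
        results[pair] = PairResult(
            model=model,
            training=training,
            validation=validation,
            overall=overall,
            merged_auc=merged_auc,
            merged_roc_points=merged_points,
        )
    all_scores = pca.transform(dataset.intensity_matrix())
    ellipse_summary = confusion_ellipse_analysis(all_scores, dataset.labels())
    return StagingResult(pca=pca, pairs=results, ellipse_summary=ellipse_summary)
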
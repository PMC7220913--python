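"""Connectome-based predictive modeling core.

Per cross-validation fold: motion-sensitive edges are excluded from
candidacy, edges correlated with the behavioral score at p < 0.01 (two
tailed, Student-t transform at df = n_train - 2) are split by sign into
positive and negative sets, each set is summed into a single network
strength, and an ordinary least-squares model maps strengths to scores.
All selection statistics are computed strictly inside the training fold.

The leave-one-out loop is implemented with rank-one downdates of the
full-sample sufficient statistics, so a single fold costs O(n_edges); the
permutation test reuses this path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .cohort import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMask",
    "CPMModel",
    "PredictionResult",
    "critical_r",
    "exclude_motion_edges",
    "select_features",
    "network_strength",
    "fit_model",
    "predict",
    "loocv",
    "loocv_predict",
    "kfold_cv",
    "consensus_features",
    "fit_consensus_model",
    "apply_model",
]

VARIANTS = ("glm", "positive", "negative")


@dataclass
class FeatureMask:
    """Disjoint positive/negative edge index sets selected on a training fold."""

    positive_edges: np.ndarray
    negative_edges: np.ndarray
    selection_p_threshold: float = 0.01

    def __post_init__(self) -> None:
        self.positive_edges = np.sort(np.asarray(self.positive_edges, dtype=int))
        self.negative_edges = np.sort(np.asarray(self.negative_edges, dtype=int))
        if np.intersect1d(self.positive_edges, self.negative_edges).size:
            raise ValueError("positive and negative edge sets must be disjoint")

    @property
    def is_empty(self) -> bool:
        return self.positive_edges.size == 0 and self.negative_edges.size == 0

    def to_dict(self) -> dict:
        return {
            "positive_edges": self.positive_edges.tolist(),
            "negative_edges": self.negative_edges.tolist(),
            "selection_p_threshold": self.selection_p_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureMask":
        return cls(
            positive_edges=np.asarray(d["positive_edges"], dtype=int),
            negative_edges=np.asarray(d["negative_edges"], dtype=int),
            selection_p_threshold=d.get("selection_p_threshold", 0.01),
        )


@dataclass
class CPMModel:
    """Linear strength-to-score model for one variant, with its feature mask."""

    variant: str
    b0: float
    b_pos: float | None = None
    b_neg: float | None = None
    mask: FeatureMask | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.variant in ("glm", "positive") and self.b_pos is None:
            raise ValueError(f"variant {self.variant!r} requires b_pos")
        if self.variant in ("glm", "negative") and self.b_neg is None:
            raise ValueError(f"variant {self.variant!r} requires b_neg")
        for coef in (self.b0, self.b_pos, self.b_neg):
            if coef is not None and not np.isfinite(coef):
                raise ValueError("coefficients must be finite")


@dataclass
class PredictionResult:
    """Observed/predicted score pairs with evaluation statistics."""

    observed: np.ndarray
    predicted: np.ndarray
    r_pred_obs: float = np.nan
    p_parametric: float = np.nan
    p_permutation: float | None = None
    fold_masks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if len(self.observed) != len(self.predicted) or len(self.observed) < 3:
            raise ValueError("observed/predicted must be equal length >= 3")


def _evaluate(observed: np.ndarray, predicted: np.ndarray,
              fold_masks: list | None = None) -> PredictionResult:
    from .stats import pearson_with_p

    if np.std(predicted) == 0 or np.std(observed) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = pearson_with_p(observed, predicted)
    return PredictionResult(observed=observed, predicted=predicted, r_pred_obs=r,
                            p_parametric=p, fold_masks=fold_masks or [])


def critical_r(n: int, alpha: float) -> float:
    """|r| above which the two-tailed correlation p falls below alpha (df = n-2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if alpha <= 0:
        return np.inf
    if alpha >= 1:
        return 0.0
    t = sps.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t / np.sqrt(n - 2 + t**2))


def _columnwise_r(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of X with y; zero-variance columns give r=0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    num = Xc.T @ yc
    den = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.clip(r, -1.0, 1.0)


def exclude_motion_edges(edge_matrix: np.ndarray, mean_fd: np.ndarray,
                         alpha_motion: float = 0.05) -> np.ndarray:
    """Indices of edges NOT significantly correlated with mean FD (admissible)."""
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    mean_fd = np.asarray(mean_fd, dtype=float)
    n = edge_matrix.shape[0]
    if n < 4:
        raise ValueError("need at least 4 participants")
    if np.std(mean_fd) == 0:
        logger.warning("mean FD has zero variance; no motion edges excluded")
        return np.arange(edge_matrix.shape[1])
    r_fd = _columnwise_r(edge_matrix, mean_fd)
    return np.flatnonzero(np.abs(r_fd) < critical_r(n, alpha_motion))


def select_features(edge_matrix_train: np.ndarray, gf_train: np.ndarray,
                    p_threshold: float = 0.01,
                    admissible: np.ndarray | None = None) -> FeatureMask:
    """Split behavior-correlated edges (two-tailed p < threshold) by sign of r."""
    edge_matrix_train = np.asarray(edge_matrix_train, dtype=float)
    gf_train = np.asarray(gf_train, dtype=float)
    n = edge_matrix_train.shape[0]
    if n < 4:
        raise ValueError("need at least 4 training participants")
    if np.std(gf_train) == 0:
        logger.warning("constant behavioral score in training fold; empty mask")
        return FeatureMask(np.array([], int), np.array([], int), p_threshold)
    if admissible is None:
        admissible = np.arange(edge_matrix_train.shape[1])
    admissible = np.asarray(admissible, dtype=int)
    r = _columnwise_r(edge_matrix_train[:, admissible], gf_train)
    r_crit = critical_r(n, p_threshold)
    pos = admissible[r > r_crit]
    neg = admissible[r < -r_crit]
    return FeatureMask(positive_edges=pos, negative_edges=neg,
                       selection_p_threshold=p_threshold)


def network_strength(edge_vector: np.ndarray, mask: FeatureMask) -> tuple[float, float]:
    """Summed edge values over the positive and negative sets (empty set -> 0)."""
    edge_vector = np.asarray(edge_vector, dtype=float)
    s_pos = float(edge_vector[mask.positive_edges].sum()) if mask.positive_edges.size else 0.0
    s_neg = float(edge_vector[mask.negative_edges].sum()) if mask.negative_edges.size else 0.0
    return s_pos, s_neg


def network_strengths(edge_matrix: np.ndarray, mask: FeatureMask) -> np.ndarray:
    """(n, 2) matrix of [S_pos, S_neg] per participant."""
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    n = edge_matrix.shape[0]
    s = np.zeros((n, 2))
    if mask.positive_edges.size:
        s[:, 0] = edge_matrix[:, mask.positive_edges].sum(axis=1)
    if mask.negative_edges.size:
        s[:, 1] = edge_matrix[:, mask.negative_edges].sum(axis=1)
    return s


def _design(strengths: np.ndarray, variant: str) -> np.ndarray:
    strengths = np.atleast_2d(np.asarray(strengths, dtype=float))
    n = strengths.shape[0]
    if variant == "glm":
        return np.column_stack([np.ones(n), strengths[:, 0], strengths[:, 1]])
    if variant == "positive":
        return np.column_stack([np.ones(n), strengths[:, 0]])
    return np.column_stack([np.ones(n), strengths[:, 1]])


def fit_model(strengths: np.ndarray, gf: np.ndarray, variant: str = "glm",
              mask: FeatureMask | None = None) -> CPMModel:
    """Ordinary least squares of scores on network strengths (plus intercept).

    Collinear designs fall back to the minimum-norm pseudoinverse solution.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    gf = np.asarray(gf, dtype=float)
    design = _design(strengths, variant)
    if design.shape[0] < 3:
        raise ValueError("need at least 3 training participants")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("collinear strengths; using pseudoinverse solution")
    beta, *_ = np.linalg.lstsq(design, gf, rcond=None)
    b_pos = b_neg = None
    if variant == "glm":
        b_pos, b_neg = float(beta[1]), float(beta[2])
    elif variant == "positive":
        b_pos = float(beta[1])
    else:
        b_neg = float(beta[1])
    return CPMModel(variant=variant, b0=float(beta[0]), b_pos=b_pos, b_neg=b_neg, mask=mask)


def predict(model: CPMModel, strengths: np.ndarray) -> np.ndarray:
    """Evaluate the fitted linear model at the given [S_pos, S_neg] rows."""
    strengths = np.atleast_2d(np.asarray(strengths, dtype=float))
    out = np.full(strengths.shape[0], model.b0)
    if model.b_pos is not None:
        out = out + model.b_pos * strengths[:, 0]
    if model.b_neg is not None:
        out = out + model.b_neg * strengths[:, 1]
    return out


# ---------------------------------------------------------------------------
# cross-validation


def _effective_variant(variant: str, mask: FeatureMask) -> str:
    """Drop the unused strength when one edge set is empty (identical
    predictions to fitting the full design with a zero column, without the
    collinearity fallback)."""
    if variant == "glm":
        if not mask.positive_edges.size and mask.negative_edges.size:
            return "negative"
        if mask.positive_edges.size and not mask.negative_edges.size:
            return "positive"
    return variant


def _loo_column_r_all(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(n, n_edges) matrix: row i holds per-column r over all rows except i.

    Downdates the full-sample sufficient statistics, vectorized over folds.
    """
    n = X.shape[0]
    m = n - 1
    X2 = X**2
    fx = X.sum(axis=0)[None, :] - X
    fxx = X2.sum(axis=0)[None, :] - X2
    fxy = (X.T @ y)[None, :] - X * y[:, None]
    fy = y.sum() - y
    fyy = y @ y - y**2
    num = m * fxy - fx * fy[:, None]
    den2 = (m * fxx - fx**2) * (m * fyy - fy**2)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den2 > 0, num / np.sqrt(np.maximum(den2, 0.0)), 0.0)
    return np.clip(r, -1.0, 1.0)


def loocv_predict(edges: np.ndarray, gf: np.ndarray, mean_fd: np.ndarray,
                  p_threshold: float = 0.01, variant: str = "glm",
                  alpha_motion: float = 0.05, collect_masks: bool = False,
                  test_edges: np.ndarray | None = None, warn_empty: bool = True):
    """Leave-one-out predictions; optionally score held-out rows of another
    session's edge matrix (``test_edges``, aligned row-for-row).

    Returns ``(predicted, fold_masks)``; ``fold_masks`` is empty unless
    ``collect_masks`` is true.
    """
    edges = np.asarray(edges, dtype=float)
    gf = np.asarray(gf, dtype=float)
    mean_fd = np.asarray(mean_fd, dtype=float)
    n, n_edges = edges.shape
    if n < 10:
        raise ValueError("LOOCV requires at least 10 participants")
    if test_edges is not None:
        test_edges = np.asarray(test_edges, dtype=float)
        if test_edges.shape != edges.shape:
            raise ValueError("test_edges must match the training edge matrix shape")

    r_crit_sel = critical_r(n - 1, p_threshold)
    fd_varies = np.std(mean_fd) > 0
    if not fd_varies and alpha_motion > 0:
        logger.warning("mean FD has zero variance; no motion edges excluded")
    r_crit_fd = critical_r(n - 1, alpha_motion) if (fd_varies and alpha_motion > 0) else np.inf

    r_gf_all = _loo_column_r_all(edges, gf)
    if np.isfinite(r_crit_fd):
        admissible_all = np.abs(_loo_column_r_all(edges, mean_fd)) < r_crit_fd
    else:
        admissible_all = np.ones((n, n_edges), dtype=bool)
    pos_all = admissible_all & (r_gf_all > r_crit_sel)
    neg_all = admissible_all & (r_gf_all < -r_crit_sel)

    use_pos = variant in ("glm", "positive")
    use_neg = variant in ("glm", "negative")
    has_features = ((use_pos & pos_all.any(axis=1))
                    | (use_neg & neg_all.any(axis=1)))

    sum_gf = gf.sum()
    predicted = (sum_gf - gf) / (n - 1)  # empty-mask fallback: training mean
    masks: list[FeatureMask] = []
    idx = np.arange(n)
    for i in range(n):
        if not has_features[i]:
            if collect_masks:
                masks.append(FeatureMask(np.flatnonzero(pos_all[i]),
                                         np.flatnonzero(neg_all[i]), p_threshold))
            if warn_empty:
                logger.warning("fold %d: empty feature mask; predicting training mean", i)
            continue
        pos = np.flatnonzero(pos_all[i])
        neg = np.flatnonzero(neg_all[i])
        mask = FeatureMask(pos, neg, p_threshold)
        if collect_masks:
            masks.append(mask)
        strengths = network_strengths(edges, mask)
        train = idx != i
        model = fit_model(strengths[train], gf[train],
                          variant=_effective_variant(variant, mask), mask=mask)
        held = test_edges[i] if test_edges is not None else edges[i]
        s_held = np.array([network_strength(held, mask)])
        predicted[i] = predict(model, s_held)[0]
    return predicted, masks


def loocv(cohort: Cohort, p_threshold: float = 0.01, variant: str = "glm",
          alpha_motion: float = 0.05,
          test_cohort: Cohort | None = None) -> PredictionResult:
    """Full leave-one-out cross-validation on a cohort.

    If ``test_cohort`` is given (same participants, e.g. a retest session),
    each fold's model is evaluated on the held-out participant's edges from
    that session instead of the training session.
    """
    test_edges = None
    if test_cohort is not None:
        if not np.array_equal(test_cohort.ids, cohort.ids):
            raise ValueError("test cohort must contain the same participants")
        test_edges = test_cohort.edges
    predicted, masks = loocv_predict(
        cohort.edges, cohort.gf, cohort.mean_fd, p_threshold=p_threshold,
        variant=variant, alpha_motion=alpha_motion, collect_masks=True,
        test_edges=test_edges,
    )
    return _evaluate(cohort.gf, predicted, fold_masks=masks)


def kfold_cv(cohort: Cohort, k: int = 20, repeats: int = 50, seed: int = 0,
             p_threshold: float = 0.01, variant: str = "glm",
             alpha_motion: float = 0.05) -> tuple[np.ndarray, tuple[float, float]]:
    """Repeated k-fold cross-validation; one predicted-vs-observed r per repeat.

    Folds are random equal-as-possible partitions (sizes differ by at most 1).
    Returns the r values and their (mean, sd).
    """
    n = cohort.n_participants
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    edges, gf, fd = cohort.edges, cohort.gf, cohort.mean_fd
    r_values = np.empty(repeats)
    for rep in range(repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        predicted = np.empty(n)
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            admissible = (exclude_motion_edges(edges[train], fd[train], alpha_motion)
                          if alpha_motion > 0 and np.std(fd[train]) > 0
                          else np.arange(edges.shape[1]))
            mask = select_features(edges[train], gf[train], p_threshold, admissible)
            use_pos = variant in ("glm", "positive") and mask.positive_edges.size
            use_neg = variant in ("glm", "negative") and mask.negative_edges.size
            if not use_pos and not use_neg:
                predicted[fold] = gf[train].mean()
                continue
            strengths = network_strengths(edges, mask)
            model = fit_model(strengths[train], gf[train],
                              variant=_effective_variant(variant, mask), mask=mask)
            predicted[fold] = predict(model, strengths[fold])
        r_values[rep] = _evaluate(gf, predicted).r_pred_obs
    return r_values, (float(r_values.mean()), float(r_values.std(ddof=1) if repeats > 1 else 0.0))


def consensus_features(per_fold_masks: list[FeatureMask]) -> FeatureMask:
    """Edges selected in every fold (set intersection, per sign)."""
    if not per_fold_masks:
        raise ValueError("need at least one fold mask")
    pos = per_fold_masks[0].positive_edges
    neg = per_fold_masks[0].negative_edges
    for mask in per_fold_masks[1:]:
        pos = np.intersect1d(pos, mask.positive_edges)
        neg = np.intersect1d(neg, mask.negative_edges)
    out = FeatureMask(pos, neg, per_fold_masks[0].selection_p_threshold)
    if out.is_empty:
        logger.warning("consensus feature set is empty")
    return out


def fit_consensus_model(train_cohort: Cohort, consensus: FeatureMask,
                        variant: str = "glm") -> CPMModel:
    """Fit one model on the full training cohort using the consensus mask."""
    if consensus.is_empty:
        raise ValueError("consensus mask is empty")
    strengths = network_strengths(train_cohort.edges, consensus)
    return fit_model(strengths, train_cohort.gf, variant=variant, mask=consensus)


def apply_model(model: CPMModel, test_cohort: Cohort) -> PredictionResult:
    """Score a cohort with a fitted model (edge order must match training)."""
    if model.mask is None:
        raise ValueError("model carries no feature mask")
    needed = max(
        [e.max() for e in (model.mask.positive_edges, model.mask.negative_edges) if e.size],
        default=-1,
    )
    if needed >= test_cohort.n_edges:
        raise ValueError(
            f"model mask references edge {needed} but cohort has {test_cohort.n_edges} edges"
        )
    strengths = network_strengths(test_cohort.edges, model.mask)
    predicted = predict(model, strengths)
    return _evaluate(test_cohort.gf, predicted, fold_masks=[model.mask])
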
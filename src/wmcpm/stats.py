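"""Inference and evaluation: permutation null, partial correlation,
dependent-correlation comparison, and network-level consensus summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .cohort import Cohort
from .connectome import edge_index_pairs
from .cpm import FeatureMask, loocv_predict
from .maskparc import Parcellation

__all__ = [
    "PermutationResult",
    "NetworkEdgeCounts",
    "pearson_with_p",
    "permutation_test",
    "partial_correlation",
    "steiger_z",
    "explained_variance",
    "network_edge_counts",
]


@dataclass
class PermutationResult:
    """Observed statistic versus its shuffled-score null distribution."""

    observed_r: float
    null_r: np.ndarray
    p_permutation: float
    B: int
    seed: int

    def __post_init__(self) -> None:
        self.null_r = np.asarray(self.null_r, dtype=float)
        if len(self.null_r) != self.B:
            raise ValueError("null distribution length must equal B")
        if not 0.0 <= self.p_permutation <= 1.0:
            raise ValueError("p must lie in [0, 1]")


@dataclass
class NetworkEdgeCounts:
    """Symmetric network-by-network count matrix of consensus edges."""

    counts: np.ndarray
    node_degree: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("count matrix must be symmetric")

    @property
    def total_edges(self) -> int:
        upper = np.triu(self.counts, k=1).sum()
        return int(upper + np.diag(self.counts).sum())


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with two-tailed p via the Student-t transform at df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def permutation_test(cohort: Cohort, B: int = 5000, seed: int = 0,
                     p_threshold: float = 0.01, variant: str = "glm",
                     alpha_motion: float = 0.05,
                     smoothed: bool = False) -> PermutationResult:
    """Shuffle scores B times, re-running the full LOOCV prediction each time.

    p = #{null_r >= observed_r} / B (one-sided); ``smoothed`` applies the
    (count + 1) / (B + 1) variant.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    edges, gf, fd = cohort.edges, cohort.gf, cohort.mean_fd

    def run(y: np.ndarray) -> float:
        predicted, _ = loocv_predict(edges, y, fd, p_threshold=p_threshold,
                                     variant=variant, alpha_motion=alpha_motion,
                                     warn_empty=False)
        if np.std(predicted) == 0:
            return 0.0
        return float(np.corrcoef(y, predicted)[0, 1])

    observed = run(gf)
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        null[b] = run(rng.permutation(gf))
    count = int((null >= observed).sum())
    p = (count + 1) / (B + 1) if smoothed else count / B
    return PermutationResult(observed_r=observed, null_r=null, p_permutation=float(p),
                             B=B, seed=seed)


def partial_correlation(x, y, covariates) -> tuple[float, float]:
    """Correlation of x and y after removing covariates (residual method).

    p is two-tailed at df = n - 2 - n_covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != len(x):
        cov = cov.T
    n, p_cov = cov.shape
    if len(x) != n or len(y) != n:
        raise ValueError("covariate rows must match x/y length")
    if n <= p_cov + 2:
        raise ValueError("need n > n_covariates + 2")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        import warnings

        warnings.warn("zero residual variance; partial correlation undefined, returning 0")
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - p_cov
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), df=df))
    return r, p


def steiger_z(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Steiger's (1980) Z for two dependent correlations sharing variable 1.

    Fisher-transforms r12 and r13 and uses the asymptotic covariance based on
    r23 and the mean of the two compared correlations.  Returns (z, two-tailed
    normal p).
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly in (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rm = (r12 + r13) / 2.0
    cov = (r23 * (1.0 - 2.0 * rm**2) - 0.5 * rm**2 * (1.0 - 2.0 * rm**2 - r23**2)) \
        / (1.0 - rm**2) ** 2
    z = (z12 - z13) * np.sqrt((n - 3.0) / (2.0 - 2.0 * cov))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), p


def explained_variance(r: float) -> float:
    """Percent of variance explained by a correlation: 100 * r**2."""
    if abs(r) > 1.0:
        raise ValueError("|r| must be <= 1")
    return 100.0 * r**2


def network_edge_counts(consensus: FeatureMask, parc: Parcellation,
                        n_networks: int | None = None) -> NetworkEdgeCounts:
    """Count consensus edges within and between networks; node degrees too."""
    if not parc.network_of_node:
        raise ValueError("parcellation has no network assignments")
    k = parc.n_nodes
    for node in range(1, k + 1):
        if node not in parc.network_of_node:
            raise ValueError(f"node {node} has no network assignment")
    if n_networks is None:
        n_networks = max(parc.network_of_node.values())
    iu, ju = edge_index_pairs(k)
    counts = np.zeros((n_networks, n_networks), dtype=int)
    degree = {node: 0 for node in range(1, k + 1)}
    all_edges = np.concatenate([consensus.positive_edges, consensus.negative_edges])
    for e in all_edges:
        a, b = int(iu[e]) + 1, int(ju[e]) + 1
        na, nb = parc.network_of_node[a] - 1, parc.network_of_node[b] - 1
        counts[na, nb] += 1
        if na != nb:
            counts[nb, na] += 1
        degree[a] += 1
        degree[b] += 1
    return NetworkEdgeCounts(counts=counts, node_degree=degree)
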
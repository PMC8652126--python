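"""Bootstrap resampling of conditions and per-edge summary statistics.

Edge scores are point estimates; their sampling variability is estimated by
resampling the n conditions (columns) with replacement, re-standardizing each
replicate, and re-scoring. Each edge is then summarized by its bootstrap mean
s_bar, standard error Se, and a t-statistic:

* regression scorers: t = s_bar / Se,
* correlation:        t = s_bar * sqrt(n-2) / sqrt(1 - s_bar^2),

the latter being the classical test statistic for a Pearson correlation with
n-2 degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .exceptions import DegenerateGeneError, ParameterError
from .io import ExpressionMatrix, standardize_values
from .scoring import ScoringParams, pair_index, score

T_SENTINEL = 1e12  # signed stand-in when Se = 0 with a non-zero mean
MAX_REDRAWS = 100  # attempts before a replicate with a constant gene is fatal


@dataclasses.dataclass
class BootstrapSummary:
    """Per-edge bootstrap summary for one scoring method.

    Arrays cover the p(p-1)/2 unordered gene pairs in upper-triangle order.
    """

    method: str
    B: int
    n: int
    mean: np.ndarray
    se: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.se < 0):
            raise ParameterError("bootstrap standard errors must be non-negative")


def bootstrap_scores(
    x: ExpressionMatrix,
    method: str,
    params: ScoringParams | None = None,
    B: int = 100,
    seed: int = 1,
) -> np.ndarray:
    """Per-replicate edge scores: a ``(B, p(p-1)/2)`` matrix.

    Each replicate draws n condition columns with replacement,
    re-standardizes gene rows within the replicate, scores, symmetrizes, and
    records the unordered-pair scores. Deterministic for a fixed seed. A
    replicate that leaves a gene constant is redrawn (up to 100 times).
    """
    if B < 2:
        raise ParameterError(f"need B >= 2 bootstrap samples, got {B}")
    params = params or ScoringParams()
    rng = np.random.default_rng(seed)
    p, n = x.values.shape
    iu = pair_index(p)
    out = np.empty((B, p * (p - 1) // 2))
    cond_ids = [f"b{j}" for j in range(n)]
    for j in range(B):
        for attempt in range(MAX_REDRAWS + 1):
            cols = rng.integers(0, n, size=n)
            sub = x.values[:, cols]
            if np.all(sub.std(axis=1, ddof=1) > 0):
                break
        else:
            raise DegenerateGeneError(
                f"replicate {j}: a gene stayed constant after {MAX_REDRAWS} redraws"
            )
        rep = ExpressionMatrix(
            list(x.gene_ids), cond_ids, standardize_values(sub), standardized=True
        )
        out[j] = score(rep, method, params).scores[iu]
    return out


def summarize_bootstrap(
    replicates: np.ndarray, n: int, method: str
) -> BootstrapSummary:
    """Reduce a ``(B, edges)`` replicate matrix to mean, SE and t per edge.

    mean = (1/B) sum_j s_j ; Se = sqrt( (1/(B-1)) sum_j (s_j - mean)^2 ).
    """
    replicates = np.asarray(replicates, dtype=float)
    if replicates.ndim != 2 or replicates.shape[0] < 2:
        raise ParameterError(
            "need a (B, edges) replicate matrix with B >= 2 "
            f"(got shape {replicates.shape})"
        )
    B = replicates.shape[0]
    mean = replicates.mean(axis=0)
    se = replicates.std(axis=0, ddof=1)
    t = t_statistic(mean, se, n, method)
    return BootstrapSummary(method=method, B=B, n=n, mean=mean, se=se, t=t)


def t_statistic(
    s_bar: np.ndarray | float,
    se: np.ndarray | float,
    n: int,
    method: str,
) -> np.ndarray | float:
    """Per-edge t-statistic; vectorized over edges.

    For the correlation scorer, t = s_bar*sqrt(n-2)/sqrt(1-s_bar^2); a mean
    with |s_bar| >= 1 is clamped to 1 - 1e-12 (with a warning). For the
    regression scorers, t = s_bar/Se; Se = 0 with a non-zero mean yields a
    signed large sentinel (+-1e12, with a warning).
    """
    scalar = np.isscalar(s_bar)
    s_bar = np.atleast_1d(np.asarray(s_bar, dtype=float))
    if method == "correlation":
        clipped = np.abs(s_bar) >= 1.0
        if np.any(clipped):
            warnings.warn(
                f"{int(clipped.sum())} edge(s) with |mean correlation| >= 1 "
                "clamped to 1 - 1e-12",
                stacklevel=2,
            )
        s = np.where(clipped, np.sign(s_bar) * (1.0 - 1e-12), s_bar)
        t = s * np.sqrt(n - 2) / np.sqrt(1.0 - s**2)
    else:
        se = np.atleast_1d(np.asarray(se, dtype=float))
        se = np.broadcast_to(se, s_bar.shape)
        zero_se = se == 0
        degenerate = zero_se & (s_bar != 0)
        if np.any(degenerate):
            warnings.warn(
                f"{int(degenerate.sum())} edge(s) with zero bootstrap SE and "
                "non-zero mean; t set to signed sentinel",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(zero_se, 0.0, s_bar / np.where(zero_se, 1.0, se))
        t = np.where(degenerate, np.sign(s_bar) * T_SENTINEL, t)
    return float(t[0]) if scalar else t
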
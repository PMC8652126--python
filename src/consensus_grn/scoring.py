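"""Per-edge connectivity scores from four methods.

Each scorer maps a standardized genes-by-conditions matrix to a symmetric
p x p matrix of per-gene-pair connectivity scores:

* **correlation** — Pearson correlation of the two gene rows.
* **pcr** — principal-component regression: each gene is regressed on the
  leading k principal components of the remaining genes and the component
  coefficients are back-projected onto genes.
* **pls** — partial least squares: each gene is regressed on v latent
  components built from the remaining genes to maximize covariance with the
  target; per-gene scores are the weight-expanded latent coefficients.
* **ridge** — L2-penalized regression of each gene on all others.

The three regression scorers yield a directional (asymmetric) coefficient
matrix — the coefficient of gene k in the regression targeting gene i need
not equal its converse — which is symmetrized by averaging the two
directions. Diagonals are held at 0 and never reported as edges.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .exceptions import ContractError, DimensionError, ParameterError, SingularityError
from .io import ExpressionMatrix, VALID_METHODS


@dataclasses.dataclass
class ScoringParams:
    """Tuning parameters for the regression scorers.

    pcr_components
        Number of principal components k (1 <= k <= p-1, k < n).
    pls_components
        Number of latent components v (1 <= v <= min(p-1, n)).
    ridge_lambda
        L2 penalty lambda >= 0; lambda = 0 is ordinary least squares and
        requires a full-rank leave-one-gene-out design.

    Defaults k=3, v=3, lambda=1.0 follow the reference R implementation of
    these network scorers.
    """

    pcr_components: int = 3
    pls_components: int = 3
    ridge_lambda: float = 1.0

    def validate_for(self, p: int, n: int) -> None:
        if not (1 <= self.pcr_components <= p - 1):
            raise ParameterError(
                f"pcr_components must be in [1, p-1]={p - 1}, got {self.pcr_components}"
            )
        if self.pcr_components >= n:
            raise ParameterError(
                f"pcr_components must be < n={n}, got {self.pcr_components}"
            )
        if not (1 <= self.pls_components <= min(p - 1, n)):
            raise ParameterError(
                f"pls_components must be in [1, min(p-1, n)]={min(p - 1, n)}, "
                f"got {self.pls_components}"
            )
        if self.ridge_lambda < 0:
            raise ParameterError(
                f"ridge_lambda must be >= 0, got {self.ridge_lambda}"
            )


@dataclasses.dataclass
class EdgeScoreMatrix:
    """Symmetric p x p connectivity scores for one method."""

    gene_ids: list[str]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.method not in VALID_METHODS:
            raise ParameterError(f"unknown scoring method '{self.method}'")
        p = len(self.gene_ids)
        if self.scores.shape != (p, p):
            raise DimensionError(
                f"score matrix shape {self.scores.shape} != ({p}, {p})"
            )

    def pair_scores(self) -> np.ndarray:
        """Upper-triangle scores as a flat vector over unordered pairs."""
        iu = np.triu_indices(len(self.gene_ids), k=1)
        return self.scores[iu]


def pair_index(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the p(p-1)/2 unordered gene pairs (i < k)."""
    return np.triu_indices(p, k=1)


def symmetrize_scores(directional: np.ndarray) -> np.ndarray:
    """Average the two directions of a square score matrix; zero the diagonal."""
    directional = np.asarray(directional, dtype=float)
    if directional.ndim != 2 or directional.shape[0] != directional.shape[1]:
        raise DimensionError(f"expected a square matrix, got {directional.shape}")
    if not np.all(np.isfinite(directional)):
        raise DimensionError("non-finite entries in directional score matrix")
    sym = (directional + directional.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return sym


def _require_standardized(x: ExpressionMatrix) -> None:
    if not x.standardized:
        raise ContractError("scoring requires a standardized expression matrix")


def score_correlation(x: ExpressionMatrix) -> EdgeScoreMatrix:
    """Pearson correlation of every gene pair.

    On standardized rows this is x_i . x_k / sqrt((x_i . x_i)(x_k . x_k)).
    """
    _require_standardized(x)
    v = x.values
    dots = v @ v.T
    norms = np.sqrt(np.diag(dots))
    scores = dots / np.outer(norms, norms)
    scores = symmetrize_scores(scores)
    return EdgeScoreMatrix(list(x.gene_ids), scores, "correlation")


def _eig_components(predictors: np.ndarray, k: int) -> np.ndarray:
    """First k eigenvectors (descending eigenvalue) of the predictor scatter.

    ``predictors`` is (m, n): m gene rows over n conditions. Eigenvectors are
    sign-fixed so each vector's largest-magnitude entry is positive.
    """
    scatter = predictors @ predictors.T
    w, v = np.linalg.eigh(scatter)  # ascending
    order = np.argsort(w)[::-1][:k]
    vk = v[:, order]
    for j in range(vk.shape[1]):
        idx = np.argmax(np.abs(vk[:, j]))
        if vk[idx, j] < 0:
            vk[:, j] = -vk[:, j]
    return vk


def score_pcr(x: ExpressionMatrix, k: int) -> EdgeScoreMatrix:
    """Principal-component-regression connectivity scores.

    For each target gene g: project the remaining p-1 gene rows onto their
    first k principal components, regress gene g on the component scores, and
    back-transform the fitted coefficients through the eigenvector matrix to
    one coefficient per predictor gene. The directional matrix is then
    symmetrized by averaging.
    """
    _require_standardized(x)
    p, n = x.values.shape
    if not (1 <= k <= p - 1):
        raise ParameterError(f"pcr components k must be in [1, {p - 1}], got {k}")
    if k >= n:
        raise ParameterError(f"pcr components k must be < n={n}, got {k}")
    directional = np.zeros((p, p))
    for g in range(p):
        others = np.delete(np.arange(p), g)
        preds = x.values[others]  # (p-1, n)
        y = x.values[g]
        vk = _eig_components(preds, k)  # (p-1, k)
        t = preds.T @ vk  # (n, k) component scores
        beta, _, rank, _ = np.linalg.lstsq(t, y, rcond=None)
        if rank < k:
            warnings.warn(
                f"rank-deficient component scores for gene '{x.gene_ids[g]}' "
                f"(rank {rank} < k={k}); least-squares pseudo-solution used",
                stacklevel=2,
            )
        directional[g, others] = vk @ beta
    scores = symmetrize_scores(directional)
    return EdgeScoreMatrix(list(x.gene_ids), scores, "pcr")


def score_pls(x: ExpressionMatrix, v: int) -> EdgeScoreMatrix:
    """Partial-least-squares connectivity scores.

    For each target gene i with predictor block X (conditions x other genes),
    v latent components are extracted: the direction weights for component l
    are c^(l) = X^(l)T x_i normalized to unit length, the latent scores are
    t^(l) = X^(l) c^(l), and the latent regression coefficient is
    b_l = (t^(l)T t^(l))^-1 t^(l)T x_i. The predictor block is deflated by
    regressing out t^(l) after each component (NIPALS). Gene k's directional
    score is sum_l b_l c_k^(l); the two directions are averaged.

    Components beyond the rank of the predictor block contribute nothing and
    extraction stops early with a warning.
    """
    _require_standardized(x)
    p, n = x.values.shape
    if not (1 <= v <= min(p - 1, n)):
        raise ParameterError(
            f"pls components v must be in [1, min(p-1, n)]={min(p - 1, n)}, got {v}"
        )
    directional = np.zeros((p, p))
    scale = np.linalg.norm(x.values)
    tol = 1e-12 * max(scale, 1.0)
    for i in range(p):
        others = np.delete(np.arange(p), i)
        block = x.values[others].T.copy()  # (n, p-1), deflated in place
        y = x.values[i]
        coef = np.zeros(p - 1)
        for l in range(v):
            w = block.T @ y
            nw = np.linalg.norm(w)
            if nw <= tol:
                if l == 0:
                    break
                warnings.warn(
                    f"pls: predictor block for gene '{x.gene_ids[i]}' exhausted "
                    f"after {l} component(s); v capped",
                    stacklevel=2,
                )
                break
            w = w / nw
            t = block @ w
            tt = t @ t
            if tt <= tol**2:
                break
            b = (t @ y) / tt
            coef += b * w
            block = block - np.outer(t, (t @ block) / tt)
        directional[i, others] = coef
    scores = symmetrize_scores(directional)
    return EdgeScoreMatrix(list(x.gene_ids), scores, "pls")


def score_ridge(x: ExpressionMatrix, ridge_lambda: float) -> EdgeScoreMatrix:
    """Ridge-regression connectivity scores.

    For each target gene g the directional scores are
    (Xg'T Xg' + lambda I)^-1 Xg'T x_g where Xg' stacks all other gene rows as
    predictor columns. lambda = 0 reduces to OLS and requires full rank.
    """
    _require_standardized(x)
    p, n = x.values.shape
    if ridge_lambda < 0:
        raise ParameterError(f"ridge lambda must be >= 0, got {ridge_lambda}")
    directional = np.zeros((p, p))
    eye = np.eye(p - 1)
    for g in range(p):
        others = np.delete(np.arange(p), g)
        design = x.values[others].T  # (n, p-1)
        y = x.values[g]
        gram = design.T @ design
        if ridge_lambda == 0 and np.linalg.matrix_rank(design) < p - 1:
            raise SingularityError(
                f"leave-one-out design for gene '{x.gene_ids[g]}' is rank-deficient "
                "with lambda=0; use lambda > 0"
            )
        directional[g, others] = np.linalg.solve(
            gram + ridge_lambda * eye, design.T @ y
        )
    scores = symmetrize_scores(directional)
    return EdgeScoreMatrix(list(x.gene_ids), scores, "ridge")


def score(
    x: ExpressionMatrix, method: str, params: ScoringParams | None = None
) -> EdgeScoreMatrix:
    """Dispatch to one of the four scorers by method label."""
    params = params or ScoringParams()
    if method == "correlation":
        return score_correlation(x)
    if method == "pcr":
        return score_pcr(x, params.pcr_components)
    if method == "pls":
        return score_pls(x, params.pls_components)
    if method == "ridge":
        return score_ridge(x, params.ridge_lambda)
    raise ParameterError(f"unknown scoring method '{method}'")
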
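"""Synthetic expression data with a planted regulatory network.

Ground truth is a Gaussian graphical model: a sparse symmetric positive-
definite precision matrix Omega whose off-diagonal zero pattern encodes the
non-edges. Expression profiles are i.i.d. multivariate-normal draws with
covariance Omega^-1, so the planted edges are exactly the gene pairs with
non-zero partial correlation — the quantity the regression scorers target —
which makes edge-recovery tests against this generator meaningful.

Construction: planted off-diagonals are set to +-strength with random signs,
the diagonal is boosted to (row absolute sum + 0.1) to force diagonal
dominance (hence positive definiteness), and the matrix is rescaled to unit
diagonal so off-diagonals are negated partial correlations. The realized
|partial correlation| of a planted edge is strength / (degree*strength + 0.1),
below the nominal strength for genes with degree >= 2.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import ExpressionMatrix

MIN_EIGENVALUE = 1e-8


@dataclasses.dataclass
class PlantedNetwork:
    """A known sparse Gaussian-graphical-model ground truth.

    ``edges`` maps each unordered planted pair (i, k), i < k, to its signed
    realized partial correlation. ``precision`` is the p x p unit-diagonal
    precision matrix Omega.
    """

    p: int
    edges: dict[tuple[int, int], float]
    precision: np.ndarray

    def __post_init__(self) -> None:
        omega = np.asarray(self.precision, dtype=float)
        if omega.shape != (self.p, self.p) or not np.allclose(omega, omega.T):
            raise ParameterError("precision matrix must be symmetric p x p")
        if np.linalg.eigvalsh(omega)[0] <= MIN_EIGENVALUE:
            raise ParameterError("precision matrix is not positive definite")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.p)]

    def edge_frame(self) -> pd.DataFrame:
        """Ground-truth edge list: gene_a, gene_b, partial_correlation."""
        ids = self.gene_ids
        rows = [
            {"gene_a": ids[i], "gene_b": ids[k], "partial_correlation": rho}
            for (i, k), rho in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "partial_correlation"])

    def adjacency(self) -> np.ndarray:
        """Boolean p x p adjacency of planted edges."""
        adj = np.zeros((self.p, self.p), dtype=bool)
        for i, k in self.edges:
            adj[i, k] = adj[k, i] = True
        return adj


def make_planted_network(
    p: int, n_edges: int, strength: float = 0.5, seed: int = 1
) -> PlantedNetwork:
    """Plant ``n_edges`` random edges of nominal partial-correlation strength.

    Pairs are chosen uniformly without replacement; signs are random.
    Deterministic for a fixed seed. ``n_edges = 0`` yields the identity
    precision (pure independence, the calibration null).
    """
    max_edges = p * (p - 1) // 2
    if not (0 <= n_edges <= max_edges):
        raise ParameterError(
            f"n_edges must be in [0, p(p-1)/2]={max_edges}, got {n_edges}"
        )
    if not (0 < strength < 1):
        raise ParameterError(f"strength must be in (0, 1), got {strength}")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, k=1)
    chosen = rng.choice(max_edges, size=n_edges, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_edges)

    omega = np.zeros((p, p))
    for idx, sign in zip(chosen, signs):
        i, k = int(iu[0][idx]), int(iu[1][idx])
        omega[i, k] = omega[k, i] = sign * strength
    np.fill_diagonal(omega, np.abs(omega).sum(axis=1) + 0.1)
    # rescale to unit diagonal: off-diagonals become negated partial correlations
    d = np.sqrt(np.diag(omega))
    omega = omega / np.outer(d, d)
    np.fill_diagonal(omega, 1.0)

    edges = {
        (int(iu[0][idx]), int(iu[1][idx])): float(
            -omega[int(iu[0][idx]), int(iu[1][idx])]
        )
        for idx in chosen
    }
    return PlantedNetwork(p=p, edges=edges, precision=omega)


def simulate_expression(
    net: PlantedNetwork, n: int, seed: int = 1
) -> ExpressionMatrix:
    """Draw n i.i.d. conditions from N(0, Omega^-1); genes in rows.

    Gene ids g1..gp, condition ids c1..cn. Deterministic for a fixed seed.
    """
    if n < 4:
        raise ParameterError(f"need n >= 4 conditions, got {n}")
    rng = np.random.default_rng(seed)
    cov = np.linalg.inv(net.precision)
    chol = np.linalg.cholesky(cov)
    values = chol @ rng.standard_normal((net.p, n))
    return ExpressionMatrix(
        gene_ids=net.gene_ids,
        condition_ids=[f"c{j + 1}" for j in range(n)],
        values=values,
        standardized=False,
    )


def write_expression_csv(x: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix in the pipeline's input CSV dialect."""
    df = pd.DataFrame(x.values, index=x.gene_ids, columns=x.condition_ids)
    df.index.name = "gene"
    df.to_csv(path)


def write_truth_csv(net: PlantedNetwork, path: str | Path) -> None:
    """Write the ground-truth edge list (gene_a, gene_b, partial_correlation)."""
    net.edge_frame().to_csv(path, index=False)
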
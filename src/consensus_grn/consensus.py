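"""Fisher combination of per-method p-values into a consensus edge score.

Each gene pair carries one p-value per scoring method. Fisher's statistic

    Fw = -2 * sum_m ln p_m

is chi-square with 2m degrees of freedom when the m p-values are independent
and uniform under the null, giving a combined p-value per edge. The four
methods share the same data so the p-values are positively dependent and the
chi-square reference is mildly anti-conservative; Benjamini-Hochberg
adjustment of the combined p-values is therefore applied by default before
selecting consensus edges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError

P_FLOOR = 1e-300  # prevents -ln(0); floored edges are flagged

DEFAULT_ALPHA = 0.05


def fisher_combine(
    *p_values: np.ndarray | float, weights: np.ndarray | None = None
) -> np.ndarray | float:
    """Fisher's combined statistic Fw = -2 * sum_m ln p_m.

    Accepts m scalars or m equal-length vectors (one per method, vectorized
    over edges). Computed as a sum of logs, never a product, so tiny
    p-values cannot underflow. Zero p-values are floored at 1e-300.

    ``weights`` (optional, default all 1) generalizes to
    Fw = -2 * sum_m w_m ln p_m; the unweighted form is the standard one.
    """
    if len(p_values) < 1:
        raise ParameterError("need at least one p-value vector")
    scalar = all(np.isscalar(p) for p in p_values)
    mat = np.vstack([np.atleast_1d(np.asarray(p, dtype=float)) for p in p_values])
    if np.any((mat < 0) | (mat > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    mat = np.maximum(mat, P_FLOOR)
    if weights is None:
        fw = -2.0 * np.log(mat).sum(axis=0)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (mat.shape[0],):
            raise ParameterError(
                f"weights must have one entry per method ({mat.shape[0]})"
            )
        fw = -2.0 * (w[:, None] * np.log(mat)).sum(axis=0)
    return float(fw[0]) if scalar else fw


def combined_p(fw: np.ndarray | float, n_methods: int = 4) -> np.ndarray | float:
    """Upper-tail chi-square(2m) probability of the Fisher statistic."""
    scalar = np.isscalar(fw)
    fw_arr = np.atleast_1d(np.asarray(fw, dtype=float))
    if np.any(fw_arr < 0):
        raise ParameterError("Fisher statistic must be non-negative")
    if n_methods < 1:
        raise ParameterError("need at least one method")
    p = stats.chi2.sf(fw_arr, df=2 * n_methods)
    return float(p[0]) if scalar else p


def build_consensus_table(
    gene_a: list[str],
    gene_b: list[str],
    per_method_p: dict[str, np.ndarray],
    alpha: float = DEFAULT_ALPHA,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Assemble the per-edge consensus table.

    Columns: gene_a, gene_b, p_<method> per method, Fw, p_combined,
    q_combined (BH-adjusted), floored (any per-method p at the 1e-300
    floor), significant.
    """
    if len(per_method_p) < 2:
        raise ParameterError(
            "Fisher combination needs p-values from at least 2 methods; "
            f"got {sorted(per_method_p)}"
        )
    methods = list(per_method_p)
    mat = np.vstack([np.asarray(per_method_p[m], dtype=float) for m in methods])
    fw = fisher_combine(*mat)
    p_comb = combined_p(fw, n_methods=len(methods))
    q_comb = multipletests(p_comb, method="fdr_bh")[1]
    table = pd.DataFrame({"gene_a": gene_a, "gene_b": gene_b})
    for m in methods:
        table[f"p_{_short(m)}"] = per_method_p[m]
    table["Fw"] = fw
    table["p_combined"] = p_comb
    table["q_combined"] = q_comb
    table["floored"] = (mat <= P_FLOOR).any(axis=0)
    if adjust == "bh":
        table["significant"] = table["q_combined"] <= alpha
    elif adjust == "none":
        table["significant"] = table["p_combined"] <= alpha
    else:
        raise ParameterError(f"adjust must be 'bh' or 'none', got '{adjust}'")
    return table


def _short(method: str) -> str:
    return "cor" if method == "correlation" else method


def select_significant(
    table: pd.DataFrame, alpha: float = DEFAULT_ALPHA, adjust: str = "bh"
) -> pd.DataFrame:
    """Filter a consensus table to significant edges, sorted by descending Fw.

    adjust='bh' (default): Benjamini-Hochberg step-up on p_combined across
    all edges, keep q <= alpha. adjust='none': keep p_combined <= alpha.
    """
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if adjust == "bh":
        q = multipletests(table["p_combined"].to_numpy(), method="fdr_bh")[1]
        keep = q <= alpha
    elif adjust == "none":
        keep = table["p_combined"].to_numpy() <= alpha
    else:
        raise ParameterError(f"adjust must be 'bh' or 'none', got '{adjust}'")
    out = table.loc[keep].copy()
    return out.sort_values(
        by=["Fw", "gene_a", "gene_b"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
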
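"""Independent brute-force oracles used to verify the scorers.

Deliberately slow, literal transcriptions kept free of any code shared with
the package: textbook Pearson correlation from the covariance definition,
OLS via the normal equations, ridge via a direct linear solve, and PLS via
explicit per-component loops.
"""

import math

import numpy as np


def pearson_brute(a, b):
    """Textbook Pearson correlation of two sequences."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
    va = sum((ai - ma) ** 2 for ai in a)
    vb = sum((bi - mb) ** 2 for bi in b)
    return cov / math.sqrt(va * vb)


def ols_directional(values):
    """OLS coefficients of each gene on all others, via the normal equations."""
    p = values.shape[0]
    directional = np.zeros((p, p))
    for g in range(p):
        others = [k for k in range(p) if k != g]
        design = values[others].T
        beta = np.linalg.inv(design.T @ design) @ design.T @ values[g]
        directional[g, others] = beta
    return directional


def ridge_directional(values, lam):
    """Ridge coefficients of each gene on all others, via a direct solve."""
    p = values.shape[0]
    directional = np.zeros((p, p))
    for g in range(p):
        others = [k for k in range(p) if k != g]
        design = values[others].T
        directional[g, others] = np.linalg.solve(
            design.T @ design + lam * np.eye(p - 1), design.T @ values[g]
        )
    return directional


def pcr_directional(values, k):
    """Literal PCR transcription: eigendecomposition of the leave-one-out
    predictor scatter, regression on the first k component scores,
    back-projection through the eigenvectors."""
    p = values.shape[0]
    directional = np.zeros((p, p))
    for g in range(p):
        others = [i for i in range(p) if i != g]
        preds = values[others]
        scatter = preds @ preds.T
        eigvals, eigvecs = np.linalg.eigh(scatter)
        order = np.argsort(eigvals)[::-1][:k]
        vk = eigvecs[:, order]
        scores = preds.T @ vk
        beta = np.linalg.inv(scores.T @ scores) @ scores.T @ values[g]
        directional[g, others] = vk @ beta
    return directional


def pls_directional(values, v):
    """Literal per-component PLS transcription: unit-norm weights
    c^(l) = X^(l)T x_i / ||X^(l)T x_i||, latent scores t^(l) = X^(l) c^(l),
    latent coefficients b_l = (t^T t)^-1 t^T x_i, NIPALS deflation of X,
    directional score sum_l b_l c_k^(l)."""
    p = values.shape[0]
    directional = np.zeros((p, p))
    for i in range(p):
        others = [k for k in range(p) if k != i]
        block = values[others].T.copy()
        y = values[i]
        coef = np.zeros(p - 1)
        for _ in range(v):
            w = block.T @ y
            norm_w = math.sqrt(float(w @ w))
            if norm_w < 1e-12:
                break
            w = w / norm_w
            t = block @ w
            tt = float(t @ t)
            if tt < 1e-24:
                break
            b = float(t @ y) / tt
            coef = coef + b * w
            block = block - np.outer(t, (t @ block) / tt)
        directional[i, others] = coef
    return directional


def symmetrized(directional):
    out = (directional + directional.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out
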
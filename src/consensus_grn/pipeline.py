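"""End-to-end consensus-GRN pipeline.

Read and standardize the expression matrix; per scoring method: bootstrap
the edge scores, summarize to t-statistics, fit the empirical null and
derive p/fdr values, and write a per-method edge table; finally combine the
per-method p-values with Fisher's method and write the full and significant
consensus tables plus a JSON run manifest.

All four methods are scored on the *same* bootstrap resamples (the replicate
column draws depend only on the seed and the data), so their per-edge
statistics are paired.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import bootstrap_scores, summarize_bootstrap, t_statistic
from .consensus import build_consensus_table, select_significant
from .exceptions import ParameterError
from .io import (
    EdgeTable,
    ExpressionMatrix,
    VALID_METHODS,
    drop_constant_genes,
    read_expression_matrix,
    standardize,
    write_edge_table,
)
from .scoring import ScoringParams, pair_index, score
from .significance import edge_stats

logger = logging.getLogger("consensus_grn")

METHOD_ALIASES = {
    "cor": "correlation",
    "correlation": "correlation",
    "pcr": "pcr",
    "pls": "pls",
    "ridge": "ridge",
}


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of one pipeline run; validated before any compute."""

    input: str | Path
    outdir: str | Path
    B: int = 100
    seed: int = 1
    pcr_k: int = 3
    pls_v: int = 3
    ridge_lambda: float = 1.0
    alpha: float = 0.05
    adjust: str = "bh"
    drop_constant: bool = False
    methods: tuple[str, ...] = VALID_METHODS
    cor_t_source: str = "bootstrap-mean"

    def __post_init__(self) -> None:
        self.methods = tuple(
            METHOD_ALIASES.get(m, m) for m in self.methods
        )
        unknown = [m for m in self.methods if m not in VALID_METHODS]
        if unknown:
            raise ParameterError(f"unknown method(s): {', '.join(unknown)}")
        if len(set(self.methods)) != len(self.methods):
            raise ParameterError("duplicate methods in selection")
        if len(self.methods) < 2:
            raise ParameterError(
                "Fisher combination needs at least 2 methods; "
                f"got {list(self.methods)}"
            )
        if self.B < 2:
            raise ParameterError(f"need B >= 2 bootstrap samples, got {self.B}")
        if not (0 < self.alpha < 1):
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.adjust not in ("bh", "none"):
            raise ParameterError(f"adjust must be 'bh' or 'none', got '{self.adjust}'")
        if self.cor_t_source not in ("bootstrap-mean", "full-data"):
            raise ParameterError(
                "cor_t_source must be 'bootstrap-mean' or 'full-data', "
                f"got '{self.cor_t_source}'"
            )

    @property
    def scoring_params(self) -> ScoringParams:
        return ScoringParams(
            pcr_components=self.pcr_k,
            pls_components=self.pls_v,
            ridge_lambda=self.ridge_lambda,
        )


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full workflow; returns a name -> path map of outputs.

    Emits edges_<method>.csv per method (score, t, p, fdr), consensus_all.csv,
    consensus_significant.csv and manifest.json into the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    x = read_expression_matrix(config.input)
    logger.info("read %d genes x %d conditions from %s", x.p, x.n, config.input)
    if config.drop_constant:
        x, dropped = drop_constant_genes(x)
        if dropped:
            logger.info("dropped %d constant gene(s): %s", len(dropped), dropped)
    xs = standardize(x)
    config.scoring_params.validate_for(xs.p, xs.n)

    iu = pair_index(xs.p)
    gene_a = [xs.gene_ids[i] for i in iu[0]]
    gene_b = [xs.gene_ids[k] for k in iu[1]]

    outputs: dict[str, Path] = {}
    per_method_p: dict[str, np.ndarray] = {}
    for method in config.methods:
        stage0 = time.perf_counter()
        full_scores = score(xs, method, config.scoring_params).scores[iu]
        reps = bootstrap_scores(
            xs, method, config.scoring_params, B=config.B, seed=config.seed
        )
        summary = summarize_bootstrap(reps, n=xs.n, method=method)
        t = summary.t
        if method == "correlation" and config.cor_t_source == "full-data":
            t = t_statistic(full_scores, summary.se, xs.n, method)
        p, fdr, null = edge_stats(t)
        per_method_p[method] = p
        table = EdgeTable(
            df=pd.DataFrame(
                {
                    "gene_a": gene_a,
                    "gene_b": gene_b,
                    "score": full_scores,
                    "t": t,
                    "p": p,
                    "fdr": fdr,
                }
            ),
            method=method,
        )
        path = outdir / f"edges_{method}.csv"
        write_edge_table(table, path)
        outputs[f"edges_{method}"] = path
        logger.info(
            "%s: B=%d bootstrap, sigma0=%.3f, eta0=%.3f (%.2fs)",
            method, config.B, null.sigma0, null.eta0,
            time.perf_counter() - stage0,
        )

    consensus = build_consensus_table(
        gene_a, gene_b, per_method_p, alpha=config.alpha, adjust=config.adjust
    )
    all_path = outdir / "consensus_all.csv"
    consensus.sort_values(
        by=["Fw", "gene_a", "gene_b"], ascending=[False, True, True], kind="stable"
    ).to_csv(all_path, index=False)
    outputs["consensus_all"] = all_path

    significant = select_significant(
        consensus, alpha=config.alpha, adjust=config.adjust
    )
    sig_path = outdir / "consensus_significant.csv"
    significant.to_csv(sig_path, index=False)
    outputs["consensus_significant"] = sig_path
    logger.info(
        "consensus: %d/%d edges significant at alpha=%g (%s)",
        len(significant), len(consensus), config.alpha, config.adjust,
    )

    manifest = {
        "package": "consensus-grn",
        "version": __version__,
        "input": str(config.input),
        "outdir": str(outdir),
        "genes": xs.p,
        "conditions": xs.n,
        "B": config.B,
        "seed": config.seed,
        "pcr_k": config.pcr_k,
        "pls_v": config.pls_v,
        "ridge_lambda": config.ridge_lambda,
        "alpha": config.alpha,
        "adjust": config.adjust,
        "drop_constant": config.drop_constant,
        "methods": list(config.methods),
        "cor_t_source": config.cor_t_source,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    outputs["manifest"] = manifest_path
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return outputs
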
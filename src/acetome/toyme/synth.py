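"""Synthetic noisy expression datasets with known ground truth.

Stands in for RNA-seq comparison data: observed expression is the model's
true transcription flux under multiplicative lognormal noise, plus a set
of null genes whose values are drawn independently of growth.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

__all__ = ["synth_expression_dataset"]


def synth_expression_dataset(
    sweep,
    noise_sd: float,
    n_null_genes: int,
    seed: int,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Build an expression table from a sweep plus planted null genes.

    Returns ``(table, labels)``: the table has one row per gene and one
    column per sweep grid point; labels are ``"linked"`` for model genes
    whose true transcription flux correlates with growth at r > 0.9,
    ``"unlinked"`` for other model genes, ``"null"`` for planted genes.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    points = [s for s in sweep.solutions if s is not None and s.status == "optimal"]
    if not points:
        raise ValueError("sweep has no solved points")
    mus = np.array([s.mu_star for s in points])
    gene_ids = sorted(points[0].expression_fluxes)
    rows: Dict[str, np.ndarray] = {}
    labels: Dict[str, str] = {}
    for gid in gene_ids:
        true = np.array([s.expression_fluxes.get(gid, 0.0) for s in points])
        eps = rng.normal(0.0, noise_sd, size=true.shape) if noise_sd > 0 else 0.0
        rows[gid] = true * np.exp(eps)
        if np.std(true) == 0 or np.std(mus) == 0:
            labels[gid] = "unlinked"
        else:
            r = np.corrcoef(true, mus)[0, 1]
            labels[gid] = "linked" if r > 0.9 else "unlinked"
    scale = np.mean([np.mean(v) for v in rows.values()]) or 1.0
    for i in range(n_null_genes):
        base = scale * rng.lognormal(0.0, 1.0)
        eps = rng.normal(0.0, max(noise_sd, 1e-12), size=mus.shape)
        rows[f"null_{i}"] = base * np.exp(eps)
        labels[f"null_{i}"] = "null"
    table = pd.DataFrame(rows, index=[f"point_{i}" for i in range(len(points))]).T
    return table, pd.Series(labels, name="label")
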
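"""Expression-growth correlation with permutation p-values.

Per-gene Pearson r of predicted transcription flux against growth rate
across sweep points, with p-values from shuffles of the expression vector
(1000 random shuffles by default, or every permutation when requested) and
Bonferroni correction over the genes whose r is defined.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .sweeps import SweepResult

__all__ = [
    "CorrelationResult",
    "expression_growth_corr",
    "correlation_from_table",
    "correlate_vs_substrate",
    "aggregate_by_category",
    "pearson_with_permutation",
]

ALPHA = 0.05


@dataclass
class CorrelationResult:
    table: pd.DataFrame  # index gene, columns r, rho, p_perm, significant
    n_permutations: int
    seed: int
    n_points: int
    exhaustive: bool = False

    @property
    def n_defined(self) -> int:
        return int(self.table["r"].notna().sum())

    def significant_genes(self, r_threshold: float = 0.0) -> List[str]:
        t = self.table
        mask = t["significant"] & (t["r"] > r_threshold)
        return sorted(t.index[mask])


def _gather_points(
    sweeps: Union[SweepResult, Sequence[SweepResult]],
) -> Tuple[np.ndarray, pd.DataFrame]:
    if isinstance(sweeps, SweepResult):
        sweeps = [sweeps]
    mus: List[float] = []
    rows: List[Dict[str, float]] = []
    for sweep in sweeps:
        for _, sol in sweep.solved_points():
            if sol.status != "optimal":
                continue
            mus.append(sol.mu_star)
            rows.append(sol.expression_fluxes)
    if len(mus) < 4:
        raise ValueError("need at least 4 solved grid points for correlation")
    expr = pd.DataFrame(rows).fillna(0.0)
    return np.asarray(mus), expr


def _batch_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of X (m x n) against y (n)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Xc @ yc) / denom


def pearson_with_permutation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    exhaustive: bool = False,
) -> Tuple[float, float]:
    """Pearson r and two-sided permutation p for a single gene.

    Sampled: ``p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm)``.
    Exhaustive: the exact fraction over all n! orderings of x.
    r is NaN (p 1.0) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), 1.0
    r_obs = float(np.corrcoef(x, y)[0, 1])
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(len(x)))))
        perm_r = _batch_pearson(x[perms], y)
        exceed = int(np.sum(np.abs(perm_r) >= abs(r_obs) - 1e-12))
        return r_obs, exceed / len(perms)
    exceed = 0
    for _ in range(n_perm):
        r_p = np.corrcoef(rng.permutation(x), y)[0, 1]
        if abs(r_p) >= abs(r_obs) - 1e-12:
            exceed += 1
    return r_obs, (1 + exceed) / (1 + n_perm)


def correlation_from_table(
    table: pd.DataFrame,
    mus: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    plus_one: bool = True,
) -> CorrelationResult:
    """Correlation of each row of ``table`` (genes x points) against growth.

    ``plus_one=True`` (default) uses the add-one estimator
    ``(1 + k)/(1 + n_perm)`` whose minimum is ``1/(n_perm + 1)``;
    ``plus_one=False`` uses the plain fraction ``k/n_perm``, which can
    reach zero and is what a shuffle-count screen applies before a
    Bonferroni threshold finer than ``1/n_perm``.
    """
    mus = np.asarray(mus, dtype=float)
    n_points = len(mus)
    if table.shape[1] != n_points:
        raise ValueError("table columns must match the number of points")
    rng = np.random.default_rng(seed)
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n_points))))
    else:
        # one shared permutation batch keeps the run deterministic and fast
        perms = np.stack([rng.permutation(n_points) for _ in range(n_perm)])
    mu_std = mus.std()
    records = {}
    for gene, row in table.iterrows():
        x = row.to_numpy(dtype=float)
        if np.std(x) == 0 or mu_std == 0:
            records[gene] = (float("nan"), float("nan"), 1.0)
            continue
        r_obs = float(np.corrcoef(x, mus)[0, 1])
        rho = float(stats.spearmanr(x, mus).statistic)
        perm_r = _batch_pearson(x[perms], mus)
        exceed = int(np.sum(np.abs(perm_r) >= abs(r_obs) - 1e-12))
        if exhaustive:
            p = exceed / len(perms)
        elif plus_one:
            p = (1 + exceed) / (1 + n_perm)
        else:
            p = exceed / n_perm
        records[gene] = (r_obs, rho, p)
    out = pd.DataFrame.from_dict(
        records, orient="index", columns=["r", "rho", "p_perm"]
    ).sort_index()
    n_defined = int(out["r"].notna().sum())
    threshold = ALPHA / max(n_defined, 1)
    out["significant"] = out["p_perm"] < threshold
    out.loc[out["r"].isna(), "significant"] = False
    return CorrelationResult(
        table=out,
        n_permutations=len(perms) if exhaustive else n_perm,
        seed=seed,
        n_points=n_points,
        exhaustive=exhaustive,
    )


def expression_growth_corr(
    sweeps: Union[SweepResult, Sequence[SweepResult]],
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    plus_one: bool = True,
) -> CorrelationResult:
    """Correlate each gene's expression flux with growth across sweep points."""
    mus, expr = _gather_points(sweeps)
    return correlation_from_table(
        expr.T, mus, n_perm=n_perm, seed=seed, exhaustive=exhaustive,
        plus_one=plus_one,
    )


def correlate_vs_substrate(
    sweep: SweepResult,
    gene_set: Iterable[str],
    normalization: str = "max",
) -> Tuple[float, float]:
    """(r vs substrate uptake, r vs growth) for a summed, normalized gene set.

    Each gene's expression is scaled by its maximum (``max``) or its sum
    (``sum``) across points before summing over the set.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set must be non-empty")
    points = [(g, s) for g, s in sweep.solved_points() if s.status == "optimal"]
    if len(points) < 2:
        raise ValueError("need at least 2 solved points for correlation")
    mus = np.array([s.mu_star for _, s in points])
    uptake = np.array([abs(s.fluxes.get(sweep.swept_id, 0.0)) for _, s in points])
    profile = np.zeros(len(points))
    for gene in gene_set:
        vals = np.array([s.expression_fluxes.get(gene, 0.0) for _, s in points])
        scale = vals.max() if normalization == "max" else vals.sum()
        if scale > 0:
            profile = profile + vals / scale
    r_sub = float(np.corrcoef(profile, uptake)[0, 1])
    r_mu = float(np.corrcoef(profile, mus)[0, 1])
    return r_sub, r_mu


def aggregate_by_category(
    expression_fluxes: Mapping[str, float],
    categories: Mapping[str, str],
    weights: Mapping[str, float],
) -> Dict[str, float]:
    """Mass-weighted category totals: sum of flux * weight over member genes."""
    out: Dict[str, float] = {}
    for gene, flux in expression_fluxes.items():
        if flux < 0:
            raise ValueError(f"negative expression flux for gene {gene!r}")
        cat = categories.get(gene, "uncategorized")
        out[cat] = out.get(cat, 0.0) + flux * weights.get(gene, 0.0)
    return out
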
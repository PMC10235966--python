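"""Per-cell actin gene-set expression scores across labeled cell populations.

The score follows the standard single-cell signature recipe: normalize counts
per cell, log-transform, then score each cell as the mean expression of the
gene set minus the mean of control genes drawn from the same
average-expression bins (n_ctrl controls per set gene, bins over all genes'
mean log expression).  The bin matching removes the depth/abundance component
so a null gene set scores ~0 in every population.

Population comparisons reuse the Mann-Whitney machinery from the AFM module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .afm import RegionComparison, compare_regions
from .errors import ValidationError


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError("gene set must be non-empty")


@dataclass
class ModuleScoreResult:
    scores: pd.Series  # per-cell score, indexed by cell id
    populations: pd.Series  # per-cell labels, same index
    set_genes_used: tuple[str, ...]
    control_genes: tuple[str, ...]
    seed: int

    def population_summary(self) -> pd.DataFrame:
        """Per-population mean, SD and n of the score."""
        df = pd.DataFrame({"score": self.scores, "population": self.populations})
        g = df.groupby("population", observed=True)["score"]
        return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})

    def pairwise_p_values(self) -> dict[tuple[str, str], float]:
        """Two-sided Mann-Whitney p for every population pair (>= 3 cells each)."""
        pops = sorted(self.populations.unique())
        out = {}
        for i, a in enumerate(pops):
            for b in pops[i + 1 :]:
                va = self.scores[self.populations == a].to_numpy()
                vb = self.scores[self.populations == b].to_numpy()
                if min(va.size, vb.size) >= 3:
                    out[(a, b)] = compare_regions(va, vb).p_value
        return out


def normalize_counts(adata, target_sum: float = 1e4):
    """Library-size normalize to ``target_sum`` per cell, then log1p.

    Cells with zero total counts are excluded with a warning.  Returns a new
    AnnData; raw counts are kept in ``.layers['counts']``.
    """
    import scanpy as sc

    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        warnings.warn(
            f"excluding {int(np.sum(totals == 0))} zero-count cell(s)", stacklevel=2
        )
        adata = adata[totals > 0].copy()
    else:
        adata = adata.copy()
    adata.layers["counts"] = adata.X.copy()
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    return adata


def _dense(x) -> np.ndarray:
    return x.toarray() if hasattr(x, "toarray") else np.asarray(x)


def module_score(
    adata,
    gene_set: GeneSet,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    population_key: str = "population",
) -> ModuleScoreResult:
    """Bin-matched control score per cell for one gene set.

    Genes absent from the matrix are dropped with a warning if at least half
    the set remains; otherwise a validation error is raised.
    """
    var_names = list(adata.var_names)
    present = [g for g in gene_set.genes if g in set(var_names)]
    missing = len(gene_set.genes) - len(present)
    if not present:
        raise ValidationError(f"no gene of set {gene_set.name!r} present in matrix")
    if missing:
        if len(present) < len(gene_set.genes) / 2:
            raise ValidationError(
                f"{missing}/{len(gene_set.genes)} set genes missing from matrix"
            )
        warnings.warn(f"dropping {missing} set gene(s) absent from matrix", stacklevel=2)

    x = _dense(adata.X)
    gene_means = x.mean(axis=0)
    order = np.argsort(gene_means, kind="stable")
    bin_of = np.empty(len(var_names), dtype=int)
    bin_of[order] = np.arange(len(var_names)) * n_bins // len(var_names)

    name_to_idx = {g: i for i, g in enumerate(var_names)}
    set_idx = np.array([name_to_idx[g] for g in present])
    in_set = np.zeros(len(var_names), dtype=bool)
    in_set[set_idx] = True

    rng = np.random.default_rng(seed)
    ctrl: set[int] = set()
    for gi in set_idx:
        pool = np.flatnonzero((bin_of == bin_of[gi]) & ~in_set)
        if pool.size == 0:
            continue
        take = min(n_ctrl, pool.size)  # without replacement where possible
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    if not ctrl:
        raise ValidationError("no control genes available in matched bins")
    ctrl_idx = np.array(sorted(ctrl))

    scores = x[:, set_idx].mean(axis=1) - x[:, ctrl_idx].mean(axis=1)
    if population_key in adata.obs:
        pops = adata.obs[population_key].astype(str)
    else:
        pops = pd.Series("all", index=adata.obs_names)
    return ModuleScoreResult(
        pd.Series(scores, index=adata.obs_names, name="actin_score"),
        pd.Series(pops, index=adata.obs_names),
        tuple(present),
        tuple(var_names[i] for i in ctrl_idx),
        seed,
    )


def compare_population_scores(
    result: ModuleScoreResult, pop_a: str, pop_b: str
) -> tuple[float, RegionComparison]:
    """Mean-score difference (A - B) and Mann-Whitney comparison."""
    for pop in (pop_a, pop_b):
        if pop not in set(result.populations):
            raise ValidationError(f"population {pop!r} not present")
    va = result.scores[result.populations == pop_a].to_numpy()
    vb = result.scores[result.populations == pop_b].to_numpy()
    comparison = compare_regions(va, vb)
    return float(va.mean() - vb.mean()), comparison
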
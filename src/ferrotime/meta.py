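"""Cross-study harmonization of differential-expression calls.

Independent expression studies of the same perturbation rarely share
platforms or statistics, so their DE lists are first re-called under one
common criterion — |log2FC| >= 0.5 and p < 0.01, deliberately looser than
a single-study threshold because some published studies only report genes
passing exactly this cut — and then intersected: genes DE in >= k studies,
and the "core set" DE in all of them, with a concordance label (all-up /
all-down / mixed) from the per-study directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cluster as _cluster


@dataclass
class MetaCriteria:
    min_abs_log2fc: float = 0.5
    max_p: float = 0.01

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0 or not 0 < self.max_p <= 1:
            raise ValueError("criteria thresholds must be positive (max_p in (0,1])")


def harmonize(study: pd.DataFrame, criteria: MetaCriteria | None = None) -> pd.DataFrame:
    """Re-call DE under the common criteria for one study table.

    ``study`` columns: gene_id, log2fc, p.  Genes with missing values are
    dropped (count reported via a warning).  Returns gene_id-indexed frame
    with ``de`` and ``direction`` (+1/-1/0).
    """
    crit = criteria or MetaCriteria()
    work = study[["gene_id", "log2fc", "p"]].copy()
    n_missing = int(work[["log2fc", "p"]].isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(f"dropping {n_missing} genes with missing log2FC or p")
        work = work.dropna(subset=["log2fc", "p"])
    de = (work["log2fc"].abs() >= crit.min_abs_log2fc) & (work["p"] < crit.max_p)
    out = pd.DataFrame(
        {
            "de": de.to_numpy(),
            "direction": np.sign(work["log2fc"]).astype(int).to_numpy(),
        },
        index=pd.Index(work["gene_id"], name="gene_id"),
    )
    return out


def intersect(studies: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine harmonized studies into per-gene intersection sets.

    The gene universe is the genes measured in *all* studies (percentages
    relative to other bases can be recomputed by the caller).  Returns a
    frame indexed by gene_id with per-study DE flags/directions,
    ``n_studies_de``, ``in_ge2``, ``in_core`` and, for core genes, a
    ``concordance`` label (all-up / all-down / mixed).
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    universe = None
    for frame in studies.values():
        ids = set(frame.index)
        universe = ids if universe is None else universe & ids
    if not universe:
        raise ValueError("empty common gene universe")
    genes = sorted(universe)
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for name, frame in studies.items():
        out[f"de_{name}"] = frame["de"].reindex(genes).astype(bool)
        out[f"dir_{name}"] = frame["direction"].reindex(genes).astype(int)
    de_cols = [c for c in out.columns if c.startswith("de_")]
    out["n_studies_de"] = out[de_cols].sum(axis=1).astype(int)
    out["in_ge2"] = out["n_studies_de"] >= 2
    out["in_core"] = out["n_studies_de"] == len(studies)

    dir_cols = [c for c in out.columns if c.startswith("dir_")]
    conc = []
    for _, row in out.iterrows():
        if not row["in_core"]:
            conc.append("")
            continue
        dirs = {row[c] for c in dir_cols}
        if dirs == {1}:
            conc.append("all-up")
        elif dirs == {-1}:
            conc.append("all-down")
        else:
            conc.append("mixed")
    out["concordance"] = conc
    return out


def genes_in_at_least(result: pd.DataFrame, k: int) -> pd.Index:
    """Genes called DE in at least ``k`` studies (nested in k)."""
    return result.index[result["n_studies_de"] >= k]


def core_heatmap_matrix(
    result: pd.DataFrame, expression: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene x study expression matrix for the core set, with a hierarchical
    row order (complete linkage, centered correlation)."""
    core = result.index[result["in_core"]]
    missing = [g for g in core if g not in expression.index]
    if missing:
        raise ValueError(f"core genes without expression values: {missing[:5]}")
    matrix = expression.loc[core]
    order, _ = _cluster.hierarchical_order(matrix)
    return matrix, order
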
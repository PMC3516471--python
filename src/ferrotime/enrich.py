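"""Gene-set enrichment: hypergeometric over-representation and a parametric
mean-fold-change z-score.

Two complementary engines, applied per time point:

* over-representation (EADEG): is a functional category over-represented
  among the differentially expressed genes, tested separately for up- and
  downregulated selections against the expressed-gene universe with the
  upper hypergeometric tail P(X >= k);
* parametric gene-set score (PGSEA-style): is the mean log2 fold change of
  a set displaced from the global mean, z = (mean_set - mean_all) *
  sqrt(n_set) / sd_all, compared against the standard normal.  Driven by
  the central limit theorem, hence the minimum set size of 10.

Both correct p-values by Benjamini-Hochberg within their stratum (time
point, and direction for over-representation).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr

MIN_SET_SIZE_ORA = 5
MIN_SET_SIZE_PGSEA = 10


def _set_members(payload) -> list[str]:
    return list(payload["genes"]) if isinstance(payload, Mapping) else list(payload)


def hypergeom_enrich(
    selected: Iterable[str],
    gene_sets: Mapping[str, Mapping | Sequence[str]],
    universe: Iterable[str],
    min_size: int = MIN_SET_SIZE_ORA,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``selected`` genes.

    ``universe`` is the expressed-gene reference; gene sets are intersected
    with it and sets smaller than ``min_size`` are skipped.  Returns one row
    per tested set with counts (N, K, n, k), p and BH FDR.
    """
    universe = set(universe)
    selected = set(selected)
    stray = selected - universe
    if stray:
        raise ValueError(f"selected genes not in universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(selected)
    rows = []
    for set_id, payload in gene_sets.items():
        members = set(_set_members(payload)) & universe
        K = len(members)
        if K < min_size:
            continue
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((set_id, N, K, n, k, p))
    result = pd.DataFrame(rows, columns=["set_id", "N", "K", "n", "k", "p"])
    result["fdr"] = bh_fdr(result["p"].to_numpy()) if len(result) else []
    return result.sort_values("p", kind="mergesort").reset_index(drop=True)


def pgsea_zscore(
    log2fc: pd.Series,
    members: Iterable[str],
    min_size: int = MIN_SET_SIZE_PGSEA,
    ddof: int = 0,
) -> tuple[float, float]:
    """z-score and two-sided normal p for one gene set at one time point.

    ``log2fc`` is indexed by expressed gene ids; the set is intersected with
    it.  ``sd_all`` is the population (divide-by-n) standard deviation by
    default.
    """
    members = [g for g in members if g in log2fc.index]
    n_set = len(members)
    if n_set < min_size:
        raise ValueError(f"gene set too small after intersection ({n_set} < {min_size})")
    all_vals = log2fc.to_numpy(dtype=float)
    sd_all = all_vals.std(ddof=ddof)
    if sd_all == 0:
        raise ValueError("zero standard deviation across all genes")
    z = (log2fc.loc[members].mean() - all_vals.mean()) * np.sqrt(n_set) / sd_all
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def pgsea_enrich(
    fc_table: pd.DataFrame,
    gene_sets: Mapping[str, Mapping | Sequence[str]],
    min_size: int = MIN_SET_SIZE_PGSEA,
) -> pd.DataFrame:
    """Parametric set scores for every set at every time point, BH-corrected
    within each time point.  ``fc_table`` needs ``log2fc_<t>`` columns."""
    tps = [c.removeprefix("log2fc_") for c in fc_table.columns if c.startswith("log2fc_")]
    frames = []
    for t in tps:
        fc = fc_table[f"log2fc_{t}"].dropna()
        rows = []
        for set_id, payload in gene_sets.items():
            members = [g for g in _set_members(payload) if g in fc.index]
            if len(members) < min_size:
                continue
            z, p = pgsea_zscore(fc, members, min_size=min_size)
            rows.append((set_id, t, len(members), z, p))
        frame = pd.DataFrame(rows, columns=["set_id", "timepoint", "n_set", "z", "p"])
        frame["fdr"] = bh_fdr(frame["p"].to_numpy()) if len(frame) else []
        frames.append(frame)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["set_id", "timepoint", "n_set", "z", "p", "fdr"]
    )


def eadeg_enrich(
    fc_table: pd.DataFrame,
    gene_sets: Mapping[str, Mapping | Sequence[str]],
    universe: Iterable[str],
    min_size: int = MIN_SET_SIZE_ORA,
) -> pd.DataFrame:
    """Over-representation per (time point, direction) from a DE table.

    Up/down selections at time t are the DE transcripts (``de_<t>``) with
    positive/negative log2FC; each stratum is BH-corrected separately.
    """
    universe = set(universe)
    tps = [c.removeprefix("de_") for c in fc_table.columns if c.startswith("de_") and c != "de_any"]
    frames = []
    for t in tps:
        de = fc_table[f"de_{t}"]
        fc = fc_table[f"log2fc_{t}"]
        for direction, mask in (("up", de & (fc > 0)), ("down", de & (fc < 0))):
            selected = set(fc_table.index[mask]) & universe
            res = hypergeom_enrich(selected, gene_sets, universe, min_size=min_size)
            res.insert(1, "timepoint", t)
            res.insert(2, "direction", direction)
            frames.append(res)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
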
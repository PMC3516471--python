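"""Marker-correlated sRNA screening and interaction-energy target filtering.

Trans-acting sRNAs co-regulated with the iron-stress regulon are found by
correlating each differentially expressed sRNA's log2FC profile with a
marker gene (*isiA* in the motivating experiment) over the post-treatment
time points; |r| >= 0.7 defines the candidate lists.

Candidate sRNA targets come from an external RNA-RNA interaction predictor
run on a window of 250 nt around each start codon (150 upstream, 100
downstream) — the energy computation itself is consumed as an input table.
Predicted targets are filtered in two stages: interaction free energy
<= -10 kcal/mol, then expression anticorrelation (Spearman r < -0.5 with
the sRNA), reflecting that most characterized bacterial sRNAs repress
their targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .pairs import CorrelationMethod, profile_correlation
from . import enrich


@dataclass
class ScreenConfig:
    """Thresholds of the marker screen and target filter."""

    marker_id: str = "sll0247"
    method: CorrelationMethod = "pearson"
    abs_r_min: float = 0.7
    energy_max: float = -10.0  # kcal/mol; more negative = stronger
    target_r_max: float = -0.5
    window_upstream: int = 150
    window_downstream: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.abs_r_min <= 1:
            raise ValueError("abs_r_min must be in (0, 1]")
        if self.window_upstream < 0 or self.window_downstream < 0:
            raise ValueError("window extents must be non-negative")


def _profiles(fc_table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in fc_table.columns if c.startswith("log2fc_") and c != "log2fc_0h"]
    return fc_table[cols]


def marker_screen(
    fc_table: pd.DataFrame,
    srna_ids: list[str],
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate DE sRNAs with the marker gene's profile.

    ``fc_table`` is a fold-change table containing both the marker and the
    sRNAs (``log2fc_<t>`` columns, ``de_any`` flag).  Returns
    (positive list, negative list), each sorted by |r| descending, with
    candidates r >= abs_r_min resp. r <= -abs_r_min.
    """
    cfg = config or ScreenConfig()
    if cfg.marker_id not in fc_table.index:
        raise ValueError(f"marker {cfg.marker_id!r} absent from fold-change table")
    if "de_any" in fc_table.columns and not bool(fc_table.loc[cfg.marker_id, "de_any"]):
        warnings.warn(f"marker {cfg.marker_id} is not differentially expressed")
    profiles = _profiles(fc_table)
    marker = profiles.loc[cfg.marker_id].to_numpy(dtype=float)
    rows = []
    for sid in srna_ids:
        if sid not in profiles.index or sid == cfg.marker_id:
            continue
        if "de_any" in fc_table.columns and not bool(fc_table.loc[sid, "de_any"]):
            continue
        r = profile_correlation(marker, profiles.loc[sid].to_numpy(dtype=float), cfg.method)
        rows.append((sid, r))
    result = pd.DataFrame(rows, columns=["srna_id", "r"])
    positive = result.loc[result["r"] >= cfg.abs_r_min]
    negative = result.loc[result["r"] <= -cfg.abs_r_min]
    key = lambda df: df.reindex(df["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)
    return key(positive), key(negative)


def extract_windows(
    coords: pd.DataFrame,
    genome: dict[str, str],
    upstream: int = 150,
    downstream: int = 100,
) -> pd.DataFrame:
    """Strand-aware sequence windows around annotated start codons.

    Convention: position +1 is the first base of the start codon; the
    window spans [-upstream, +downstream] relative to it (length
    upstream + downstream).  For minus-strand genes the mirrored genomic
    span is taken and reverse-complemented.  Windows truncated at contig
    ends are flagged ``clipped``.

    ``coords`` columns: gene_id, contig, start, end (1-based inclusive),
    strand (+/-); for minus-strand genes the start codon begins at ``end``.
    """
    rows = []
    for _, g in coords.iterrows():
        contig = g["contig"]
        if contig not in genome:
            raise ValueError(f"contig {contig!r} of gene {g['gene_id']!r} not in genome")
        seq = genome[contig]
        length = len(seq)
        if g["strand"] == "+":
            first = int(g["start"])  # first base of start codon, 1-based
            lo, hi = first - upstream, first + downstream - 1
        else:
            first = int(g["end"])
            lo, hi = first - downstream + 1, first + upstream
        clipped = lo < 1 or hi > length
        lo_c, hi_c = max(lo, 1), min(hi, length)
        window = seq[lo_c - 1 : hi_c]
        if g["strand"] == "-":
            window = str(Seq(window).reverse_complement())
        rows.append((g["gene_id"], contig, lo_c, hi_c, g["strand"], clipped, window))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "contig", "window_start", "window_end", "strand", "clipped", "sequence"],
    )


def filter_targets(
    interactions: pd.DataFrame,
    fc_table: pd.DataFrame,
    srna_id: str,
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Two-stage filter of predicted sRNA targets.

    ``interactions`` columns: srna_id, target_id, energy (kcal/mol).
    Stage 1 keeps energy <= energy_max; stage 2 keeps targets whose
    expression profile is anticorrelated with the sRNA (Spearman
    r < target_r_max).  Returns the surviving table plus per-stage counts.
    """
    cfg = config or ScreenConfig()
    mine = interactions.loc[interactions["srna_id"] == srna_id]
    if srna_id not in fc_table.index:
        raise ValueError(f"sRNA {srna_id!r} absent from fold-change table")
    profiles = _profiles(fc_table)
    srna_profile = profiles.loc[srna_id].to_numpy(dtype=float)

    stage1 = mine.loc[mine["energy"] <= cfg.energy_max].copy()
    kept_rows = []
    n_missing = 0
    for _, row in stage1.iterrows():
        target = row["target_id"]
        if target not in profiles.index:
            n_missing += 1
            continue
        r = profile_correlation(
            srna_profile, profiles.loc[target].to_numpy(dtype=float), "spearman"
        )
        if r < cfg.target_r_max:
            kept_rows.append((row["srna_id"], target, row["energy"], r))
    result = pd.DataFrame(kept_rows, columns=["srna_id", "target_id", "energy", "r"])
    counts = {
        "n_input": int(len(mine)),
        "n_energy_pass": int(len(stage1)),
        "n_missing_profile": n_missing,
        "n_final": int(len(result)),
    }
    return result.sort_values("energy", kind="mergesort").reset_index(drop=True), counts


def target_enrichment(
    targets: pd.DataFrame | list[str],
    gene_sets: dict,
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of filtered targets against the
    expressed universe (delegates to :mod:`ferrotime.enrich`)."""
    ids = targets["target_id"].tolist() if isinstance(targets, pd.DataFrame) else list(targets)
    if not ids:
        return pd.DataFrame(columns=["set_id", "N", "K", "n", "k", "p", "fdr"])
    return enrich.hypergeom_enrich(ids, gene_sets, universe)
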
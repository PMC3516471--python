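"""From raw probe intensities to a normalized transcript-level expression set.

The processing order follows single-channel array convention for this kind
of experiment:

1. background clipping to a positive floor (stand-in for a full
   background-correction model; keeps the log transform defined);
2. detection filter against the control-spot null: a probe counts as
   expressed only if, at some time point, its raw signal exceeds the
   maximum control-spot signal on *every* replicate array of that time
   point.  The filter runs on background-corrected, pre-normalization
   signals (probe and control signals share each array's scale, so the
   decision is invariant to per-array rescaling);
3. log2 transform and quantile normalization across arrays;
4. transcript summarization by averaging replicated probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AGGREGATES = ("any", "all", "majority")


@dataclass
class ExpressionSet:
    """Transcript-level normalized log2 expression with design metadata.

    Attributes
    ----------
    values:
        transcript x array DataFrame of normalized log2 intensities.
    design:
        One row per array: ``array_id``, ``timepoint``, ``replicate``.
    expressed:
        Boolean Series per transcript (detection filter outcome).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    expressed: pd.Series

    @property
    def mean_intensity(self) -> pd.Series:
        """Average normalized log2 intensity per transcript."""
        return self.values.mean(axis=1)

    def expressed_values(self) -> pd.DataFrame:
        return self.values.loc[self.expressed.reindex(self.values.index, fill_value=False)]

    def timepoints(self) -> np.ndarray:
        return np.sort(self.design["timepoint"].unique())


def background_correct(matrix: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Clip intensities from below so every value is >= ``floor``."""
    if floor < 0:
        raise ValueError("floor must be non-negative")
    return matrix.clip(lower=floor)


def expression_filter(
    matrix: pd.DataFrame,
    probe_map: pd.DataFrame,
    design: pd.DataFrame,
    aggregate: str = "any",
) -> tuple[pd.Series, pd.Series]:
    """Detection flags per probe and per transcript.

    A probe is expressed iff there is a time point at which its signal
    exceeds the per-array maximum over control probes on every replicate
    array of that time point.  A transcript is expressed according to
    ``aggregate`` over its probes: ``any`` (default), ``all`` or
    ``majority``.
    """
    if aggregate not in AGGREGATES:
        raise ValueError(f"aggregate must be one of {AGGREGATES}")
    pm = probe_map.set_index("probe_id")
    is_control = pm["is_control"].reindex(matrix.index)
    if is_control.isna().any():
        missing = matrix.index[is_control.isna()][:3].tolist()
        raise ValueError(f"probes missing from probe map, e.g. {missing}")
    if not is_control.any():
        raise ValueError("no control probes present")
    missing_arrays = set(design["array_id"]) - set(matrix.columns)
    if missing_arrays:
        raise ValueError(f"arrays missing from intensity matrix: {sorted(missing_arrays)}")

    ctrl_max = matrix.loc[is_control].max(axis=0)  # per array
    above = matrix.gt(ctrl_max, axis=1)
    probe_expr = pd.Series(False, index=matrix.index)
    for _, group in design.groupby("timepoint"):
        cols = group["array_id"].tolist()
        probe_expr |= above[cols].all(axis=1)
    probe_expr = probe_expr & ~is_control

    signal = pm.loc[~pm["is_control"]]
    per_tx = probe_expr.loc[signal.index].groupby(signal["transcript_id"])
    if aggregate == "any":
        tx_expr = per_tx.any()
    elif aggregate == "all":
        tx_expr = per_tx.all()
    else:
        tx_expr = per_tx.mean() > 0.5
    return probe_expr, tx_expr


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force identical value distributions on all columns.

    Each column's values are replaced by the across-column mean of order
    statistics at the value's rank; ties within a column receive the mean of
    the reference values their positions span.  Idempotent, and afterwards
    ``sorted(col_i) == sorted(col_j)`` for all column pairs.
    """
    if matrix.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # ties: average the reference values spanned by each tie group
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def summarize_transcripts(
    log2_matrix: pd.DataFrame, probe_map: pd.DataFrame
) -> pd.DataFrame:
    """Average replicated probes into one row per transcript."""
    pm = probe_map.loc[~probe_map["is_control"]].set_index("probe_id")
    present = pm.index.intersection(log2_matrix.index)
    mapped = log2_matrix.loc[present]
    return mapped.groupby(pm.loc[present, "transcript_id"]).mean()


def relative_abundance(expr: ExpressionSet, expressed_only: bool = True) -> pd.Series:
    """Per-transcript intensity relative to the grand mean.

    Computed on the linear intensity scale: each transcript's mean
    (2**log2) intensity divided by the grand mean over the expressed
    transcripts, mirroring how relative transcript abundance is ranked.
    """
    linear = (2.0 ** expr.values).mean(axis=1)
    base = linear[expr.expressed.reindex(linear.index, fill_value=False)] if expressed_only else linear
    if len(base) == 0 or base.mean() == 0:
        raise ValueError("no expressed transcripts / zero grand mean")
    return linear / base.mean()


def preprocess(
    probes: pd.DataFrame,
    probe_map: pd.DataFrame,
    design: pd.DataFrame,
    floor: float = 1.0,
    aggregate: str = "any",
) -> ExpressionSet:
    """Run the full probe -> transcript preprocessing chain.

    ``probes`` is the long table (probe_id, array_id, intensity); the
    returned :class:`ExpressionSet` contains all transcripts with their
    detection flags — downstream statistics subset to the expressed ones.
    """
    matrix = probes.pivot(index="probe_id", columns="array_id", values="intensity")
    matrix = matrix[design["array_id"].tolist()]
    matrix = background_correct(matrix, floor)
    probe_expr, tx_expr = expression_filter(matrix, probe_map, design, aggregate)
    signal_ids = probe_map.loc[~probe_map["is_control"], "probe_id"]
    log2_signal = np.log2(matrix.loc[matrix.index.intersection(signal_ids)])
    normalized = quantile_normalize(log2_signal)
    values = summarize_transcripts(normalized, probe_map)
    return ExpressionSet(
        values=values,
        design=design.reset_index(drop=True),
        expressed=tx_expr.reindex(values.index, fill_value=False),
    )
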
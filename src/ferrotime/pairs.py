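"""Sense-antisense pair analysis: correlation, coupling classes, direction
calls and relative-abundance contrast.

Cis-antisense RNAs can stabilize their sense mRNA (duplex formation masking
ribonuclease cleavage sites) or destabilize it (promoting degradation), so
the sign of the sense-antisense expression correlation is biologically
informative.  Pairs in which both members are differentially expressed are
classified by the correlation r of their log2FC profiles over the five
post-treatment time points:

* class I:   r > 0.5   (coupled, same direction — candidate stabilizers)
* class II:  -0.5 <= r <= 0.5  (no strong coupling; boundary values
  inclusive to class II)
* class III: r < -0.5  (anticorrelated — candidate destabilizers; the
  IsrR/isiA pair is the canonical member)

Pearson is the default correlation (it reproduces published pair tables
computed from these profiles); Spearman is available.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

CLASS_I_MIN_R = 0.5
CLASS_III_MAX_R = -0.5

CorrelationMethod = Literal["pearson", "spearman"]


def profile_correlation(
    x: np.ndarray, y: np.ndarray, method: CorrelationMethod = "pearson"
) -> float:
    """Correlation between two log2FC profiles.

    Profiles must have >= 3 points; a zero-variance profile has no defined
    Pearson correlation and returns NaN (callers flag such pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("profiles must have equal length >= 3")
    if method == "pearson":
        if x.std() == 0 or y.std() == 0:
            return float("nan")
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def classify_pair(r: float) -> str:
    """Coupling class from the correlation: I (r > 0.5), II (|r| <= 0.5,
    boundaries inclusive), III (r < -0.5)."""
    if np.isnan(r):
        raise ValueError("cannot classify an undefined correlation")
    if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
        raise ValueError("correlation must lie in [-1, 1]")
    if r > CLASS_I_MIN_R:
        return "I"
    if r < CLASS_III_MAX_R:
        return "III"
    return "II"


def median_direction(profile: np.ndarray) -> str:
    """'up' / 'down' / 'flat' by the sign of the median log2FC."""
    med = float(np.median(np.asarray(profile, dtype=float)))
    if med > 0:
        return "up"
    if med < 0:
        return "down"
    return "flat"


def build_pairs(
    annotation: pd.DataFrame, de_flags: pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Sense-antisense pairs in which BOTH members are DE.

    ``annotation`` needs columns transcript_id/class/partner_id;
    ``de_flags`` is a boolean Series indexed by transcript id (overall DE).
    Returns the pair frame (antisense_id, sense_id) and the list of DE
    asRNAs whose sense partner is not DE (reported separately).
    """
    as_rows = annotation.loc[annotation["class"] == "asRNA"]
    rows, solo = [], []
    seen = set()
    for _, row in as_rows.iterrows():
        asrna, sense = row["transcript_id"], row["partner_id"]
        if not sense:
            import warnings

            warnings.warn(f"asRNA {asrna} has no annotated sense partner; skipped")
            continue
        if not bool(de_flags.get(asrna, False)):
            continue
        if bool(de_flags.get(sense, False)):
            key = (asrna, sense)
            if key not in seen:
                seen.add(key)
                rows.append(key)
        else:
            solo.append(asrna)
    return pd.DataFrame(rows, columns=["antisense_id", "sense_id"]), solo


def classify_pairs(
    pair_profiles: pd.DataFrame,
    method: CorrelationMethod = "pearson",
    sense_prefix: str = "sense_fc",
    antisense_prefix: str = "antisense_fc",
) -> pd.DataFrame:
    """Correlation, class and median-direction calls for a pair table.

    ``pair_profiles`` holds one row per pair with the five post-treatment
    log2FC values of each member in ``<prefix>_3h .. <prefix>_72h`` columns
    (any consistent suffix set works).  Adds columns r, pair_class,
    sense_direction, antisense_direction.
    """
    sense_cols = [c for c in pair_profiles.columns if c.startswith(sense_prefix + "_")]
    as_cols = [c for c in pair_profiles.columns if c.startswith(antisense_prefix + "_")]
    out = pair_profiles.copy()
    r_vals, classes, s_dir, a_dir = [], [], [], []
    for _, row in pair_profiles.iterrows():
        s = row[sense_cols].to_numpy(dtype=float)
        a = row[as_cols].to_numpy(dtype=float)
        r = profile_correlation(s, a, method)
        r_vals.append(r)
        classes.append(classify_pair(r) if not np.isnan(r) else "undefined")
        s_dir.append(median_direction(s))
        a_dir.append(median_direction(a))
    out["r"] = r_vals
    out["pair_class"] = classes
    out["sense_direction"] = s_dir
    out["antisense_direction"] = a_dir
    return out


def compare_class_abundance(
    class_i: pd.DataFrame,
    class_iii: pd.DataFrame,
    mean_intensity: pd.Series,
) -> dict:
    """Do class I asRNAs sit higher above their mRNAs than class III ones?

    For each pair, Delta = mean normalized intensity(asRNA) - mean
    normalized intensity(mRNA); the Delta distributions of class I and
    class III are compared with a two-sided Wilcoxon rank-sum
    (Mann-Whitney U) test.
    """
    if len(class_i) == 0 or len(class_iii) == 0:
        raise ValueError("both classes must be nonempty")

    def deltas(frame: pd.DataFrame) -> np.ndarray:
        return (
            mean_intensity.reindex(frame["antisense_id"]).to_numpy()
            - mean_intensity.reindex(frame["sense_id"]).to_numpy()
        )

    d1, d3 = deltas(class_i), deltas(class_iii)
    res = stats.mannwhitneyu(d1, d3, alternative="two-sided")
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "median_delta_class_I": float(np.median(d1)),
        "median_delta_class_III": float(np.median(d3)),
        "n_class_I": len(d1),
        "n_class_III": len(d3),
    }


def analyze_pairs(
    fc_table: pd.DataFrame,
    annotation: pd.DataFrame,
    method: CorrelationMethod = "pearson",
) -> pd.DataFrame:
    """End-to-end pair analysis from a DE fold-change table and annotation.

    Builds the both-DE pairs, pulls both members' post-treatment profiles
    from ``fc_table`` (``log2fc_<t>`` columns) and classifies them.
    """
    fc_cols = [c for c in fc_table.columns if c.startswith("log2fc_") and c != "log2fc_0h"]
    pairs, _ = build_pairs(annotation, fc_table["de_any"])
    if len(pairs) == 0:
        return pd.DataFrame(
            columns=["antisense_id", "sense_id", "r", "pair_class",
                     "sense_direction", "antisense_direction"]
        )
    wide = pairs.copy()
    for col in fc_cols:
        suffix = col.removeprefix("log2fc_")
        wide[f"sense_fc_{suffix}"] = fc_table.loc[pairs["sense_id"], col].to_numpy()
        wide[f"antisense_fc_{suffix}"] = fc_table.loc[pairs["antisense_id"], col].to_numpy()
    return classify_pairs(wide, method=method)
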
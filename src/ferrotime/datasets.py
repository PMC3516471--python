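"""Published printed values bundled with the package.

Two small tables transcribed from the published iron-depletion time course
in *Synechocystis* sp. PCC 6803 (GEO accession GSE39804) ship with the
package so that the pair-classification and sRNA-screening machinery can be
exercised and checked against published numbers without any external data:

* the 62 differentially expressed sense-antisense pairs (log2 fold change
  at 3/12/24/48/72 h for both members, the reported q-values and the
  reported sense-antisense correlation coefficient);
* the 10 intergenic sRNAs whose expression tracked the iron-stress marker
  gene *isiA* (|r| >= 0.7), with the reported correlations for the four
  upregulated ones.

Values are printed to two decimals, so correlations recomputed from them
agree with the reported coefficients only up to rounding noise (about
+/-0.02).
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

TIMEPOINT_LABELS = ("3h", "12h", "24h", "48h", "72h")
POST_TIMEPOINTS = (3.0, 12.0, 24.0, 48.0, 72.0)

#: transcript id of the iron-stress marker gene isiA
ISIA = "sll0247"
#: transcript id of IsrR, the asRNA complementary to isiA
ISRR = "sll0247-as2"


def _load(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("ferrotime.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])


def load_sense_antisense_pairs() -> pd.DataFrame:
    """The 62 sense-antisense pairs in which both members were differentially
    expressed, one row per pair."""
    return _load("sense_antisense_pairs.tsv")


def load_isia_correlated_srnas() -> pd.DataFrame:
    """The 10 sRNAs reported as strongly (anti)correlated with *isiA*."""
    return _load("isia_correlated_srnas.tsv")


def profile_matrix(df: pd.DataFrame, prefix: str = "fc") -> np.ndarray:
    """Extract the 5-point log2FC profiles ``<prefix>_3h .. <prefix>_72h``
    from a loaded table as an (n, 5) array."""
    cols = [f"{prefix}_{lab}" for lab in TIMEPOINT_LABELS]
    return df[cols].to_numpy(dtype=float)


def isia_profile() -> np.ndarray:
    """The printed isiA log2FC profile over the five post-depletion time points."""
    pairs = load_sense_antisense_pairs()
    row = pairs.loc[pairs["sense_id"] == ISIA]
    return profile_matrix(row, "sense_fc")[0]
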
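"""Filter predicted sRNA targets by interaction energy and anticorrelation.

Interaction energies come from an external RNA-RNA predictor run on
250-nt windows around start codons (the package extracts the windows; the
energy model is consumed as a table).  The two-stage filter keeps targets
with energy <= -10 kcal/mol whose expression is anticorrelated with the
sRNA (Spearman r < -0.5) — repression being the default mode of bacterial
sRNA action.
"""

import pandas as pd

from ferrotime import srna_screen

srna_profile = [3.0, 2.0, 1.0, 0.5, 0.1]
profiles = {"NC-sim": srna_profile}
rows = []
for i in range(10):  # true targets: strong energy, anticorrelated
    profiles[f"target{i:02d}"] = [-x for x in srna_profile]
    rows.append(("NC-sim", f"target{i:02d}", -12.0))
for i in range(10, 30):  # weak-energy decoys
    profiles[f"target{i:02d}"] = [-x for x in srna_profile]
    rows.append(("NC-sim", f"target{i:02d}", -9.5))
for i in range(30, 50):  # strong-energy but co-expressed decoys
    profiles[f"target{i:02d}"] = srna_profile
    rows.append(("NC-sim", f"target{i:02d}", -12.0))

fc = pd.DataFrame.from_dict(
    profiles, orient="index",
    columns=[f"log2fc_{t}h" for t in (3, 12, 24, 48, 72)],
)
interactions = pd.DataFrame(rows, columns=["srna_id", "target_id", "energy"])

result, counts = srna_screen.filter_targets(interactions, fc, "NC-sim")
print(
    f"{counts['n_input']} predicted -> {counts['n_energy_pass']} pass energy "
    f"<= -10 kcal/mol -> {counts['n_final']} also anticorrelated"
)
print("surviving targets:", ", ".join(result["target_id"]))

# window extraction for an external predictor:
genome = {"chr1": "ACGT" * 500}
coords = pd.DataFrame(
    {"gene_id": ["gA"], "contig": ["chr1"], "start": [1000], "end": [1500],
     "strand": ["+"]}
)
windows = srna_screen.extract_windows(coords, genome)
w = windows.iloc[0]
print(f"window for gA: {w['window_start']}..{w['window_end']} ({len(w['sequence'])} nt)")
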
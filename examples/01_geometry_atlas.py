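"""Per-cell 3D geometry statistics across BR-signalling conditions.

Generates a synthetic single-cell geometry atlas (three conditions:
adequate, low and high BR signalling), classifies each cell into meristem
or elongation zone from the per-stratum cell-length mixture, then fits
the random-intercept mixed models, adjusts the pairwise contrasts, and
reports the share of variance attributable to BR signalling.
"""

import pandas as pd

from meriquant.stats3d import analyze_geometry, anisotropy_index
from meriquant.synth import SynthGeometryConfig, generate_geometry_table
from meriquant.zones import classify_meristem, zone_counts

pd.set_option("display.width", 110)

table = generate_geometry_table(
    SynthGeometryConfig(cells_per_root_per_tissue=80, seed=1)
)
print(f"generated {len(table)} cells "
      f"({table['root_id'].nunique()} roots, "
      f"{table['tissue'].nunique()} tissues, "
      f"{table['treatment'].nunique()} conditions)")

labeled, fits = classify_meristem(table)
counts = zone_counts(labeled)
n_mer = counts.query("zone == 'meristem'")["n_cells"].sum()
print(f"zone classification: {n_mer} meristem cells of {len(labeled)} "
      f"(posterior of the short length component > 0.8)")

labeled["anisotropy"] = anisotropy_index(
    labeled["length"], labeled["depth"], labeled["width"]
)
ani = labeled[labeled.zone == "meristem"].groupby("treatment")["anisotropy"].median()
print("\nmedian anisotropy index (length²/(depth·width)) of meristem cells:")
print(ani.round(2).to_string())
print("low BR (bri1) is the most isotropic, high BR (BL) the most elongated.")

comparisons, model_fits, fdr = analyze_geometry(labeled)
print(f"\nmixed models fitted: {len(model_fits)}  "
      f"(stage-1 significant: {fdr.n_stage1_significant}/{fdr.n_models}, "
      f"stage-2 level {fdr.stage2_alpha:.4f})")
print("\nlength comparisons in the cortex "
      "(estimates on the log scale; % variance explained by BR):")
print(
    comparisons.query("parameter == 'length' and tissue == 'cortex'")
    .drop(columns=["parameter", "tissue"])
    .round(4)
    .to_string(index=False)
)
print("\nPositive 'WT vs bri1' and negative 'WT vs BL' length estimates mean "
      "BR signalling lengthens meristematic cells dose-dependently.")
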
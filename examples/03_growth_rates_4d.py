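"""Directional growth rates of single cells from two-time-point data.

Generates lineage-tracked pairs (≈12 h apart), merges daughters of
divided cells (lengths/volumes sum, depths/widths average), restricts the
analysis to cells that stay inside the meristem window, and tests
condition effects on each directional rate by ANCOVA with the starting
distance from the QC as covariate.
"""

from meriquant.growth4d import (
    ancova_rates,
    count_divisions,
    filter_meristem_window,
    merge_and_rate,
)
from meriquant.synth import Synth4DConfig, generate_pairs_4d

raw = generate_pairs_4d(Synth4DConfig(n_cells_per_condition=120, seed=3))
pairs = merge_and_rate(raw)
print(f"{len(pairs)} lineages merged from {len(raw)} daughter rows")

pairs = filter_meristem_window(pairs, d0_max=60.0, d1_max=100.0)
print(f"meristem window (≤60 µm at t0, ≤100 µm at t1): "
      f"{len(pairs)} kept, {pairs.attrs['n_removed']} removed")

div = count_divisions(pairs)
print(f"divisions detected: {div['n_divisions'].sum()} "
      f"(binned by starting distance)\n")

for parameter in ("length", "width", "depth", "volume"):
    res = ancova_rates(pairs, parameter)
    print(f"{parameter} rate — {res.model_form} model "
          f"(interaction p = {res.interaction_pvalue:.3f})")
    print(res.contrasts.round(4).to_string(index=False), "\n")

print("Condition contrasts are per-hour rate differences at the mean "
      "position: the high-BR condition accelerates elongation (length "
      "rate) most, while radial rates (width/depth) respond far less — "
      "growth direction, not volume, is what BR signalling reorients.")
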
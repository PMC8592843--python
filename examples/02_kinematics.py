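"""Displacement kinematics along the meristem.

Generates 6 h time-lapse tracks for three conditions, fits the linear
displacement-velocity field v(x) per condition, and derives meristem
residence times (8→100 µm from the quiescent centre) plus a
production-rate cross-check for a genotype without live imaging.
"""

from meriquant.kinematics import (
    KinematicsFit,
    ProductionInputs,
    fit_displacement,
    relative_rate_from_production,
    residence_time,
)
from meriquant.synth import SynthTrackConfig, generate_tracks

tracks = generate_tracks(SynthTrackConfig(seed=7))
print(f"generated {tracks['cell_id'].nunique()} tracks, "
      f"{len(tracks)} observations (30-min sampling over 6 h)")

fits = fit_displacement(tracks)
print("\ncondition   slope (1/h)   R²      fold vs WT")
for cond, f in fits.items():
    print(f"{cond:10s}  {f.slope:10.4f}   {f.r_squared:.3f}   {f.relative_rate:.3f}")
print("(generating folds were 1.0, 0.57 and 3.0 — low BR slows displacement,"
      " high BR speeds it up)")

print("\nresidence time 8→100 µm (h), forced-zero intercept:")
for cond, f in fits.items():
    zero = KinematicsFit(cond, 0.0, f.slope, f.r_squared, f.n_cells)
    print(f"  {cond:6s} {residence_time(zero):7.1f}")
print("the slow condition spends ~75% more time in the meristem than WT;"
      " the fast one leaves it ~3× sooner.")

wt = ProductionInputs(
    root_elongation_day=4800.0,
    mature_cell_length=160.0,
    mean_meristem_cell_length=8.0,
    meristem_cell_number=30,
)
slow = ProductionInputs(2700.0, 150.0, 7.0, 32)
rel = relative_rate_from_production(slow, wt)
print(f"\nproduction-rate bookkeeping for an unimaged genotype: "
      f"{rel:.2f}-fold displacement rate vs WT")
print("(daily root elongation / mature cell length gives cells produced per "
      "day; meristem length over the length leaving it per day is the "
      "residence proxy whose WT ratio is the relative rate)")
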
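"""Simulate a delayed match-to-sample recording session.

Generates the default two-area synthetic population (85 AIT-like and 53
LIP-like cells), prints the trial-design arithmetic, and shows one cell's
ground truth.  The per-cell design mirrors the emulated recording protocol: 12
repetitions of each of 9 sample conditions in each of 2 attention tasks
(216 non-catch matching trials), plus flagged catch trials and two passive
tasks.
"""

from attnspace import SimConfig, simulate_population

cfg = SimConfig(seed=1)
table, truth = simulate_population(cfg)

att = table[table["task"].isin(["shape_attention", "location_attention"])]
per_cell = att[~att["is_catch"]].groupby("cell_id").size()
print(f"cells simulated:                {table['cell_id'].nunique()}")
print(f"total trials:                   {len(table)}")
print(f"non-catch attention trials/cell: {per_cell.unique()}")
print(f"catch-trial fraction (attention): {att['is_catch'].mean():.3f}")

cell = truth[0]
print(f"\nexample cell {cell.cell_id}:")
print(f"  preferred angle {cell.preferred_angle:.1f} deg, "
      f"kappa {cell.location_kappa}, ecc {cell.eccentricity:.2f} deg")
print(f"  active shapes {cell.active_shapes}, "
      f"active angles {tuple(round(a, 1) for a in cell.active_angles)}")
print("  gains (task, decode space):")
for key, g in sorted(cell.gains.items()):
    print(f"    {key[0]:>18} / {key[1]:<8} {g:.3f}")
print("\nEach gain is the multiplicative factor attention applies to that "
      "cell's passive responses in the corresponding decode space.")
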
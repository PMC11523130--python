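"""Compute the soil quality index for the packaged field-trial table.

Loads the per-treatment soil chemistry / earthworm table from the
long-term tillage trial, runs the PCA minimum-data-set selection,
sigmoid scoring and weighted aggregation, and prints the resulting SQI
ranking.  A higher SQI means the treatment's retained indicators sit
further above their across-treatment baselines (with salinity, EC,
scored low-is-good).
"""

from mycodiv import load_reference_soil_table, sqi_pipeline

soil = load_reference_soil_table()
result = sqi_pipeline(soil)

print("Minimum data set (indicator: weight, source component):")
for ind, w in result.selection.weights.items():
    print(f"  {ind:>16s}: W = {w:.3f}  ({result.selection.source_pc[ind]})")

print("\nSQI ranking (0-1 scale; higher = better soil quality):")
for obs, val in result.ranking().items():
    print(f"  {obs}: {val:.3f}")

print("\nSelection audit trail:")
for line in result.selection.log:
    print("  " + line)
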
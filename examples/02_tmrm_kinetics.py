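"""Membrane-potential collapse kinetics from synthetic TMRM traces.

Generates StDev traces for all condition presets, extracts (MAX, Y_spread,
t1/2_decay) per cell, and clusters the condition profiles into the three
response groups: unaffected controls, sensitized, already collapsed.
"""

from mitomorph.simulate import generate_condition_traces
from mitomorph.tmrm import cluster_conditions, condition_profiles, extract_params_table

traces = generate_condition_traces(30, seed=1)
params = extract_params_table(traces)

summary = params.groupby("condition", sort=False).agg(
    MAX=("MAX", "mean"),
    Y_spread=("Y_spread", "mean"),
    t_half=("t_half_decay", "mean"),
    censored=("censored", "mean"),
)
print(summary.round(1).to_string())
# t_half is the time (s) at which the cell's TMRM StDev falls to half its
# initial level; NaN/censored = 1.0 means depolarization never occurred
# (pore blocked) or the trace was already collapsed at onset.

clusters = cluster_conditions(condition_profiles(traces))["cut"](3)
print("\nEuclidean clustering at k=3:")
for cond, grp in clusters.items():
    print(f"  group {grp}: {cond}")
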
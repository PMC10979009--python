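"""Count ori and ter foci and quantify the ori:ter ratio.

Compares a replication-halted population (one origin and one terminus per
cell) with a replicating one (four origins), applying the 15%-of-cell-signal
filter to the dim terminus channel before counting.
"""

import chromoshape as cs
from chromoshape.foci import count_and_ratio, detect_foci
from chromoshape.segment import detect_cells, max_project, screen_round

PSF_PX = 120.0 / 65.35

for name, n_ori in (("halted", 1), ("replicating", 4)):
    params = cs.SimParams(include_ter=True, n_ori_spots=n_ori)
    cells, _ = cs.simulate_condition(params, 25, seed=11)
    table = {}
    for i, (stack, _) in enumerate(cells):
        roi = screen_round(detect_cells(stack))[0]
        table[i] = {
            "PARB": detect_foci(max_project(stack, "PARB"), roi.mask, PSF_PX, cell_id=i),
            "TER": detect_foci(max_project(stack, "TER"), roi.mask, PSF_PX, cell_id=i),
        }
    summary, ratio = count_and_ratio(table)
    print(f"{name}: ori foci/cell = {summary.mean['PARB']:.2f} "
          f"+/- {summary.sd['PARB']:.2f}, ori:ter ratio = {ratio:.2f}")
# A ratio of ~1 confirms a single chromosome per cell after the replication
# halt; ~4 reflects ongoing replication with multiple origins.
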
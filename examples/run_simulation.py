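"""A small end-to-end tumour simulation.

Initialises a 12^3 tissue block (cancer seed sphere at the centre, healthy
tissue around it, eight parent vessels), runs 60 hourly macro steps of the
train phase and prints how the populations and the vasculature evolve.
A full-scale run uses the default 40^3 lattice and 504 steps; see the
command line: ``oncolattice simulate --steps 504``.
"""

import pandas as pd

from oncolattice.config import load_config
from oncolattice.decision import run_train_phase

cfg = load_config(None, {
    "geometry": {"nx": 12, "ny": 12, "nz": 12},
    "horizon": 60,
    "seed": 4,
})
learners, trace, world = run_train_phase(cfg)
df = pd.DataFrame(trace)
cols = ["step", "n_cancerous", "n_necrotic", "n_healthy", "n_tip", "n_stalk",
        "perfused_segments"]
print(df[cols].iloc[::10].to_string(index=False))
print(f"\nexperience window sizes: "
      f"{ {cat: len(l.window) for cat, l in learners.items()} }")
print("(cancerous counts rise as the seed expands; hypoxic cells secrete "
      "VEGF, parent-vessel stalk cells sprout, and perfused segments begin "
      "supplying nutrients once an arteriole path touches the venous side)")
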
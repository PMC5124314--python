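"""Slide a 14-nt window along held-out hairpins and call cleavage sites.

Per-arm SVMs (w=14, k=5) are trained on 160 simulated precursors with a
strong planted cue; each held-out precursor is then scanned, the decision
score profile is maximised on each side of the apex, and the End Absolute
Error (EAE, |predicted - true| in nt) is summarised.
"""

import numpy as np

from lbsizecleav import (
    RunConfig,
    SyntheticParams,
    generate_dataset,
    scan_dataset,
    scan_precursor,
    train_eval,
)

params = SyntheticParams(n_precursors=180, signal_mode="mixed", signal_strength=1.0)
precursors, truth = generate_dataset(params, seed=29)
train, held_out = precursors[:160], precursors[160:]

cfg = RunConfig(scheme="lbsize", w=14, k=5, seed=29)
results, models = train_eval(train, cfg)

p = held_out[0]
res = scan_precursor(models, p)
row = truth[truth["id"] == p.id].iloc[0]
print(f"{p.id}: {len(res.sites)} candidate sites, apex at {res.apex}")
print(f"  true CD-5p={row['cd5p']}  predicted={res.predicted_cd5p}")
print(f"  true CD-3p={row['cd3p']}  predicted={res.predicted_cd3p}")
peak = np.argmax(res.scores)
print(f"  profile peak: site {res.sites[peak]} score {res.scores[peak]:.2f}")

truth_map = {r["id"]: (int(r["cd5p"]), int(r["cd3p"])) for _, r in truth.iterrows()}
_, profile = scan_dataset(models, held_out, truth_map)
print("\ncumulative EAE profile over", 2 * len(held_out), "arm calls:")
for t, frac in enumerate(profile):
    print(f"  fraction with EAE <= {t}: {frac:.2f}")
# A fraction near 1 at t=0..1 means the scanner recovers the planted cut
# site to within a nucleotide on almost every held-out hairpin.
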
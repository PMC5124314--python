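"""Simulate hairpins with a loop-length-dependent cleavage cue and compare
encodings by fivefold cross-validation.

90% of the 200 simulated precursors carry a 3-nt bulge at a fixed offset
from each true cleavage site; the bulge's bases are random, so only an
encoding that sees structure can find it.  Folds are split by precursor.
"""

from lbsizecleav import RunConfig, SyntheticParams, generate_dataset, train_eval

params = SyntheticParams(n_precursors=200, signal_strength=0.9)
precursors, truth = generate_dataset(params, seed=17)
print(f"{len(precursors)} precursors, {int(truth['planted'].sum())} carry the cue\n")

print(f"{'scheme':<10} {'arm':<4} {'Sn':>6} {'Sp':>6} {'Ac':>6} {'MCC':>7} {'AUC':>6}")
for scheme in ("lbsize", "extended", "struct", "seq"):
    cfg = RunConfig(scheme=scheme, w=8, k=2, seed=17)
    results, _ = train_eval(precursors, cfg, fit_final=False)
    for arm, res in results.items():
        m = res.mean
        print(
            f"{scheme:<10} {arm:<4} {m['Sn']:6.3f} {m['Sp']:6.3f} "
            f"{m['Ac']:6.3f} {m['MCC']:7.3f} {res.auc:6.3f}"
        )

# The loop-length scheme recovers the cue almost perfectly (accuracy near
# the 0.95 ceiling set by the 90% cue penetrance); presence-only structure
# schemes do worse, and the sequence-only scheme stays at chance because
# the cue carries no base information.
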
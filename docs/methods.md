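# Methods

## Model

The task is binary classification of inter-nucleotide sites on a
pre-miRNA hairpin: is this site a Dicer cleavage site (CD-5p on the 5p
arm, CD-3p on the 3p arm)? A site is represented by the even-length
window of `w` nucleotides centred on it, together with the `w` positions
facing it on the opposite strand of the stem. The classifier is a
soft-margin SVM with an RBF kernel on binary features; the contribution
is the feature map, which encodes the *length* of the loop/bulge run
containing each unpaired position.

Assumptions inherited from the problem setting:

* the secondary structure is given (a nested, pseudoknot-free
  dot-bracket string from any folding tool); this package never folds;
* cleavage sites are derived from annotated mature spans — CD-5p is the
  index just after the 3′ end of the 5p mature product, CD-3p the index
  of the first nucleotide of the 3p product (coordinates are 0-based
  half-open internally, 1-based inclusive in files);
* negatives are real sites of the same precursor a fixed offset
  (default 6 nt) from the true cut, by default shifted toward the apex
  into the Dicer-removed region. The offset and direction are
  configurable; the construction only requires the negative centre to be
  far from the true cut relative to the 1–2-nt biological wobble.

## Structure annotation

`parse_dotbracket` builds the pair map by stack matching and rejects
pseudoknotted notation outright. A loop/bulge is a maximal run of
consecutive unpaired positions *on one strand* (an asymmetric internal
loop of 2+3 nt yields l=2 on one strand, l=3 on the other), and the
terminal apex loop counts as a run like any bulge — its nucleotides get
loop tokens and it participates in the dataset maximum `M`. The apex is
located as the innermost pair's enclosed run; for multi-hairpin inputs
the innermost pair whose midpoint is closest to the sequence midpoint
wins (5′-most on ties), deterministically.

The complementary segment of a window takes the partners of the paired
window positions, walks the opposite-strand span between the outermost
partners in window orientation (nested pairing reverses order), includes
unpaired opposite-strand positions inside the span, and trims or pads
with gap placeholders at the apex-distal end to exactly `w` tokens. The
handling of asymmetric bulges here is a documented package choice —
"span walk with apex-distal adjustment" — because no canonical rule
exists; gaps encode as all-zero blocks, the least-informative choice,
and an all-zero feature block provably cannot change an RBF or linear
SVM's decision (tested).

## Encodings

Per-token dimension d, full-vector length in brackets:

| scheme | d | loop token | total |
|---|---|---|---|
| seq-binary | 4 | one-hot of its base | 4w (arm side only) |
| struct-binary | 4 | all zeros | 8w |
| extended-binary | 5 | fifth symbol L | 10w |
| lbsize | M+k+3 | k ones at 1-based slots (4+l)…(k+3+l) | 2w(M+k+3) |

`M` is the maximum loop/bulge run length over all precursors of the
training set (both arms jointly) and is frozen into the scheme at fit
time and serialized with the model; a longer loop seen at prediction
time is clipped to `M` with a warning. A loop token carries no base
identity (slots 1–4 stay zero), mirroring the extended pattern where L
replaces the base. When every loop has l=1 and k=1, d=5 and the lbsize
token map coincides with the extended pattern slot for slot (tested as
the reduction property).

Two exact kernel identities follow from the shifted-ones design and are
verified exhaustively for k ∈ {1..5}, l ∈ {1..10}:

* inner product `x1·x2 = max{k − |l1−l2|, 0}`;
* squared distance `‖x1−x2‖² = 2·min{|l1−l2|, k}`, via
  `‖x1‖² = ‖x2‖² = k`.

A quadratic variant of the RBF exponent, `4·min{(l1−l2)², k²}`, is
sometimes quoted for this construction but is inconsistent with the
inner product above; the test suite pins the linear form down as the one
the encoding actually produces (e.g. l=1 vs 3 at k=3 gives distance 4,
not 16).

## Training and evaluation

The SVM is scikit-learn's `SVC`. Hyperparameters are not dictated by the
problem, so the package fixes reproducible defaults: `gamma = 1 /
n_features` and `cost C = 1`; both are exposed. Models are trained **per
arm** — the two arms are separate classification problems, and pooling
them lets a 5p window shifted toward the terminus mimic the 3p positive
pattern, which measurably corrupts the scanner (a consistent −5-nt bias
under the synthetic conditions). The model archive stores the scheme and
both arms' fitted machines.

Cross-validation is fivefold with folds assigned by shuffling precursor
ids (caller-supplied seed) and dealing round-robin, so one hairpin's
positive and negative windows never straddle train and test; the split
is re-asserted structurally on every run. Each precursor contributes one
positive and one negative per arm, so folds are class-balanced by
construction. Reported per arm: per-fold Sn, Sp, Ac, MCC; their mean and
sample variance (n−1 denominator); pooled ROC (threshold sweep over
unique decision scores, trapezoidal AUC). MCC is defined as 0 when any
factor of its denominator is 0.

The scanner slides the model's window over every site admitting a full
window (profile length `L − w + 1`), scores each with the decision
function of its own arm's model (apex-interior sites use the 5p model up
to the apex midpoint), and calls the argmax on each side of the apex,
ties broken toward the 5′-most site. Windows with no paired position
take an all-gap complementary segment rather than failing, so the
profile stays complete. Site calls are summarised as the cumulative
fraction of EAE ≤ t.

## Synthetic data

The generator emulates the aspects of real precursors the method feeds
on, and only those:

* stem of 38–44 pairs per arm — long enough that every window size
  8–14 plus the 6-nt negative offset fits on an arm without touching the
  apex; total length ~85–100 nt;
* apex loop of 4–8 nt; bulges at rate 0.08 per stem position with
  lengths 1 (60%) or 2 (40%), never adjacent so run lengths stay exact;
* pairing 90% Watson–Crick / 10% G·U wobble, bases otherwise uniform;
* mature spans of 20–24 nt at the precursor ends; their inner
  boundaries are the true sites;
* a planted cue carried by 90% of precursors by default
  (`signal_strength`): a signature 3-nt bulge starting 4 nt before CD-5p
  and 1 nt after CD-3p (inside every positive window, outside every
  negative one for w ∈ {8..14}), and/or a fixed 4-mer ending at the cut.
  Background bulge lengths exclude the signature length, so the cue is
  unambiguous; the bulge's bases are random, so the sequence-only
  encoding gains nothing from it.

What it does *not* emulate: thermodynamic realism, miRBase length/GC
distributions, position-dependent base composition around real Dicer
sites, or structure-prediction noise. Passing the recovery tests
therefore shows the pipeline is correct and the loop-length features are
extractable when present — not that real-data accuracies are
reproduced; those depend on curated data and tuned hyperparameters
outside this package's scope.

Study conditions used by the test suite and `scripts/acceptance.py`,
chosen once as desk-scale defaults: 400 precursors for the
recovery/null cross-validation runs (800 windows per arm, w=8, k=2);
240 precursors (200 train / 40 scan) for the scanner benchmark with the
mixed cue at full penetrance and the w=14, k=5 model — the mixed cue is
used there because argmax localization benefits from position-specific
evidence on both the sequence and structure channels; 100 precursors
with apex length 1 and unit bulges for the reduction property.

## Numerical choices and degenerate inputs

* `gamma` default 1/n_features; grid search deliberately not run by
  default (determinism over tuning).
* Truncated windows (too close to a precursor end) are skipped with a
  logged warning, never padded — padding would invent sequence.
* Windows with no paired position raise in dataset construction but are
  tolerated in scanning (all-gap complement).
* `T` is accepted and folded to `U`; case is folded.
* Zero-length apex (a directly closed pair) yields an empty apex range;
  arm assignment still splits at it.
* EAE profile is reported from t=0 to max error and is non-decreasing
  by construction.

## Known limitations

* The complementary-segment rule at asymmetric bulges is one defensible
  convention among several; alternatives would change a minority of
  comp-strand tokens.
* The scanner assumes a single-hairpin structure; cloverleafs are
  handled by the deterministic apex rule but are not meaningful inputs.
* No probability calibration; decision scores are comparable within a
  model only.
* Real-data performance claims are out of scope (see above).
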
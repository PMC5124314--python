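# lbsizecleav

Prediction of Dicer cleavage sites on pre-miRNA hairpins from a binary
feature encoding that carries the **length** of loop/bulge structures,
not just their presence.

## The problem

A pre-miRNA is a ~65–90-nt stem–loop. Dicer cuts both arms of the stem
(at the sites CD-5p and CD-3p) to release the mature miRNA duplex, and
the loops and bulges of the stem are known determinants of where the cut
falls. Classifiers for this task slide an even-length window `w` over the
hairpin, centre positive examples on the true cut, centre negatives 6 nt
away, and encode each window position as a short binary block:

* sequence pattern — 4-dim one-hot over A/U/C/G (4w features, arm side);
* structure pattern — one-hot, with loop/bulge positions zeroed;
* extended pattern — 5-dim one-hot over A/U/C/G/L, where L marks any
  loop/bulge position (10w features, both strands).

All of these treat a 1-nt bulge and a 7-nt loop identically. The encoding
implemented here replaces the single L symbol with a run-length-aware
block: let `M` be the largest loop/bulge length in the training data and
`k ≥ 1` a sensitivity parameter. A nucleotide token occupies a one-hot in
the first 4 of `M+k+3` slots; a loop token of length `l` carries `k` ones
in slots `(4+l) … (k+3+l)`. A window then maps to a `2w(M+k+3)`-dim
vector (arm + complementary strand). The shifted-ones design gives the
kernel a closed form on loop tokens:

```
x1 · x2      = max{ k − |l1 − l2|, 0 }
‖x1 − x2‖²   = 2 · min{ |l1 − l2|, k }
```

so similarity under the RBF kernel `exp(−γ‖x1−x2‖²)` decays smoothly
with the loop-length difference, at a rate set by `k`. An RBF-kernel SVM
is trained per arm; evaluation is fivefold cross-validation split by
precursor (sensitivity, specificity, accuracy, MCC, with per-fold
variance and pooled ROC/AUC), and a shift-window scanner scores every
candidate site of a hairpin, calling the argmax on each side of the apex
loop. Site calls are summarised by the End Absolute Error (EAE),
`|predicted − true|` in nucleotides.

Because curated precursor datasets cannot be redistributed here, the
package includes a synthetic hairpin generator (stem, bulges of
controlled lengths, apex loop, mature spans, and an optional planted
sequence- or loop-length-dependent cue at the true sites) that exercises
every stage end to end.

## Worked example

`examples/03_simulate_and_crossvalidate.py` simulates 200 hairpins, 90%
of which carry a 3-nt bulge at a fixed offset from each true cut (the
bulge's bases are random, so sequence alone is uninformative), then
cross-validates four encodings:

```
200 precursors, 178 carry the cue

scheme     arm      Sn     Sp     Ac     MCC    AUC
lbsize     5p    0.890  1.000  0.945   0.896  0.934
lbsize     3p    0.890  1.000  0.945   0.896  0.922
extended   5p    0.895  0.945  0.920   0.843  0.944
extended   3p    0.895  0.940  0.918   0.836  0.933
struct     5p    0.895  0.940  0.917   0.838  0.944
struct     3p    0.895  0.935  0.915   0.831  0.939
seq        5p    0.445  0.530  0.487  -0.025  0.500
seq        3p    0.555  0.475  0.515   0.030  0.499
```

The loop-length encoding sits at the ~0.95 accuracy ceiling implied by
the 90% cue penetrance; presence-only structure encodings trail it, and
the sequence-only encoding stays at chance. The other example scripts
cover structure annotation (`01`), the token encoding and its kernel
closed forms (`02`), and whole-precursor scanning with EAE (`04`).

The same workflows are available from the shell:

```sh
lbsizecleav simulate --n 200 --seed 17 --out data/
lbsizecleav train --fasta data/precursors.fa --structures data/precursors.dbn \
    --annotation data/annotation.tsv --scheme lbsize -w 14 --k 5 --out run/
lbsizecleav scan --model run/model.joblib --fasta data/precursors.fa \
    --structures data/precursors.dbn --truth data/truth.tsv --out scan/
```

Inputs are FASTA, Vienna dot-bracket records, and a tab-separated
annotation of mature-arm spans (1-based inclusive); outputs are TSV
reports, SVM-light feature files, and a joblib model archive.

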
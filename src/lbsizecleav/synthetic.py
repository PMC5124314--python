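"""Synthetic pre-miRNA hairpins with controlled loop/bulge statistics.

Real training data for cleavage-site prediction (miRBase precursors with
experimentally validated mature arms and folded structures) cannot be
bundled, so this module generates stem--loop precursors from scratch:

* a stem of Watson--Crick (90%) / G-U wobble (10%) pairs, long enough that
  every window size 8--14 nt plus the 6-nt negative offset fits on an arm,
* background bulges (unpaired runs on one strand, alternating strands by
  construction of independent per-arm placement) with controlled lengths,
* a terminal apex loop,
* mature spans at the precursor ends whose inner boundaries define the
  true cleavage sites CD-5p and CD-3p,
* an optional planted cue at the true sites, carried by the sequence
  (a fixed 4-mer ending at the cut), by the structure (a bulge of a
  signature length at a fixed offset from the cut), or both ("mixed").
  ``signal_strength`` is the probability a precursor carries the cue;
  0 yields a null dataset with label-independent windows.

Generated structures are valid nested dot-brackets by construction and
ground truth (true sites, cue presence) is emitted in the same annotation
dialect the dataset loader reads, so synthetic and real data flow through
identical code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import LabeledWindow, Precursor, Token

__all__ = [
    "SyntheticParams",
    "generate_precursor",
    "generate_dataset",
    "write_dataset",
    "fixture_worked_example",
]

_WC = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WOBBLE = {"G": "U", "U": "G"}
_BASES = np.array(list("AUCG"))


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; the defaults define the package's study conditions.

    stem_pairs 38--44 keeps the arms long enough for all supported window
    geometries; mature length 20--24 nt matches the ~22-nt mature miRNA;
    the signature bulge (length 3) is planted so it sits inside every
    positive window and outside every negative window for w in {8..14}
    with the default 6-nt offset.  Background bulges are 1--2 nt, so the
    signature length never occurs by chance.
    """

    n_precursors: int = 400
    stem_pairs: tuple[int, int] = (38, 44)
    apex_length: tuple[int, int] = (4, 8)
    bulge_rate: float = 0.08
    bulge_lengths: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.4}
    )
    signal_mode: str = "loop-length"  # sequence-motif | loop-length | mixed
    signal_strength: float = 0.9
    signal_loop_len: int = 3
    signal_motif: str = "GGAC"
    signal_offset5: int | None = None  # bulge start relative to CD-5p; default -(l+1)
    signal_offset3: int = 1  # bulge start relative to CD-3p
    mature_length: tuple[int, int] = (20, 24)
    wobble_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.signal_mode not in ("sequence-motif", "loop-length", "mixed"):
            raise ValueError(f"unknown signal mode {self.signal_mode!r}")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if not 0.0 <= self.bulge_rate <= 1.0:
            raise ValueError("bulge_rate must be in [0, 1]")
        if self.signal_loop_len < 1:
            raise ValueError("signal_loop_len must be >= 1")
        for lo, hi in (self.stem_pairs, self.apex_length, self.mature_length):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be non-empty and positive")

    @property
    def offset5(self) -> int:
        if self.signal_offset5 is not None:
            return self.signal_offset5
        return -(self.signal_loop_len + 1)


def _sample_range(rng: np.random.Generator, span: tuple[int, int]) -> int:
    return int(rng.integers(span[0], span[1] + 1))


def _sample_bulge_length(rng: np.random.Generator, dist: dict[int, float]) -> int:
    lengths = np.array(sorted(dist))
    probs = np.array([dist[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(lengths, p=probs))


def _build_arm(
    rng: np.random.Generator,
    n_pairs: int,
    params: SyntheticParams,
    plant_start: int | None,
) -> list[bool]:
    """Paired-position flags for one arm, walked from the terminus inward.

    ``plant_start`` is the arm-local position where the signature bulge of
    length ``signal_loop_len`` begins (or None).  A one-position guard
    keeps random bulges from touching the planted run, so its run length
    stays exactly the signature length.
    """
    l_sig = params.signal_loop_len
    guard: range = (
        range(plant_start - 1, plant_start + l_sig + 1)
        if plant_start is not None
        else range(0)
    )
    flags: list[bool] = []
    pairs = 0
    pos = 0
    while pairs < n_pairs:
        if plant_start is not None and pos == plant_start:
            flags.extend([False] * l_sig)
            pos += l_sig
            continue
        # a bulge needs a paired neighbour on both sides, so runs of
        # controlled length never merge into longer ones
        can_bulge = pairs > 0 and flags[-1]
        if can_bulge and rng.random() < params.bulge_rate:
            lb = _sample_bulge_length(rng, params.bulge_lengths)
            if not (plant_start is not None and pos + lb > guard.start and pos <= guard.stop):
                flags.extend([False] * lb)
                pos += lb
                continue
        flags.append(True)
        pairs += 1
        pos += 1
    return flags


def generate_precursor(
    params: SyntheticParams,
    rng: np.random.Generator,
    index: int = 0,
) -> tuple[Precursor, dict]:
    """One synthetic hairpin plus its ground truth.

    Returns ``(precursor, truth)`` where truth records the true cleavage
    sites (inter-nucleotide indices) and whether the cue was planted.
    """
    n_pairs = _sample_range(rng, params.stem_pairs)
    apex_len = _sample_range(rng, params.apex_length)
    m5 = _sample_range(rng, params.mature_length)
    m3 = _sample_range(rng, params.mature_length)
    planted = bool(rng.random() < params.signal_strength)
    plant_loop = planted and params.signal_mode in ("loop-length", "mixed")
    plant_motif = planted and params.signal_mode in ("sequence-motif", "mixed")
    l_sig = params.signal_loop_len

    # 5p arm in sequence order; planted bulge starts at CD-5p + offset5.
    plant5 = m5 + params.offset5 if plant_loop else None
    arm5 = _build_arm(rng, n_pairs, params, plant5)
    # 3p arm walked from the 3' terminus inward; the planted bulge occupies
    # sequence positions CD-3p + offset3 .. + offset3 + l - 1, i.e. arm-local
    # (from-terminus) positions starting at m3 - offset3 - l.
    plant3 = m3 - params.signal_offset3 - l_sig if plant_loop else None
    rev3 = _build_arm(rng, n_pairs, params, plant3)

    if m5 > len(arm5) or m3 > len(rev3):
        raise ValueError(
            f"precursor {index}: mature span longer than arm "
            f"({m5}/{len(arm5)} nt on 5p, {m3}/{len(rev3)} nt on 3p)"
        )

    structure = (
        "".join("(" if p else "." for p in arm5)
        + "." * apex_len
        + "".join(")" if p else "." for p in reversed(rev3))
    )
    L = len(structure)

    # Base assignment: pair-consistent random bases, then motif overrides.
    from .structure import parse_dotbracket

    pairmap = parse_dotbracket(structure)
    seq = [""] * L
    for i, j in pairmap.pairs():
        b = str(rng.choice(_BASES))
        if b in _WOBBLE and rng.random() < params.wobble_rate:
            seq[i], seq[j] = b, _WOBBLE[b]
        else:
            seq[i], seq[j] = b, _WC[b]
    for i in range(L):
        if not seq[i]:
            seq[i] = str(rng.choice(_BASES))

    cd5p, cd3p = m5, L - m3
    if plant_motif:
        motif = params.signal_motif
        n = len(motif)
        # 3p first, 5p last: partner fixes from the 5p motif may fall near
        # the 3p motif, and the 5p cue is the one the scanner benchmark uses.
        for start in (cd3p, cd5p - n):
            for t, base in enumerate(motif):
                p = start + t
                seq[p] = base
                q = int(pairmap.partner[p])
                if q >= 0:
                    seq[q] = _WC[base]

    precursor = Precursor(
        id=f"synth-{index:04d}",
        sequence="".join(seq),
        structure=structure,
        mature5p=(0, m5),
        mature3p=(L - m3, L),
    )
    truth = {
        "id": precursor.id,
        "cd5p": cd5p,
        "cd3p": cd3p,
        "planted": planted,
        "signal_mode": params.signal_mode,
    }
    return precursor, truth


def generate_dataset(params: SyntheticParams, seed: int):
    """``n_precursors`` independent hairpins and their ground-truth table."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    precursors: list[Precursor] = []
    truths: list[dict] = []
    for i in range(params.n_precursors):
        prec, truth = generate_precursor(params, rng, index=i)
        precursors.append(prec)
        truths.append(truth)
    truth_table = pd.DataFrame(
        truths, columns=["id", "cd5p", "cd3p", "planted", "signal_mode"]
    )
    return precursors, truth_table


def write_dataset(precursors, truth_table, outdir) -> dict[str, str]:
    """Write FASTA + dot-bracket + annotation TSV + ground-truth TSV.

    The annotation TSV uses the loader's dialect (1-based inclusive mature
    spans), so synthetic data round-trips through the same I/O as real data.
    Returns the written paths.
    """
    from pathlib import Path

    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(outdir / "precursors.fa"),
        "structures": str(outdir / "precursors.dbn"),
        "annotation": str(outdir / "annotation.tsv"),
        "truth": str(outdir / "truth.tsv"),
    }
    _io.write_fasta(precursors, paths["fasta"])
    _io.write_dotbracket(precursors, paths["structures"])
    _io.write_annotation(precursors, paths["annotation"])
    truth_table.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def fixture_worked_example() -> tuple[LabeledWindow, LabeledWindow]:
    """The hsa-miR-200c worked-example windows (k=3, w=6).

    The positive 5p window covers the letters UGGgug (lowercase = region
    removed by Dicer) with 1-nt loops at window positions 1 and 5 (1-based),
    tokenising to L1 G G G L1 G; the negative 3p window CGUCAU is fully
    paired.  The complementary strand is not part of the illustration, so
    the windows carry gap placeholders there; encode the arm side with
    ``encode_tokens`` to get the 6(M+6)-dimensional per-arm pattern.
    """
    U, G, C, A = (Token(b) for b in "UGCA")
    win5p = LabeledWindow(
        precursor_id="hsa-miR-200c-example",
        arm="5p",
        label=1,
        center=22,
        arm_tokens=(Token("U", 1), G, G, G, Token("U", 1), G),
        comp_tokens=(Token(None),) * 6,
    )
    win3p = LabeledWindow(
        precursor_id="hsa-miR-200c-example",
        arm="3p",
        label=-1,
        center=39,
        arm_tokens=(C, G, U, C, A, U),
        comp_tokens=(Token(None),) * 6,
    )
    return win5p, win3p
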
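"""RNA secondary-structure primitives for hairpin precursors.

A pre-miRNA folds into a stem--loop: two arms (5p and 3p) paired into a
stem, interrupted by loops/bulges (maximal runs of unpaired nucleotides on
one strand) and closed by the terminal apex loop.  Everything downstream --
window tokenisation, the loop-length encoding, the site scanner -- is built
on three annotations computed here from a dot-bracket string:

* the base-pair map (which position pairs with which),
* the per-position loop/bulge run length ``l`` (0 for paired positions;
  the apex loop counts as a run like any bulge),
* the apex location, which splits the precursor into its 5p and 3p arms.

Coordinates are 0-based half-open throughout this package; user-facing
files use 1-based inclusive coordinates and are converted at the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UNPAIRED = -1

__all__ = [
    "UNPAIRED",
    "StructureError",
    "PairMap",
    "LoopAnnotation",
    "ArmLabels",
    "parse_dotbracket",
    "annotate_loops",
    "find_apex",
    "complementary_segment",
    "max_loop_length",
]


class StructureError(ValueError):
    """Raised for malformed or unusable secondary structures."""


@dataclass(frozen=True)
class PairMap:
    """Base-pair map of a nested (pseudoknot-free) secondary structure.

    ``partner[i]`` is the index paired with ``i``, or ``UNPAIRED`` (-1).
    """

    partner: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "partner", np.asarray(self.partner, dtype=np.int64))

    def __len__(self) -> int:
        return int(self.partner.shape[0])

    def is_paired(self, i: int) -> bool:
        return self.partner[i] != UNPAIRED

    def pairs(self) -> list[tuple[int, int]]:
        """All base pairs as (i, j) with i < j, in 5' order."""
        return [
            (i, int(j))
            for i, j in enumerate(self.partner)
            if j != UNPAIRED and i < j
        ]

    def render(self) -> str:
        """Dot-bracket string for this pair map."""
        out = []
        for i, j in enumerate(self.partner):
            if j == UNPAIRED:
                out.append(".")
            elif i < j:
                out.append("(")
            else:
                out.append(")")
        return "".join(out)


@dataclass(frozen=True)
class LoopAnnotation:
    """Per-position loop/bulge run lengths.

    ``run_length[i]`` is the size of the maximal contiguous unpaired run
    (in sequence coordinates, i.e. per strand) containing ``i``; 0 iff the
    position is paired.  ``run_id[i]`` identifies that run (-1 if paired);
    runs are numbered 0,1,... in 5' order.
    """

    run_length: np.ndarray
    run_id: np.ndarray

    def __len__(self) -> int:
        return int(self.run_length.shape[0])


@dataclass(frozen=True)
class ArmLabels:
    """Apex (terminal loop) location and per-position arm assignment.

    ``apex`` is the half-open index range of the terminal loop; ``side[i]``
    is ``"5p"`` before it, ``"3p"`` after it, ``"apex"`` inside.
    """

    apex: tuple[int, int]
    side: np.ndarray = field(repr=False)

    def arm_of_site(self, site: int) -> str:
        """Arm of an inter-nucleotide cut index (``"5p"``, ``"3p"`` or ``"apex"``)."""
        start, stop = self.apex
        if site <= start:
            return "5p"
        if site >= stop:
            return "3p"
        return "apex"


def parse_dotbracket(structure: str) -> PairMap:
    """Parse a dot-bracket string into a :class:`PairMap`.

    Only ``.``, ``(`` and ``)`` are accepted; pseudoknotted notations
    (``[]``, ``{}``, letters) are rejected.  Raises :class:`StructureError`
    naming the offending position on unbalanced or illegal input.
    """
    partner = np.full(len(structure), UNPAIRED, dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(
                    f"unbalanced ')' at position {i}: no matching '('"
                )
            j = stack.pop()
            partner[i] = j
            partner[j] = i
        elif ch != ".":
            raise StructureError(
                f"illegal character {ch!r} at position {i} "
                "(expected '.', '(' or ')')"
            )
    if stack:
        raise StructureError(
            f"unbalanced '(' at position {stack[-1]}: no matching ')'"
        )
    return PairMap(partner)


def annotate_loops(pairmap: PairMap) -> LoopAnnotation:
    """Label every position with the length of its unpaired run.

    Runs are maximal stretches of consecutive unpaired positions in
    sequence order (per strand): an internal loop of 2+3 nucleotides
    yields l=2 on one strand and l=3 on the other.  The terminal apex
    loop is a run like any other.
    """
    n = len(pairmap)
    run_length = np.zeros(n, dtype=np.int64)
    run_id = np.full(n, -1, dtype=np.int64)
    i = 0
    rid = 0
    while i < n:
        if pairmap.partner[i] != UNPAIRED:
            i += 1
            continue
        j = i
        while j < n and pairmap.partner[j] == UNPAIRED:
            j += 1
        run_length[i:j] = j - i
        run_id[i:j] = rid
        rid += 1
        i = j
    return LoopAnnotation(run_length=run_length, run_id=run_id)


def find_apex(pairmap: PairMap) -> ArmLabels:
    """Locate the terminal (apex) loop and split the hairpin into arms.

    The apex is the unpaired run enclosed by an innermost pair -- a pair
    (i, j) with no other pair strictly inside.  Multi-hairpin structures
    are resolved deterministically: the innermost pair whose midpoint is
    closest to the sequence midpoint wins (5'-most on ties).
    """
    pairs = pairmap.pairs()
    if not pairs:
        raise StructureError("no hairpin: structure contains no base pairs")
    n = len(pairmap)
    paired_pos = np.flatnonzero(pairmap.partner != UNPAIRED)
    innermost = []
    for i, j in pairs:
        inside = paired_pos[(paired_pos > i) & (paired_pos < j)]
        if inside.size == 0:
            innermost.append((i, j))
    mid = (n - 1) / 2.0
    i, j = min(innermost, key=lambda p: (abs((p[0] + p[1]) / 2.0 - mid), p[0]))
    apex = (i + 1, j)  # half-open; may be empty for a zero-length loop
    side = np.empty(n, dtype=object)
    side[: apex[0]] = "5p"
    side[apex[0] : apex[1]] = "apex"
    side[apex[1] :] = "3p"
    return ArmLabels(apex=apex, side=side)


def complementary_segment(
    window_start: int,
    w: int,
    pairmap: PairMap,
    annotation: LoopAnnotation | None = None,
) -> list[int | None]:
    """Opposite-strand positions facing a window, as a length-``w`` list.

    For each paired window position the partner is taken; the opposite-
    strand span between the outermost partners is walked in window
    orientation (partners reverse order under nested pairing), so unpaired
    opposite-strand positions inside the span are included.  The result is
    trimmed or padded with ``None`` (gap placeholders) at the apex-distal
    end to exactly ``w`` entries.

    Raises :class:`StructureError` if the window contains no paired
    position to anchor on.
    """
    positions = range(window_start, window_start + w)
    if window_start < 0 or window_start + w > len(pairmap):
        raise StructureError(
            f"window [{window_start}, {window_start + w}) out of bounds "
            f"for length {len(pairmap)}"
        )
    anchors = [(p, int(pairmap.partner[p])) for p in positions if pairmap.is_paired(p)]
    if not anchors:
        raise StructureError(
            f"no anchor pair in window [{window_start}, {window_start + w})"
        )
    partners = [q for _, q in anchors]
    lo, hi = min(partners), max(partners)
    # Window orientation: nested pairing reverses order, so the opposite
    # span is walked high -> low for windows on either arm.
    segment: list[int | None] = list(range(hi, lo - 1, -1))
    on_5p = partners[0] > anchors[0][0]  # partners downstream => window on 5p arm
    if on_5p:
        # segment[0] faces window position 0 == the apex-distal window end
        if len(segment) > w:
            segment = segment[len(segment) - w :]
        else:
            segment = [None] * (w - len(segment)) + segment
    else:
        if len(segment) > w:
            segment = segment[:w]
        else:
            segment = segment + [None] * (w - len(segment))
    return segment


def max_loop_length(annotations) -> int:
    """Maximum loop/bulge run length M over a collection of annotations.

    M fixes the per-token dimension of the loop-length encoding and is
    computed over the whole training dataset, both arms jointly.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValueError("max_loop_length: empty collection")
    return max(int(a.run_length.max(initial=0)) for a in annotations)
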
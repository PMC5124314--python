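"""Labeled window construction around Dicer cleavage sites.

A cleavage site is an inter-nucleotide index: the cut falls between
positions ``site - 1`` and ``site``.  The 5p-arm site (CD-5p) is the index
just after the 3' end of the 5p mature product; the 3p-arm site (CD-3p) is
the index of the first nucleotide of the 3p mature product.

For each arm, a positive window of even size ``w`` is centred on the true
site and a negative window on a site ``offset`` nucleotides away (default
6 nt, shifted toward the apex into the Dicer-removed region; the direction
and offset are configurable since the negative centre only needs to be far
enough from the real cut).  Each window carries ``w`` arm-side tokens and
``w`` complementary-strand tokens; a token is a nucleotide, a loop symbol
``L_l`` (unpaired, in a run of length ``l``), or a gap placeholder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .structure import (
    ArmLabels,
    LoopAnnotation,
    PairMap,
    StructureError,
    annotate_loops,
    complementary_segment,
    find_apex,
    parse_dotbracket,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "Precursor",
    "CleavageSites",
    "LabeledWindow",
    "locate_cleavage_sites",
    "tokenize_positions",
    "extract_window",
    "make_examples",
]

GAP_SYMBOL = "-"
_VALID_BASES = frozenset("AUCG")


@dataclass(frozen=True)
class Token:
    """One window token: a nucleotide, a loop/bulge symbol, or a gap.

    ``base`` keeps the underlying nucleotide even for loop positions (the
    sequence-only encoding still needs it); ``loop`` is the run length l of
    the loop/bulge containing the position (0 = paired).  A gap placeholder
    has ``base=None``.
    """

    base: str | None
    loop: int = 0

    def __post_init__(self) -> None:
        if self.base is not None and self.base not in _VALID_BASES:
            raise ValueError(f"invalid base {self.base!r}")
        if self.loop < 0:
            raise ValueError("loop length must be >= 0")

    @property
    def is_gap(self) -> bool:
        return self.base is None

    @property
    def is_loop(self) -> bool:
        return self.loop > 0 and self.base is not None

    def render(self) -> str:
        if self.is_gap:
            return GAP_SYMBOL
        if self.is_loop:
            return f"L{self.loop}"
        return self.base


def normalize_sequence(sequence: str) -> str:
    """Case-fold and map DNA T to RNA U."""
    return sequence.upper().replace("T", "U")


@dataclass(frozen=True)
class Precursor:
    """One pre-miRNA hairpin: sequence, structure, mature-arm spans.

    ``mature5p`` / ``mature3p`` are 0-based half-open spans or ``None``;
    1-based inclusive coordinates in annotation files are converted at the
    I/O layer.
    """

    id: str
    sequence: str
    structure: str
    mature5p: tuple[int, int] | None = None
    mature3p: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if len(self.sequence) != len(self.structure):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )
        for name in ("mature5p", "mature3p"):
            span = getattr(self, name)
            if span is not None:
                a, b = span
                if not (0 <= a < b <= len(self.sequence)):
                    raise ValueError(f"{self.id}: {name} span {span} out of bounds")
        if self.mature5p is not None and self.mature3p is not None:
            if self.mature5p[1] > self.mature3p[0]:
                raise ValueError(
                    f"{self.id}: mature5p must end before mature3p starts"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def pairmap(self) -> PairMap:
        return parse_dotbracket(self.structure)

    def annotation(self) -> LoopAnnotation:
        return annotate_loops(self.pairmap())

    def arms(self) -> ArmLabels:
        return find_apex(self.pairmap())


@dataclass(frozen=True)
class CleavageSites:
    """Inter-nucleotide cut indices per arm (``None`` = arm absent)."""

    cd5p: int | None
    cd3p: int | None


@dataclass(frozen=True)
class LabeledWindow:
    """A window of w arm tokens + w complementary tokens with a ±1 label."""

    precursor_id: str
    arm: str  # "5p" | "3p"
    label: int  # +1 | -1
    center: int  # inter-nucleotide index
    arm_tokens: tuple[Token, ...]
    comp_tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be '5p' or '3p', got {self.arm!r}")
        if self.label not in (1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")
        if len(self.arm_tokens) != len(self.comp_tokens):
            raise ValueError("arm and complementary token counts differ")

    @property
    def w(self) -> int:
        return len(self.arm_tokens)


def locate_cleavage_sites(precursor: Precursor) -> CleavageSites:
    """Cleavage sites implied by the mature spans.

    CD-5p = index just after the last 5p-mature nucleotide; CD-3p = index
    of the first 3p-mature nucleotide.  An absent arm yields ``None``;
    both absent is an error.
    """
    if precursor.mature5p is None and precursor.mature3p is None:
        raise ValueError(f"{precursor.id}: no mature span on either arm")
    cd5p = precursor.mature5p[1] if precursor.mature5p is not None else None
    cd3p = precursor.mature3p[0] if precursor.mature3p is not None else None
    return CleavageSites(cd5p=cd5p, cd3p=cd3p)


def tokenize_positions(
    positions,
    sequence: str,
    annotation: LoopAnnotation,
) -> tuple[Token, ...]:
    """Turn sequence positions (``None`` = gap) into window tokens."""
    tokens = []
    for p in positions:
        if p is None:
            tokens.append(Token(base=None))
        else:
            tokens.append(
                Token(base=sequence[p], loop=int(annotation.run_length[p]))
            )
    return tuple(tokens)


def extract_window(
    site: int,
    w: int,
    precursor: Precursor,
    annotation: LoopAnnotation,
) -> tuple[Token, ...]:
    """Tokens of the w-nucleotide window centred on an inter-nucleotide site.

    The window covers positions ``site - w/2 .. site + w/2 - 1``; ``w``
    must be even so the cut sits exactly at the centre.  A window reaching
    past either end of the precursor raises (callers skip such examples).
    """
    if w % 2 != 0 or w < 2:
        raise ValueError(f"window size must be a positive even number, got {w}")
    start = site - w // 2
    if start < 0 or start + w > len(precursor):
        raise ValueError(
            f"{precursor.id}: window truncated at site {site} (w={w})"
        )
    return tokenize_positions(range(start, start + w), precursor.sequence, annotation)


def _negative_center(site: int, arm: str, offset: int, direction: str) -> int:
    toward_apex = direction == "toward-apex"
    if arm == "5p":
        return site + offset if toward_apex else site - offset
    return site - offset if toward_apex else site + offset


def make_examples(
    precursor: Precursor,
    w: int,
    offset: int = 6,
    direction: str = "toward-apex",
    annotation: LoopAnnotation | None = None,
    pairmap: PairMap | None = None,
) -> list[LabeledWindow]:
    """Positive and negative labeled windows for every available arm.

    Per arm: one positive window centred on the cleavage site, one negative
    centred ``offset`` nt away in ``direction`` ("toward-apex", into the
    Dicer-removed region, or "toward-terminus").  Windows that would be
    truncated or have no paired position to anchor the complementary strand
    are skipped with a logged warning.
    """
    if direction not in ("toward-apex", "toward-terminus"):
        raise ValueError(f"unknown direction {direction!r}")
    if pairmap is None:
        pairmap = precursor.pairmap()
    if annotation is None:
        annotation = annotate_loops(pairmap)
    sites = locate_cleavage_sites(precursor)
    windows: list[LabeledWindow] = []
    for arm, site in (("5p", sites.cd5p), ("3p", sites.cd3p)):
        if site is None:
            continue
        for label, center in (
            (1, site),
            (-1, _negative_center(site, arm, offset, direction)),
        ):
            try:
                arm_tokens = extract_window(center, w, precursor, annotation)
                comp_positions = complementary_segment(
                    center - w // 2, w, pairmap, annotation
                )
            except (ValueError, StructureError) as exc:
                logger.warning(
                    "%s: skipping %s %s window at %d: %s",
                    precursor.id,
                    "positive" if label == 1 else "negative",
                    arm,
                    center,
                    exc,
                )
                continue
            comp_tokens = tokenize_positions(
                comp_positions, precursor.sequence, annotation
            )
            windows.append(
                LabeledWindow(
                    precursor_id=precursor.id,
                    arm=arm,
                    label=label,
                    center=center,
                    arm_tokens=arm_tokens,
                    comp_tokens=comp_tokens,
                )
            )
    return windows
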
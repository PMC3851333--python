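"""Cleavage / non-cleavage pattern windows and overlapping scan windows.

A pattern window is a fixed, even width ``w`` slice of the duplex alignment:
an anchoring-arm row and its (partial) complement row.  For a cleavage
pattern the scissile bond sits exactly at the centre, between tokens ``w/2``
and ``w/2 + 1``.  Non-cleavage patterns are taken from inside the mature
miRNA body, past the six nucleotides adjacent to the cut, because Dicer
essentially never cuts in the middle of a mature miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from .hairpin import (
    GAP,
    Arm,
    CleavageSite,
    DuplexAlignment,
    Hairpin,
    build_duplex_alignment,
)

PATTERN_WIDTHS = (8, 10, 12, 14)

Label = Literal["cleavage", "noncleavage", "unlabeled"]


@dataclass(frozen=True)
class PatternWindow:
    """A width-``w`` window of arm and complement tokens around a candidate cut.

    ``center_cut_after`` is the 1-based hairpin position whose 3' bond sits at
    the window centre (``None`` when the centre column carries a gap on the
    arm row, which can happen in full-alignment mode).
    """

    hairpin_id: str
    arm: Arm
    width: int
    arm_tokens: tuple[str, ...]
    complement_tokens: tuple[str, ...]
    center_cut_after: Optional[int]
    label: Label = "unlabeled"

    def __post_init__(self) -> None:
        if self.width % 2 or self.width < 2:
            raise ValueError("width must be a positive even number")
        if len(self.arm_tokens) != self.width or len(self.complement_tokens) != self.width:
            raise ValueError("token rows must have exactly `width` entries")


def _check_width(width: int) -> None:
    if width not in PATTERN_WIDTHS:
        raise ValueError(f"width must be one of {PATTERN_WIDTHS}, got {width}")


def _window_at(
    da: DuplexAlignment,
    center_col: int,
    width: int,
    label: Label,
    center_cut_after: Optional[int],
) -> PatternWindow:
    half = width // 2
    lo, hi = center_col - half + 1, center_col + half
    arm_row, comp_row = [], []
    n = len(da)
    arm_tokens, comp_tokens = da.arm_tokens, da.complement_tokens
    for i in range(lo, hi + 1):
        if 0 <= i < n:
            arm_row.append(arm_tokens[i])
            comp_row.append(comp_tokens[i])
        else:  # beyond the stem: pad both rows
            arm_row.append(GAP)
            comp_row.append(GAP)
    return PatternWindow(
        hairpin_id=da.hairpin_id,
        arm=da.anchor,
        width=width,
        arm_tokens=tuple(arm_row),
        complement_tokens=tuple(comp_row),
        center_cut_after=center_cut_after,
        label=label,
    )


def extract_cleavage_pattern(
    da: DuplexAlignment, site: CleavageSite, width: int
) -> PatternWindow:
    """Positive-class window: the cut bond at the centre of a width-w window.

    The window spans arm positions ``[cut_after - w/2 + 1, cut_after + w/2]``;
    columns beyond the stem are gap-padded on both rows.
    """
    _check_width(width)
    if site.arm != da.anchor:
        raise ValueError(
            f"site is on {site.arm} but alignment is anchored on {da.anchor}"
        )
    center = da.column_index(site.cut_after)
    return _window_at(da, center, width, "cleavage", site.cut_after)


def extract_noncleavage_pattern(
    da: DuplexAlignment, site: CleavageSite, width: int, offset: int = 7
) -> PatternWindow:
    """Negative-class window shifted ``offset`` columns into the mature miRNA.

    The mature body lies 5' of the cut on the 5p arm and 3' of the cut on the
    3p arm.  ``offset >= 7`` guarantees the six nucleotides adjacent to the
    cut are omitted from the negative's centre.
    """
    _check_width(width)
    if offset < 7:
        raise ValueError(
            "offset must be >= 7 so the 6 nt adjacent to the cut are omitted"
        )
    if site.arm != da.anchor:
        raise ValueError(
            f"site is on {site.arm} but alignment is anchored on {da.anchor}"
        )
    direction = -1 if site.arm == "5p" else 1
    center = da.column_index(site.cut_after) + direction * offset
    half = width // 2
    if center + half < 0 or center - half + 1 >= len(da):
        raise ValueError(
            f"non-cleavage window for {da.hairpin_id!r} falls entirely outside the stem"
        )
    if 0 <= center < len(da) and da.arm_position(center) is not None:
        center_cut = da.arm_position(center)
    else:
        center_cut = site.cut_after + direction * offset
    return _window_at(da, center, width, "noncleavage", center_cut)


def enumerate_scan_windows(
    da: DuplexAlignment, width: int, true_site: Optional[CleavageSite] = None
) -> list[PatternWindow]:
    """All full (unpadded) overlapping windows along the stem, step 1 column.

    With a known ``true_site``, exactly the window whose centre bond is the
    annotated cut is labelled ``cleavage`` and every other window
    ``noncleavage``; without one all windows are ``unlabeled``.
    """
    if width % 2 or width < 2:
        raise ValueError("width must be a positive even number")
    n = len(da)
    if n < width:
        return []
    if true_site is not None and true_site.arm != da.anchor:
        raise ValueError(
            f"true site is on {true_site.arm} but alignment is anchored on {da.anchor}"
        )
    windows = []
    for start in range(0, n - width + 1):
        center = start + width // 2 - 1
        pos = da.arm_position(center)
        if true_site is None:
            label: Label = "unlabeled"
        elif pos is not None and pos == true_site.cut_after:
            label = "cleavage"
        else:
            label = "noncleavage"
        windows.append(_window_at(da, center, width, label, pos))
    return windows


def build_training_windows(
    hairpins: Sequence[Hairpin],
    annotations: Iterable[tuple[str, CleavageSite]],
    width: int = 14,
    arm: Arm = "5p",
    offset: int = 7,
    mode: str = "arm-anchored",
) -> list[PatternWindow]:
    """One positive and one paired negative window per annotated cut.

    Annotations on the other arm are ignored; an annotation naming an unknown
    hairpin raises.  This reproduces the balanced one-positive/one-negative
    dataset construction used for single-site classifiers.
    """
    by_id = {h.id: h for h in hairpins}
    windows: list[PatternWindow] = []
    for hid, site in annotations:
        if hid not in by_id:
            raise KeyError(f"annotation references unknown hairpin {hid!r}")
        if site.arm != arm:
            continue
        da = build_duplex_alignment(by_id[hid], anchor=arm, mode=mode)
        windows.append(extract_cleavage_pattern(da, site, width))
        windows.append(extract_noncleavage_pattern(da, site, width, offset=offset))
    return windows


def render_tokens(tokens: Iterable[str], dialect: str = "-") -> str:
    """Join tokens into a string, rendering GAP with the dialect glyph."""
    if dialect not in ("-", "0"):
        raise ValueError("dialect must be '-' or '0'")
    return "".join(dialect if t == GAP else t for t in tokens)


def write_patterns_tsv(windows: Sequence[PatternWindow], path, dialect: str = "-") -> None:
    """Write windows as a TSV: hairpin_id, arm, width, center, label, rows."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "hairpin_id": [w.hairpin_id for w in windows],
            "arm": [w.arm for w in windows],
            "width": [w.width for w in windows],
            "center": [w.center_cut_after for w in windows],
            "label": [w.label for w in windows],
            "arm_tokens": [render_tokens(w.arm_tokens, dialect) for w in windows],
            "complement_tokens": [
                render_tokens(w.complement_tokens, dialect) for w in windows
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)
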
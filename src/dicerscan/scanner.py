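"""Whole-hairpin scanning, position-shift error and SNP-effect calls.

A trained classifier is slid along the stem in overlapping windows; every
candidate bond gets a decision score and the top-scoring positions are
reported.  Because mature-miRNA isoforms shift the true cut by a few
nucleotides, users are advised to consider the top three predictions, and
accuracy over a set of hairpins is summarised by the Position Shift Error
(PSE): predicted minus actual cut position, negative meaning upstream, and
averaged as the mean of absolute values.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

from .hairpin import Arm, CleavageSite, DuplexAlignment, Hairpin
from .model import CleavageSVMResults
from .patterns import enumerate_scan_windows


@dataclass(frozen=True)
class ScanResult:
    """Ranked candidate cuts of one hairpin arm.

    ``sites`` is a list of ``(cut_after, score)`` sorted by descending score,
    ties broken by ascending position; all retained scores exceed the applied
    threshold.
    """

    hairpin_id: str
    arm: Arm
    sites: tuple[tuple[int, float], ...]
    threshold: float
    top_k: int

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.sites)

    def rank_of(self, cut_after: int) -> Optional[int]:
        """1-based rank of a position in the list, or None if absent."""
        for r, (p, _) in enumerate(self.sites, start=1):
            if p == cut_after:
                return r
        return None


def scan_hairpin(
    results: CleavageSVMResults,
    da: DuplexAlignment,
    width: Optional[int] = None,
    threshold: Optional[float] = None,
    top_k: int = 3,
) -> ScanResult:
    """Score every full window along the stem and rank candidate cuts.

    ``threshold`` defaults to the model's decision cutoff; pass ``-math.inf``
    to keep all ``top_k`` candidates regardless of score.
    """
    width = width if width is not None else results.width
    if width != results.width:
        raise ValueError(
            f"scan width {width} does not match the model's training width "
            f"{results.width}"
        )
    thr = results.config.threshold if threshold is None else threshold
    windows = enumerate_scan_windows(da, width)
    scored: list[tuple[int, float]] = []
    if windows:
        scores = results.score_windows(windows)
        for w, s in zip(windows, scores):
            if w.center_cut_after is not None:
                scored.append((w.center_cut_after, float(s)))
    scored.sort(key=lambda ps: (-ps[1], ps[0]))
    kept = tuple((p, s) for p, s in scored if s > thr)[:top_k]
    return ScanResult(
        hairpin_id=da.hairpin_id, arm=da.anchor, sites=kept, threshold=thr,
        top_k=top_k,
    )


def position_shift_error(predicted: CleavageSite, actual: CleavageSite) -> int:
    """Signed shift, predicted − actual: −1 is one nt upstream, +1 downstream."""
    if predicted.arm != actual.arm:
        raise ValueError(
            f"cannot compare cuts on different arms ({predicted.arm} vs {actual.arm})"
        )
    return predicted.cut_after - actual.cut_after


def average_pse(values: Sequence[int]) -> float:
    """Mean of absolute shifts (−1 counts as 1, −2 as 2, ...)."""
    if not len(values):
        raise ValueError("average_pse needs at least one value")
    return float(np.mean(np.abs(np.asarray(values, dtype=float))))


@dataclass(frozen=True)
class PSEReport:
    """Per-rank position-shift-error summary over a set of hairpins.

    ``per_hairpin[hid][r-1]`` is the signed PSE of the rank-r prediction (or
    ``None`` when fewer than r sites were reported); ``average_abs[r-1]`` the
    mean absolute PSE at rank r; ``counts[r-1]`` a Counter of signed values.
    """

    per_hairpin: Mapping[str, tuple[Optional[int], ...]]
    average_abs: tuple[Optional[float], ...]
    counts: tuple[Counter, ...]
    max_rank: int

    @property
    def n_exact_within_top_k(self) -> int:
        """Hairpins whose annotated cut appears among the ranked predictions."""
        return sum(
            1 for shifts in self.per_hairpin.values() if 0 in shifts
        )


def pse_report(
    scans: Mapping[str, ScanResult],
    actual: Mapping[str, CleavageSite],
    max_rank: int = 3,
) -> PSEReport:
    """Assemble the per-rank PSE table for scanned hairpins with known cuts."""
    per: dict[str, tuple[Optional[int], ...]] = {}
    by_rank: list[list[int]] = [[] for _ in range(max_rank)]
    for hid, scan in scans.items():
        if hid not in actual:
            raise KeyError(f"no annotated cut for hairpin {hid!r}")
        site = actual[hid]
        shifts: list[Optional[int]] = []
        for r in range(1, max_rank + 1):
            if r <= len(scan.sites):
                pse = position_shift_error(
                    CleavageSite(scan.arm, scan.sites[r - 1][0]), site
                )
                shifts.append(pse)
                by_rank[r - 1].append(pse)
            else:
                shifts.append(None)
        per[hid] = tuple(shifts)
    avg = tuple(
        average_pse(vals) if vals else None for vals in by_rank
    )
    counts = tuple(Counter(vals) for vals in by_rank)
    return PSEReport(per_hairpin=per, average_abs=avg, counts=counts, max_rank=max_rank)


# ---------------------------------------------------------------------------
# SNP effect on the cleavage site
# ---------------------------------------------------------------------------

SNPEffectLabel = Literal["remain_same", "altered", "loss_of_site"]


@dataclass(frozen=True)
class SNPEffect:
    """Effect of a variant on the predicted cleavage-site ranking."""

    label: SNPEffectLabel
    ref_sites: tuple[tuple[int, float], ...]
    var_sites: tuple[tuple[int, float], ...]
    annotated_site: int


def classify_snp_effect(
    ref: ScanResult,
    var: ScanResult,
    annotated: Optional[int] = None,
    k: int = 3,
) -> SNPEffect:
    """Compare reference and variant top-k rankings around an annotated cut.

    * ``loss_of_site`` — the annotated cut disappears from the variant top-k;
    * ``remain_same`` — the top prediction is unchanged and the annotated
      cut keeps its rank;
    * ``altered`` — anything else (the site survives but the ranking moved).

    The rule is a convention chosen as the simplest one consistent with the
    observed behaviours; swap in another policy by post-processing the two
    ranked lists.
    """
    if not ref.sites or not var.sites:
        raise ValueError("both scans must report at least one site")
    ref_top = ref.sites[:k]
    var_top = var.sites[:k]
    if annotated is None:
        annotated = ref_top[0][0]
    var_positions = [p for p, _ in var_top]
    if annotated not in var_positions:
        label: SNPEffectLabel = "loss_of_site"
    else:
        ref_rank = next(
            (r for r, (p, _) in enumerate(ref_top, 1) if p == annotated), None
        )
        var_rank = var_positions.index(annotated) + 1
        if var_top[0][0] == ref_top[0][0] and ref_rank == var_rank:
            label = "remain_same"
        else:
            label = "altered"
    return SNPEffect(
        label=label,
        ref_sites=tuple(ref_top),
        var_sites=tuple(var_top),
        annotated_site=annotated,
    )


def apply_variant(
    h: Hairpin,
    position: int,
    ref_base: str,
    alt_base: str,
    dotbracket: Optional[str] = None,
) -> Hairpin:
    """Substitute one base of a hairpin (a SNP), checking the reference allele.

    The caller supplies the variant's secondary structure when it differs;
    by default the reference structure is retained.
    """
    from .hairpin import normalize_sequence

    ref_base = normalize_sequence(ref_base, record=h.id)
    alt_base = normalize_sequence(alt_base, record=h.id)
    if not 1 <= position <= len(h):
        raise ValueError(f"variant position {position} outside hairpin {h.id!r}")
    if h.base(position) != ref_base:
        raise ValueError(
            f"reference allele mismatch at {h.id}:{position}: hairpin has "
            f"{h.base(position)}, variant says {ref_base}"
        )
    seq = h.sequence[: position - 1] + alt_base + h.sequence[position:]
    return Hairpin(
        id=f"{h.id}_{position}{ref_base}>{alt_base}",
        sequence=seq,
        dotbracket=dotbracket if dotbracket is not None else h.dotbracket,
        mfe=None,
    )
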
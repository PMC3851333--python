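"""Seeded synthetic hairpin benchmark with a plantable cleavage signal.

The generator emulates the statistical situation the classifier faces on
real pre-miRNAs: a single stem-loop whose sequence/structure context around
the true Dicer cut is discriminable from the rest of the stem.  The signal
has two planted components, controlled jointly by ``signal_strength``:

* a position-specific base bias over the 14 columns around the cut
  (multinomial tilt towards a fixed preferred base per column), visible to
  sequence-only encodings; and
* an elevated probability of an arm bulge (unpaired arm nucleotide) at
  fixed offsets from the cut, visible only to structure-aware encodings.

At ``signal_strength = 0`` both components collapse to the background
distribution, giving a proper null.  Hairpins come in families (mutated
copies of an ancestral hairpin) so that family-grouped cross-validation has
real homology structure to guard against.  G:U wobble pairs are emitted at a
fixed fraction of paired columns to exercise non-canonical pairing paths.

The generator makes no attempt at thermodynamic realism or real miRNA base
statistics; it provides controlled, reproducible inputs for every pipeline
stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hairpin import (
    CleavageSite,
    Hairpin,
    PairMap,
    map_cleavage_between_arms,
    validate_single_loop,
)

#: Fixed preferred base per column of the 14-nt window around the cut
#: (columns cut-6 .. cut+7).  Fixed so the signal is shared across families.
PREFERRED_BASES = "GGCUAGCAUCGAUG"

#: Offsets (relative to the cut position) where the planted structural signal
#: elevates the arm-bulge probability.  At signal_strength = 0 these offsets
#: fall back to the background bulge rate, so positive and negative windows
#: are identically distributed (a proper null).
BULGE_SIGNAL_OFFSETS = (-5, 2, 5)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {"G": "U", "U": "G"}
_BASES = np.array(["A", "C", "G", "U"])

#: 2-nt 3' overhang of the miR:miR* duplex (fixed Dicer geometry).
OVERHANG = 2


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic benchmark.

    Defaults are the study conditions of the planted-signal recovery
    experiment: 500 hairpins in 50 families with the signal fully on.
    """

    n_hairpins: int = 500
    stem_length: tuple[int, int] = (22, 32)
    loop_length: tuple[int, int] = (4, 8)
    bulge_probability: float = 0.05
    signal_strength: float = 1.0
    n_families: int = 50
    seed: int = 0
    wobble_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_hairpins < 1 or self.n_families < 1:
            raise ValueError("n_hairpins and n_families must be positive")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if not 0.0 <= self.bulge_probability <= 1.0:
            raise ValueError("bulge_probability must lie in [0, 1]")
        lo, hi = self.stem_length
        # The positive window (cut-6..cut+7) and its paired negative
        # (cut-13..cut) must both fit inside the stem: cut in [14, L-7].
        if lo < 21 or hi < lo:
            raise ValueError(
                "infeasible geometry: stem_length must span at least 21 nt to "
                "hold a 14-nt window plus the shifted negative window"
            )
        if self.loop_length[0] < 3 or self.loop_length[1] < self.loop_length[0]:
            raise ValueError("loop_length range must be >= 3 and non-empty")


@dataclass(frozen=True)
class SyntheticRecord:
    hairpin: Hairpin
    cd5p: CleavageSite
    cd3p: CleavageSite
    family: str


@dataclass(frozen=True)
class _Ancestor:
    """Family-level blueprint: geometry, pairing pattern and base states."""

    stem_len: int
    cut: int
    loop: str
    paired: tuple[bool, ...]          # per 5p position 1..L
    bases: tuple[str, ...]            # per 5p position
    wobble: tuple[bool, ...]          # per 5p position (relevant when paired)
    insertions: tuple[tuple[int, str], ...]  # (emission index, base) 3p bulges


def _draw_base(rng: np.random.Generator, spec: SyntheticSpec, offset: Optional[int]) -> str:
    """Background-uniform base, tilted towards the window motif near the cut."""
    if offset is not None and -6 <= offset <= 7:
        mix = 0.45 * spec.signal_strength
        if rng.random() < mix:
            return PREFERRED_BASES[offset + 6]
    return str(rng.choice(_BASES))


def _draw_paired(rng: np.random.Generator, spec: SyntheticSpec, offset: Optional[int]) -> bool:
    """Pairing state of a 5p position; bulges are enriched at signal offsets."""
    background = spec.bulge_probability / 2.0
    p_bulge = background
    if offset in BULGE_SIGNAL_OFFSETS:
        p_bulge = background + (0.90 - background) * spec.signal_strength
    return rng.random() >= p_bulge


def _make_ancestor(spec: SyntheticSpec, family_index: int) -> _Ancestor:
    rng = np.random.default_rng([spec.seed % (2**31), 1, family_index])
    stem_len = int(rng.integers(spec.stem_length[0], spec.stem_length[1] + 1))
    loop_len = int(rng.integers(spec.loop_length[0], spec.loop_length[1] + 1))
    cut = int(rng.integers(14, stem_len - 7 + 1))
    paired, bases, wobble = [], [], []
    for k in range(1, stem_len + 1):
        off = k - cut
        paired.append(_draw_paired(rng, spec, off))
        bases.append(_draw_base(rng, spec, off))
        wobble.append(bool(rng.random() < spec.wobble_fraction))
    loop = "".join(rng.choice(_BASES, size=loop_len))
    n_paired = sum(paired)
    insertions = [
        (i, str(rng.choice(_BASES)))
        for i in range(1, n_paired)
        if rng.random() < spec.bulge_probability / 2.0
    ]
    return _Ancestor(
        stem_len=stem_len,
        cut=cut,
        loop=loop,
        paired=tuple(paired),
        bases=tuple(bases),
        wobble=tuple(wobble),
        insertions=tuple(insertions),
    )


def _partner_base(base: str, use_wobble: bool) -> str:
    if use_wobble and base in _WOBBLE:
        return _WOBBLE[base]
    return _COMPLEMENT[base]


def _assemble(anc: _Ancestor, bases: Sequence[str], wobble: Sequence[bool]) -> tuple[str, str]:
    seq5, db5 = [], []
    for k in range(1, anc.stem_len + 1):
        seq5.append(bases[k - 1])
        db5.append("(" if anc.paired[k - 1] else ".")
    seq3, db3 = [], []
    ins = dict(anc.insertions)
    emission = 0
    for k in range(anc.stem_len, 0, -1):
        if not anc.paired[k - 1]:
            continue
        if emission in ins:
            seq3.append(ins[emission])
            db3.append(".")
        emission += 1
        seq3.append(_partner_base(bases[k - 1], wobble[k - 1]))
        db3.append(")")
    sequence = "".join(seq5) + anc.loop + "".join(seq3)
    dotbracket = "".join(db5) + "." * len(anc.loop) + "".join(db3)
    return sequence, dotbracket


def make_hairpin(
    spec: SyntheticSpec, index: int
) -> SyntheticRecord:
    """Generate hairpin ``index`` of the benchmark (deterministic per seed).

    Family membership is ``index mod n_families``; each member is the
    family's ancestral hairpin with a few positions re-drawn from the same
    position-specific distribution (so homologs stay similar while the
    planted signal is preserved in expectation).
    """
    if not 0 <= index < spec.n_hairpins:
        raise ValueError(f"index must lie in 0..{spec.n_hairpins - 1}")
    fam_idx = index % spec.n_families
    anc = _make_ancestor(spec, fam_idx)
    rng = np.random.default_rng([spec.seed % (2**31), 2, index])
    bases = list(anc.bases)
    wobble = list(anc.wobble)
    n_mut = int(rng.integers(1, 4))
    for pos in rng.choice(anc.stem_len, size=n_mut, replace=False):
        off = int(pos) + 1 - anc.cut
        bases[pos] = _draw_base(rng, spec, off)
        wobble[pos] = bool(rng.random() < spec.wobble_fraction)
    sequence, dotbracket = _assemble(anc, bases, wobble)
    h = Hairpin(id=f"syn-{index:04d}", sequence=sequence, dotbracket=dotbracket)
    pm = h.pair_map()
    assert validate_single_loop(pm).is_single_loop
    cd5p = CleavageSite("5p", anc.cut)
    # In the rare event the overhang-offset position is bulged, fall back to
    # the lenient nearest-paired mapping (quietly; the caller sees only cd3p).
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        cd3p = map_cleavage_between_arms(pm, cd5p, strict=False)
    return SyntheticRecord(
        hairpin=h, cd5p=cd5p, cd3p=cd3p, family=f"fam{fam_idx:03d}"
    )


class SyntheticDataset:
    """A generated benchmark: hairpins, cut annotations and the family map."""

    def __init__(self, spec: SyntheticSpec, records: Sequence[SyntheticRecord]):
        self.spec = spec
        self.records = list(records)

    @property
    def hairpins(self) -> list[Hairpin]:
        return [r.hairpin for r in self.records]

    @property
    def annotations(self) -> list[tuple[str, CleavageSite]]:
        out = []
        for r in self.records:
            out.append((r.hairpin.id, r.cd5p))
            out.append((r.hairpin.id, r.cd3p))
        return out

    @property
    def family_map(self) -> dict[str, str]:
        return {r.hairpin.id: r.family for r in self.records}

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"hairpin_id": hid, "arm": s.arm, "cut_after": s.cut_after}
                for hid, s in self.annotations
            ]
        )

    def family_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"hairpin_id": k, "family": v} for k, v in self.family_map.items()]
        )

    def write(self, outdir, provenance_header: Optional[str] = None) -> dict:
        """Emit hairpins.fa, structures.db, annotations.tsv, families.tsv."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "hairpins.fa",
            "structures": outdir / "structures.db",
            "annotations": outdir / "annotations.tsv",
            "families": outdir / "families.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for h in self.hairpins:
                fh.write(f">{h.id}\n{h.sequence}\n")
        with open(paths["structures"], "w") as fh:
            for h in self.hairpins:
                fh.write(f">{h.id}\n{h.sequence}\n{h.dotbracket}\n")
        header = provenance_header or (
            f"# dicerscan synthetic dataset | seed={self.spec.seed} "
            f"n={self.spec.n_hairpins} families={self.spec.n_families} "
            f"signal={self.spec.signal_strength}\n"
        )
        for name, frame in (
            ("annotations", self.annotation_frame()),
            ("families", self.family_frame()),
        ):
            with open(paths[name], "w") as fh:
                fh.write(header)
                frame.to_csv(fh, sep="\t", index=False)
        return paths


def make_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full benchmark described by ``spec``."""
    return SyntheticDataset(
        spec, [make_hairpin(spec, i) for i in range(spec.n_hairpins)]
    )
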
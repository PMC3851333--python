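"""Pre-miRNA hairpins: parsing, pairing topology, duplex alignment, arm mapping.

A pre-miRNA hairpin is a single stem-loop: a 5p arm and a 3p arm base-paired
into a stem, closed by a terminal loop.  Dicer cuts both arms of the stem,
leaving the characteristic 2-nt 3' overhang on the miR:miR* duplex; that
geometric constraint is what :func:`map_cleavage_between_arms` encodes.

Coordinates are 1-based throughout and a cleavage site denotes the bond
*after* its ``cut_after`` position (i.e. between ``cut_after`` and
``cut_after + 1``).
"""

from __future__ import annotations

import re
import subprocess
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

#: Internal token for an absent nucleotide (bulge/loop partner).  Rendered as
#: "-" or "0" depending on the output dialect; both glyphs mean the same thing.
GAP = "-"

#: Glyphs used by the two structure-rendering dialects for a missing base.
DIALECT_GLYPHS = {"-": "-", "0": "0"}

Arm = Literal["5p", "3p"]
ARMS = ("5p", "3p")

_RNA_ALPHABET = frozenset("ACGU")


class HairpinParseError(ValueError):
    """Raised when a sequence/structure record cannot be parsed."""


def normalize_sequence(seq: str, *, record: str = "?") -> str:
    """Uppercase, DNA->RNA (T->U) and validate against the {A,C,G,U} alphabet."""
    norm = seq.strip().upper().replace("T", "U")
    bad = set(norm) - _RNA_ALPHABET
    if bad:
        raise HairpinParseError(
            f"record {record!r}: non-ACGU residue(s) {sorted(bad)} after normalization"
        )
    return norm


@dataclass(frozen=True)
class Hairpin:
    """A hairpin sequence with its dot-bracket structure and optional MFE.

    Parameters
    ----------
    id : str
        Record identifier.
    sequence : str
        RNA sequence over {A,C,G,U}; positions are 1-based.
    dotbracket : str
        Vienna dot-bracket string of the same length.  Only one bracket
        family is accepted (nested, pseudoknot-free structures).
    mfe : float, optional
        Minimum free energy of the structure in kcal/mol.
    """

    id: str
    sequence: str
    dotbracket: str
    mfe: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise HairpinParseError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.dotbracket)}"
            )
        bad = set(self.dotbracket) - set("().")
        if bad:
            raise HairpinParseError(
                f"record {self.id!r}: unsupported structure glyph(s) {sorted(bad)} "
                "(only nested '()' structures are accepted)"
            )
        object.__setattr__(
            self, "sequence", normalize_sequence(self.sequence, record=self.id)
        )
        # Raises on unbalanced brackets.
        PairMap.from_dotbracket(self.dotbracket, record=self.id)

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Nucleotide at a 1-based position."""
        return self.sequence[pos - 1]

    def pair_map(self) -> "PairMap":
        return PairMap.from_dotbracket(self.dotbracket, record=self.id)


@dataclass(frozen=True)
class CleavageSite:
    """A Dicer cut: the bond after ``cut_after`` on the given arm."""

    arm: Arm
    cut_after: int

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.cut_after < 1:
            raise ValueError("cut_after must be >= 1")


class PairMap:
    """Base-pair partner table derived from a dot-bracket string.

    ``partner(i)`` gives the 1-based partner of position ``i`` or ``None``
    when unpaired.  The map is symmetric and nested (pseudoknot-free) by
    construction.
    """

    __slots__ = ("_partner",)

    def __init__(self, partner: Sequence[Optional[int]]):
        self._partner = tuple(partner)
        for i, j in enumerate(self._partner, start=1):
            if j is not None and (j == i or self._partner[j - 1] != i):
                raise ValueError("partner table is not a symmetric pairing")

    @classmethod
    def from_dotbracket(cls, db: str, *, record: str = "?") -> "PairMap":
        partner: list[Optional[int]] = [None] * len(db)
        stack: list[int] = []
        for i, ch in enumerate(db, start=1):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise HairpinParseError(
                        f"record {record!r}: unbalanced ')' at position {i}"
                    )
                j = stack.pop()
                partner[i - 1] = j
                partner[j - 1] = i
            elif ch != ".":
                raise HairpinParseError(
                    f"record {record!r}: invalid structure character {ch!r}"
                )
        if stack:
            raise HairpinParseError(
                f"record {record!r}: unbalanced '(' at position {stack[-1]}"
            )
        return cls(partner)

    def __len__(self) -> int:
        return len(self._partner)

    def partner(self, i: int) -> Optional[int]:
        if not 1 <= i <= len(self._partner):
            raise IndexError(f"position {i} outside 1..{len(self._partner)}")
        return self._partner[i - 1]

    def paired_positions(self) -> list[int]:
        return [i for i, j in enumerate(self._partner, start=1) if j is not None]

    def to_dotbracket(self) -> str:
        out = []
        for i, j in enumerate(self._partner, start=1):
            out.append("." if j is None else ("(" if j > i else ")"))
        return "".join(out)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PairMap) and self._partner == other._partner

    def __hash__(self) -> int:
        return hash(self._partner)


# ---------------------------------------------------------------------------
# Vienna / FASTA / TSV input
# ---------------------------------------------------------------------------

_ENERGY_RE = re.compile(r"\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")
_STRUCT_CHARS = re.compile(r"^[().]+")


def parse_vienna(text: str) -> list[Hairpin]:
    """Parse multi-record Vienna output (header, sequence, structure lines).

    Each record is an optional ``>`` header, a sequence line and a structure
    line, the latter optionally suffixed by the folding energy ``(-NN.NN)``.
    Unnamed records are assigned ``record<N>`` ids.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    hairpins: list[Hairpin] = []
    i = 0
    n_rec = 0
    while i < len(lines):
        n_rec += 1
        rid = f"record{n_rec}"
        if lines[i].lstrip().startswith(">"):
            rid = lines[i].lstrip()[1:].split()[0] or rid
            i += 1
        if i + 1 >= len(lines):
            raise HairpinParseError(
                f"record {rid!r}: truncated record near line {i + 1}"
            )
        seq_line = lines[i].strip()
        struct_line = lines[i + 1].strip()
        i += 2
        mfe = None
        m = _ENERGY_RE.search(struct_line)
        if m and _STRUCT_CHARS.match(struct_line):
            mfe = float(m.group(1))
            struct_line = struct_line[: m.start()].strip()
        hairpins.append(Hairpin(rid, seq_line, struct_line, mfe))
    return hairpins


def read_vienna(path) -> list[Hairpin]:
    with open(path) as fh:
        return parse_vienna(fh.read())


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{id: normalized RNA sequence}``."""
    return {
        rec.id: normalize_sequence(str(rec.seq), record=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    }


def read_annotations(path) -> list[tuple[str, CleavageSite]]:
    """Read a cleavage-annotation TSV with columns hairpin_id, arm, cut_after."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"hairpin_id", "arm", "cut_after"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation TSV needs columns {sorted(required)}")
    return [
        (str(row.hairpin_id), CleavageSite(str(row.arm), int(row.cut_after)))
        for row in df.itertuples()
    ]


def read_family_map(path) -> dict[str, str]:
    """Read a family-map TSV (hairpin_id, family); absent ids form singletons."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"hairpin_id", "family"}.issubset(df.columns):
        raise ValueError(f"{path}: family TSV needs columns hairpin_id, family")
    fam: dict[str, str] = {}
    for row in df.itertuples():
        hid, f = str(row.hairpin_id), str(row.family)
        if hid in fam and fam[hid] != f:
            raise ValueError(f"{path}: hairpin {hid!r} mapped to two families")
        fam[hid] = f
    return fam


def fold_sequences(
    seqs: Mapping[str, str], executable: str = "RNAfold"
) -> list[Hairpin]:
    """Optional convenience: fold sequences by shelling out to an installed
    thermodynamic folder (RNAfold-compatible stdin/stdout).  Structures are
    normally supplied as input files; this is off the main path."""
    fasta = "".join(f">{k}\n{v}\n" for k, v in seqs.items())
    proc = subprocess.run(
        [executable, "--noPS"],
        input=fasta,
        capture_output=True,
        text=True,
        check=True,
    )
    return parse_vienna(proc.stdout)


# ---------------------------------------------------------------------------
# Topology validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LoopReport:
    """Outcome of the single-stem-loop check."""

    is_single_loop: bool
    n_loops: int


def validate_single_loop(pm: PairMap) -> LoopReport:
    """Accept only single stem-loops: exactly one hairpin loop, no multiloop.

    Hairpins whose predicted structure branches into several loops are the
    ones excluded from whole-hairpin assessment (callers decide whether to
    reject).
    """
    db = pm.to_dotbracket()
    n_loops = len(re.findall(r"\(\.*\)", db))
    return LoopReport(is_single_loop=(n_loops == 1), n_loops=n_loops)


# ---------------------------------------------------------------------------
# Duplex alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentColumn:
    """One column of the antiparallel stem alignment.

    ``token5``/``token3`` are bases or :data:`GAP`; ``pos5``/``pos3`` are the
    source hairpin positions (``None`` under a gap).
    """

    token5: str
    token3: str
    pos5: Optional[int]
    pos3: Optional[int]


AlignmentMode = Literal["arm-anchored", "full-alignment"]


class DuplexAlignment:
    """Antiparallel alignment of the two stem arms.

    The 5p row is read 5'->3' and the 3p row 3'->5' (columns follow the
    anchoring arm in its 5'->3' order), so the two bases of a paired column
    are Watson-Crick (or wobble) partners.  In ``arm-anchored`` mode there is
    exactly one column per anchoring-arm stem nucleotide; ``full-alignment``
    mode additionally inserts gap-on-anchor columns for opposite-arm bulges,
    reproducing the "-" placeholders of aligned structure renderings.
    """

    def __init__(
        self,
        hairpin_id: str,
        anchor: Arm,
        mode: AlignmentMode,
        columns: Sequence[AlignmentColumn],
    ):
        self.hairpin_id = hairpin_id
        self.anchor = anchor
        self.mode = mode
        self.columns = tuple(columns)
        self._pos_to_col = {
            (c.pos5 if anchor == "5p" else c.pos3): i
            for i, c in enumerate(self.columns)
            if (c.pos5 if anchor == "5p" else c.pos3) is not None
        }

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def arm_tokens(self) -> tuple[str, ...]:
        """Anchoring-arm row, one token per column."""
        if self.anchor == "5p":
            return tuple(c.token5 for c in self.columns)
        return tuple(c.token3 for c in self.columns)

    @property
    def complement_tokens(self) -> tuple[str, ...]:
        """Opposite-arm row (partner base or GAP), one token per column."""
        if self.anchor == "5p":
            return tuple(c.token3 for c in self.columns)
        return tuple(c.token5 for c in self.columns)

    def arm_position(self, col: int) -> Optional[int]:
        c = self.columns[col]
        return c.pos5 if self.anchor == "5p" else c.pos3

    def column_index(self, cut_after: int) -> int:
        """Column index of an anchoring-arm hairpin position."""
        try:
            return self._pos_to_col[cut_after]
        except KeyError:
            raise ValueError(
                f"position {cut_after} is not on the {self.anchor} stem of "
                f"{self.hairpin_id!r}"
            ) from None


def _arm_spans(pm: PairMap) -> tuple[tuple[int, int], tuple[int, int]]:
    opens = [i for i in range(1, len(pm) + 1) if (pm.partner(i) or 0) > i]
    closes = [i for i in range(1, len(pm) + 1) if pm.partner(i) and pm.partner(i) < i]
    if not opens:
        raise ValueError("empty stem: structure has no base pairs")
    return (opens[0], opens[-1]), (closes[0], closes[-1])


def build_duplex_alignment(
    h: Hairpin,
    pm: Optional[PairMap] = None,
    anchor: Arm = "5p",
    mode: AlignmentMode = "arm-anchored",
) -> DuplexAlignment:
    """Build the stem alignment anchored on one arm.

    The anchoring arm's stem span runs from its outermost to its innermost
    paired nucleotide; interior unpaired anchor nucleotides appear as columns
    with a GAP partner.  Dangling ends and the terminal loop are excluded.
    """
    if anchor not in ARMS:
        raise ValueError(f"anchor must be one of {ARMS}")
    if mode not in ("arm-anchored", "full-alignment"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    pm = pm if pm is not None else h.pair_map()
    report = validate_single_loop(pm)
    if not report.is_single_loop:
        raise ValueError(
            f"hairpin {h.id!r} is not a single stem-loop "
            f"({report.n_loops} hairpin loops)"
        )
    span5, span3 = _arm_spans(pm)
    anchor_span = span5 if anchor == "5p" else span3
    opp_span = span3 if anchor == "5p" else span5

    columns: list[AlignmentColumn] = []

    def col(anchor_pos: Optional[int], opp_pos: Optional[int]) -> AlignmentColumn:
        a_tok = h.base(anchor_pos) if anchor_pos else GAP
        o_tok = h.base(opp_pos) if opp_pos else GAP
        if anchor == "5p":
            return AlignmentColumn(a_tok, o_tok, anchor_pos, opp_pos)
        return AlignmentColumn(o_tok, a_tok, opp_pos, anchor_pos)

    # Opposite positions decrease as anchor positions increase (antiparallel).
    prev_opp = opp_span[1] + 1
    for p in range(anchor_span[0], anchor_span[1] + 1):
        q = pm.partner(p)
        if q is not None:
            if mode == "full-alignment":
                for r in range(prev_opp - 1, q, -1):
                    columns.append(col(None, r))
            prev_opp = q
            columns.append(col(p, q))
        else:
            columns.append(col(p, None))
    return DuplexAlignment(h.id, anchor, mode, columns)


# ---------------------------------------------------------------------------
# 5p <-> 3p cleavage-site mapping (2-nt 3' overhang geometry)
# ---------------------------------------------------------------------------


class UnpairedOverhangError(ValueError):
    """The position 2 nt inside the cut, needed for arm mapping, is unpaired."""


def _nearest_paired(pm: PairMap, pos: int) -> int:
    for delta in range(1, len(pm)):
        for cand in (pos - delta, pos + delta):
            if 1 <= cand <= len(pm) and pm.partner(cand) is not None:
                return cand
    raise UnpairedOverhangError("no paired position in structure")


def map_cleavage_between_arms(
    pm: PairMap, site: CleavageSite, strict: bool = True
) -> CleavageSite:
    """Map a Dicer cut from one arm to the other via the 2-nt 3' overhang.

    The two cuts of a Dicer event leave each strand's 3' end protruding 2 nt
    beyond the duplex.  For a 5p cut after position ``i`` the 5' nucleotide of
    the 3p product is ``partner(i - 2)``, so the 3p cut falls after
    ``partner(i - 2) - 1``; the 3p->5p direction inverts this
    (``partner(j + 1) + 2``).  The round trip is the identity whenever the
    probed positions are paired.

    When the probed position is unpaired (bulged), strict mode raises
    :class:`UnpairedOverhangError`; lenient mode substitutes the nearest
    paired neighbour and emits a warning.
    """
    probe = site.cut_after - 2 if site.arm == "5p" else site.cut_after + 1
    if not 1 <= probe <= len(pm):
        raise ValueError(f"overhang-offset position {probe} outside the hairpin")
    if pm.partner(probe) is None:
        if strict:
            raise UnpairedOverhangError(
                f"unpaired at overhang offset (position {probe})"
            )
        fallback = _nearest_paired(pm, probe)
        warnings.warn(
            f"overhang-offset position {probe} unpaired; using nearest paired "
            f"neighbour {fallback}",
            stacklevel=2,
        )
        probe = fallback
    partner = pm.partner(probe)
    assert partner is not None
    if site.arm == "5p":
        return CleavageSite("3p", partner - 1)
    return CleavageSite("5p", partner + 2)
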
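"""Feature encodings for pattern windows.

Four families of encodings are provided, mirroring the usual progression for
site classifiers on fixed windows:

``comp1`` / ``comp2`` / ``comp3``
    Overlapping k-mer composition (k = 1, 2, 3) over {A,C,G,U}: 4-, 16- and
    64-dimensional vectors.  By default compositions are relative
    frequencies; raw counts are available behind a flag.  Any k-mer touching
    a gap token is excluded from numerator and denominator.
``binary_seq``
    Position-specific one-hot of the arm row only: A=[1,0,0,0], C=[0,1,0,0],
    G=[0,0,1,0], U=[0,0,0,1]; a gap contributes [0,0,0,0].  4w dims (56 for
    w=14).
``binary_struct``
    Arm-row one-hot followed by complement-row one-hot; an unpaired position
    contributes an all-zero block on the complement row.  8w dims (112 for
    w=14).
``extbinary_struct``
    Both rows with 5-state one-hot in which the loop/bulge gap is its own
    class [0,0,0,0,1], so exactly one bit fires per token.  10w dims (140
    for w=14).

The k-mer ordering is lexicographic over (A, C, G, U) and fixed; feature
matrices are bit-reproducible given the same windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np

from .hairpin import GAP
from .patterns import PatternWindow

BASES = ("A", "C", "G", "U")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SCHEMES = ("comp1", "comp2", "comp3", "binary_seq", "binary_struct", "extbinary_struct")
_COMP_K = {"comp1": 1, "comp2": 2, "comp3": 3}


def kmer_order(k: int) -> list[str]:
    """Lexicographic k-mer order over (A, C, G, U)."""
    return ["".join(p) for p in product(BASES, repeat=k)]


def scheme_dimension(scheme: str, width: int = 14) -> int:
    """Feature-vector dimension of a scheme at a given window width."""
    if scheme in _COMP_K:
        return 4 ** _COMP_K[scheme]
    if scheme == "binary_seq":
        return 4 * width
    if scheme == "binary_struct":
        return 8 * width
    if scheme == "extbinary_struct":
        return 10 * width
    raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


@dataclass(frozen=True)
class FeatureVector:
    scheme: str
    values: np.ndarray
    degenerate: bool = False

    @property
    def dimension(self) -> int:
        return self.values.shape[0]


def kmer_composition(
    win: PatternWindow,
    k: int,
    use_structure_rows: bool = False,
    frequencies: bool = True,
) -> FeatureVector:
    """Overlapping k-mer composition of the window.

    With ``use_structure_rows`` the complement row is counted as well (k-mers
    never span the two rows).  An all-gap window yields a zero vector with
    the ``degenerate`` flag set.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    order = {m: i for i, m in enumerate(kmer_order(k))}
    counts = np.zeros(4**k, dtype=float)
    rows = [win.arm_tokens]
    if use_structure_rows:
        rows.append(win.complement_tokens)
    total = 0
    for row in rows:
        for i in range(len(row) - k + 1):
            mer = row[i : i + k]
            if GAP in mer:
                continue
            counts[order["".join(mer)]] += 1
            total += 1
    if total == 0:
        return FeatureVector(f"comp{k}", counts, degenerate=True)
    return FeatureVector(f"comp{k}", counts / total if frequencies else counts)


def _one_hot_row(tokens: Sequence[str], n_states: int) -> np.ndarray:
    blocks = np.zeros((len(tokens), n_states), dtype=float)
    for i, t in enumerate(tokens):
        if t in _BASE_INDEX:
            blocks[i, _BASE_INDEX[t]] = 1.0
        elif n_states == 5:
            blocks[i, 4] = 1.0  # explicit loop/bulge class
        # 4-state encoding: gap stays all-zero
    return blocks.ravel()


def binary_sequence(win: PatternWindow) -> FeatureVector:
    """4-bit one-hot of the arm row only (gap -> zero block)."""
    return FeatureVector("binary_seq", _one_hot_row(win.arm_tokens, 4))


def binary_structure(win: PatternWindow) -> FeatureVector:
    """4-bit one-hot of the arm row then the complement row; an unpaired
    position leaves its complement block all-zero (no base pairing there)."""
    values = np.concatenate(
        [_one_hot_row(win.arm_tokens, 4), _one_hot_row(win.complement_tokens, 4)]
    )
    return FeatureVector("binary_struct", values)


def extended_binary_structure(win: PatternWindow) -> FeatureVector:
    """5-bit one-hot of both rows, with loop/bulge as its own fifth class."""
    values = np.concatenate(
        [_one_hot_row(win.arm_tokens, 5), _one_hot_row(win.complement_tokens, 5)]
    )
    return FeatureVector("extbinary_struct", values)


def encode(
    win: PatternWindow,
    scheme: str,
    use_structure_rows: bool = False,
    frequencies: bool = True,
) -> FeatureVector:
    """Encode one window under a named scheme."""
    if scheme in _COMP_K:
        return kmer_composition(
            win, _COMP_K[scheme], use_structure_rows=use_structure_rows,
            frequencies=frequencies,
        )
    if scheme == "binary_seq":
        return binary_sequence(win)
    if scheme == "binary_struct":
        return binary_structure(win)
    if scheme == "extbinary_struct":
        return extended_binary_structure(win)
    raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


_LABEL_CODE = {"cleavage": 1, "noncleavage": 0}


def feature_matrix(
    windows: Sequence[PatternWindow],
    scheme: str,
    use_structure_rows: bool = False,
    frequencies: bool = True,
) -> tuple[np.ndarray, Optional[np.ndarray], list[str]]:
    """Stack windows into ``(X, y, ids)``.

    ``y`` is 1 for cleavage and 0 for non-cleavage, or ``None`` when any
    window is unlabeled; ``ids`` are the source hairpin ids row by row.
    """
    if not windows:
        raise ValueError("no windows to encode")
    X = np.vstack(
        [
            encode(w, scheme, use_structure_rows=use_structure_rows,
                   frequencies=frequencies).values
            for w in windows
        ]
    )
    ids = [w.hairpin_id for w in windows]
    if any(w.label == "unlabeled" for w in windows):
        return X, None, ids
    y = np.array([_LABEL_CODE[w.label] for w in windows], dtype=int)
    return X, y, ids


def write_dense_tsv(X: np.ndarray, y: Optional[np.ndarray], ids: Sequence[str], path) -> None:
    """Dense TSV: hairpin_id, label, f0..f{d-1}."""
    import pandas as pd

    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df.insert(0, "label", y if y is not None else -1)
    df.insert(0, "hairpin_id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def write_svmlight(X: np.ndarray, y: Optional[np.ndarray], path) -> None:
    """Sparse ``label index:value`` format of classic SVM tools (1-based)."""
    from sklearn.datasets import dump_svmlight_file

    labels = y if y is not None else np.full(X.shape[0], -1)
    dump_svmlight_file(X, labels, str(path), zero_based=False)
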
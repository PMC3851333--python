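import pytest

from dicerscan import (
    Hairpin,
    SyntheticSpec,
    build_duplex_alignment,
    make_dataset,
)


@pytest.fixture(scope="session")
def perfect_stem():
    """Length-26 hairpin, pairs i<->27-i for i=1..10, 6-nt loop."""
    return Hairpin("stem26", "G" * 10 + "AAAAAA" + "C" * 10,
                   "(" * 10 + "." * 6 + ")" * 10)


@pytest.fixture(scope="session")
def bulged_hairpin():
    """Pairs 1-12, 2-11, 4-10, 5-9; position 3 is a 5p bulge."""
    return Hairpin("bulged", "GGAGGAAACCCC", "((.((...))))")


@pytest.fixture(scope="session")
def long_stem():
    """A 30-column perfect stem (for scan-window counting)."""
    seq = "GCAU" * 7 + "GC" + "AAAA" + ("GC" + "AUGC" * 7)[::-1].translate(
        str.maketrans("AUGC", "UACG")
    )
    # simpler: complement built explicitly below
    left = "GCAU" * 7 + "GC"
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    right = "".join(comp[b] for b in reversed(left))
    return Hairpin("stem30", left + "AAAA" + right, "(" * 30 + "." * 4 + ")" * 30)


@pytest.fixture(scope="session")
def small_signal_dataset():
    """120 hairpins, 12 families, full planted signal."""
    return make_dataset(
        SyntheticSpec(n_hairpins=120, n_families=12, signal_strength=1.0, seed=7)
    )


@pytest.fixture(scope="session")
def aligned(perfect_stem):
    return build_duplex_alignment(perfect_stem)
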
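import numpy as np
import pytest

from scnpair.align import ScoringScheme
from scnpair.records import ProteinRecord


@pytest.fixture(scope="session")
def blosum() -> ScoringScheme:
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def toy_scheme() -> ScoringScheme:
    """3-letter alphabet, match +3 / mismatch -1, gap open 4 extend 1."""
    scores = np.array([[3, -1, -1], [-1, 3, -1], [-1, -1, 3]], dtype=float)
    return ScoringScheme.from_array("ABC", scores, gap_open=4, gap_extend=1, name="toy")


def random_toy_pair(rng: np.random.Generator, max_len: int = 6) -> tuple[ProteinRecord, ProteinRecord]:
    """Random sequence pair over a 3-letter sub-alphabet of the amino acids."""
    alpha = "ACD"
    n1 = int(rng.integers(1, max_len + 1))
    n2 = int(rng.integers(1, max_len + 1))
    a = "".join(alpha[i] for i in rng.integers(0, 3, size=n1))
    b = "".join(alpha[i] for i in rng.integers(0, 3, size=n2))
    return ProteinRecord("a", a), ProteinRecord("b", b)


def random_toy_scheme(rng: np.random.Generator) -> ScoringScheme:
    """Random symmetric integer scores over ACD with random valid gap costs."""
    m = rng.integers(-4, 6, size=(3, 3))
    m = np.triu(m) + np.triu(m, 1).T
    ge = int(rng.integers(0, 3))
    go = ge + int(rng.integers(0, 5))
    return ScoringScheme.from_array("ACD", m.astype(float), gap_open=go, gap_extend=ge)


def enumerate_global_alignments(a: str, b: str):
    """Every gapped row pair aligning a and b (no gap-gap columns)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_global_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_global_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_global_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def affine_alignment_score(row_a: str, row_b: str, scheme: ScoringScheme) -> float:
    """Column-wise affine-gap score of one explicit alignment (test oracle)."""
    total = 0.0
    prev = None
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            total += scheme.score(x, y)
            state = "m"
        else:
            state = "gx" if y == "-" else "gy"
            total -= scheme.gap_extend if state == prev else scheme.gap_open
        prev = state
    return total


def brute_force_best_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Exhaustive-enumeration optimum global score (independent of Gotoh)."""
    return max(
        affine_alignment_score(ra, rb, scheme)
        for ra, rb in enumerate_global_alignments(a, b)
    )
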
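"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations used only to
check the package's optimized paths: a position-by-position IUPAC primer
scanner, a union-of-cuts digestion, and an affine-gap semi-global
alignment DP that maximizes matches among co-optimal alignments.
"""

from __future__ import annotations

import random

import pytest

from synprop import amplicon as amp
from synprop import thermo as th

# --------------------------------------------------------------------------
# thermo fixtures


@pytest.fixture(scope="session")
def registry():
    return th.registry()


@pytest.fixture(scope="session")
def digester():
    """Reference digester conditions without H2 set."""
    return th.digester_conditions()


# --------------------------------------------------------------------------
# amplicon oracles

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}

COMPLEMENT = dict(zip("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"))


def naive_revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def naive_primer_scan(template: str, primer: str, max_mismatch: int):
    """All-positions scan on both strands with a strict 3'-anchor."""
    hits = []
    k = len(primer)
    for strand, seq in (("+", template), ("-", naive_revcomp(template))):
        for i in range(len(seq) - k + 1):
            if not (IUPAC[primer[-1]] & IUPAC[seq[i + k - 1]]):
                continue
            mm = sum(
                1 for j in range(k - 1) if not (IUPAC[primer[j]] & IUPAC[seq[i + j]])
            )
            if mm <= max_mismatch:
                pos = i if strand == "+" else len(template) - i - k
                hits.append((pos, strand, mm))
    return sorted(hits)


def naive_digest(sequence: str, enzymes) -> list[int]:
    """Union-of-cuts digestion by direct window comparison."""
    cuts = set()
    for enz in enzymes:
        k = len(enz.recognition)
        for i in range(len(sequence) - k + 1):
            window = sequence[i : i + k]
            if all(IUPAC[r] & IUPAC[c] for r, c in zip(enz.recognition, window)):
                pos = i + enz.cut_offset
                if 0 < pos < len(sequence):
                    cuts.add(pos)
    bounds = [0, *sorted(cuts), len(sequence)]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


# --------------------------------------------------------------------------
# alignment oracle

NEG = float("-inf")


def gotoh_semiglobal(a: str, b: str, match=2, mismatch=-1, open_=-4, extend=-1):
    """Affine-gap alignment with free terminal gaps in both sequences.

    Returns (score, matches, columns, span_a, span_b) of an optimal
    alignment, maximizing matches (then minimizing columns) among
    co-optimal alignments.  Cells carry (score, matches, -columns,
    start_a, start_b); the alignment may start fresh at any cell (free
    leading gaps) and end at any aligned pair (free trailing gaps).
    Quadratic time and memory; meant for short sequences only, and only
    in regimes where the optimal alignment is unambiguous.
    """
    n, m = len(a), len(b)

    def better(x, y):
        if x is None:
            return y
        if y is None:
            return x
        return x if x[:3] >= y[:3] else y

    def shift(cell, dscore):
        return (cell[0] + dscore, cell[1], cell[2] - 1, cell[3], cell[4])

    # M: ends with a[i-1] aligned to b[j-1]; X: interior gap consuming a;
    # Y: interior gap consuming b.
    M = [[None] * (m + 1) for _ in range(n + 1)]
    X = [[None] * (m + 1) for _ in range(n + 1)]
    Y = [[None] * (m + 1) for _ in range(n + 1)]
    best = None
    where = None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = better(
                better(M[i - 1][j - 1], X[i - 1][j - 1]), Y[i - 1][j - 1]
            )
            prev = better(prev, (0, 0, 0, i - 1, j - 1))  # free leading gaps
            hit = 1 if a[i - 1] == b[j - 1] else 0
            M[i][j] = (
                prev[0] + (match if hit else mismatch),
                prev[1] + hit,
                prev[2] - 1,
                prev[3],
                prev[4],
            )
            for src, d in ((M[i - 1][j], open_), (X[i - 1][j], extend), (Y[i - 1][j], open_)):
                if src is not None:
                    X[i][j] = better(X[i][j], shift(src, d))
            for src, d in ((M[i][j - 1], open_), (Y[i][j - 1], extend), (X[i][j - 1], open_)):
                if src is not None:
                    Y[i][j] = better(Y[i][j], shift(src, d))
            if best is None or M[i][j][:3] > best[:3]:
                best, where = M[i][j], (i, j)  # free trailing gaps
    if best is None:
        return 0.0, 0, 0, 0, 0
    score, matches, negcols, si, sj = best
    ei, ej = where
    return float(score), matches, -negcols, ei - si, ej - sj


def oracle_identity(a: str, b: str):
    """Percent identity/coverage per the package's counting rules."""
    _, matches, columns, span_a, span_b = gotoh_semiglobal(a, b)
    if columns == 0:
        return 0.0, 0.0, 0.0
    return (
        100.0 * matches / columns,
        100.0 * span_a / len(a),
        100.0 * span_b / len(b),
    )
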
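"""Shared fixtures: seeded toy alignments and brute-force oracles.

The oracles here are deliberately naive (per-pair, per-site loops over
strings) so they stay independent of the vectorized implementation paths
they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitogeo import Alignment, SampleTable

BASES = "ACGT"
MISSING = "N-RYSWKM"  # N, gap and a few IUPAC ambiguity codes


def random_toy_alignment(rng: np.random.Generator, n: int, L: int,
                         p_missing: float = 0.0) -> Alignment:
    chars = BASES + MISSING
    probs = np.array([(1 - p_missing) / 4] * 4 + [p_missing / len(MISSING)] * len(MISSING))
    seqs = [
        "".join(rng.choice(list(chars), size=L, p=probs)) for _ in range(n)
    ]
    return Alignment.from_sequences([f"s{i}" for i in range(n)], seqs)


def two_group_table(aln: Alignment, split: int | None = None) -> SampleTable:
    split = split if split is not None else aln.n // 2
    rows = [
        (sid, "toy", "A" if i < split else "B", "")
        for i, sid in enumerate(aln.sample_ids)
    ]
    return SampleTable.from_records(rows)


# ---------------------------------------------------------------------------
# brute-force oracles (string-level, loop-based)


def oracle_usable_cols(seqs: list[str]) -> list[int]:
    return [
        j for j in range(len(seqs[0]))
        if all(s[j] in BASES for s in seqs)
    ]


def oracle_pair_diff(a: str, b: str, cols: list[int]) -> int:
    return sum(1 for j in cols if a[j] != b[j])


def oracle_indices(seqs: list[str], cols: list[int] | None = None) -> dict:
    """S, pi, h, Hd by direct per-column / per-pair recounting.

    ``cols`` fixes the usable columns (e.g. a global complete-deletion mask);
    by default they are recomputed from the sequences given.
    """
    if cols is None:
        cols = oracle_usable_cols(seqs)
    n = len(seqs)
    S = sum(1 for j in cols if len({s[j] for s in seqs}) > 1)
    total = 0
    for i in range(n):
        for k in range(i + 1, n):
            total += oracle_pair_diff(seqs[i], seqs[k], cols)
    npairs = n * (n - 1) / 2
    pi = (total / npairs) / len(cols) if cols else float("nan")
    keys = ["".join(s[j] for j in cols) for s in seqs]
    counts = {k: keys.count(k) for k in set(keys)}
    h = len(counts)
    Hd = n / (n - 1) * (1 - sum((c / n) ** 2 for c in counts.values()))
    return {"S": S, "pi": pi, "h": h, "Hd": Hd, "kbar": total / npairs,
            "keys": keys}


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
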
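"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms they check: alignment scores come
from exhaustive enumeration of all global alignments, binomial tails from
explicit summation of the mass function, FDR cutoffs from evaluating every
possible prefix, and minimal protein covers from subset enumeration.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple


def brute_force_alignment_score(
    a: str,
    b: str,
    sub: Mapping[Tuple[str, str], float],
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best global alignment score by enumerating every alignment path.

    A gap of length L costs ``gap_open + gap_extend * L``; end gaps count.
    Exponential — only for sequences of length <= ~7.
    """

    best = [-math.inf]

    def recurse(i: int, j: int, score: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, score + sub[(a[i], b[j])], "M")
        if i < len(a):  # a residue against a gap in b
            cost = gap_extend + (gap_open if prev != "A" else 0.0)
            recurse(i + 1, j, score - cost, "A")
        if j < len(b):
            cost = gap_extend + (gap_open if prev != "B" else 0.0)
            recurse(i, j + 1, score - cost, "B")

    recurse(0, 0, 0.0, "M")
    return best[0]


def binomial_tail(n: int, k: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by explicit summation."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def exhaustive_fdr_cutoff(
    scores: Sequence[float], is_decoy: Sequence[bool], level: float
) -> List[int]:
    """Indices of kept targets by evaluating every score cutoff.

    Records are sorted by descending score (decoys first on ties); every
    prefix is evaluated and the largest with #decoys/max(1,#targets) <=
    level wins.  Returns original indices of kept (non-decoy) records.
    """
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], not is_decoy[i])
    )
    best_prefix = 0
    for cut in range(1, len(order) + 1):
        prefix = order[:cut]
        d = sum(1 for i in prefix if is_decoy[i])
        t = cut - d
        if d / max(1, t) <= level:
            best_prefix = cut
    return sorted(i for i in order[:best_prefix] if not is_decoy[i])


def minimal_cover_size(peptide_to_proteins: Mapping[str, Iterable[str]]) -> int:
    """Size of the smallest protein set covering all peptides (exhaustive)."""
    proteins = sorted({p for ps in peptide_to_proteins.values() for p in ps})
    peptides = list(peptide_to_proteins)
    for size in range(1, len(proteins) + 1):
        for combo in itertools.combinations(proteins, size):
            chosen = set(combo)
            if all(set(peptide_to_proteins[pep]) & chosen for pep in peptides):
                return size
    return 0
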
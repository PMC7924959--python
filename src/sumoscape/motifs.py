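"""SUMO consensus-motif classification of conjugation-site sequence windows.

Each modified lysine is assigned to exactly one of seven categories based on
the residues at positions −3..+2 around the central K, tested in
strict-to-loose precedence so the categories are mutually exclusive and
exhaustive:

1. ``HYDROPHOBIC_VARIANT`` — ΨΨΨ-K-x-E/D: positions −3, −2, −1 all large
   hydrophobic and +2 acidic.
2. ``CONSENSUS`` — Ψ-K-x-E/D: −1 hydrophobic, +2 acidic (the canonical
   Ubc9-binding acceptor motif).
3. ``REVERSE_CONSENSUS`` — E/D-x-K-Ψ: −2 acidic, +1 hydrophobic.
4. ``ACIDIC`` — K-x-E/D: +2 acidic (partial consensus).
5. ``REVERSE_ACIDIC`` — E/D-x-K: −2 acidic.
6. ``DILYSINE`` — a lysine immediately on either flank.
7. ``NONE`` — no recognizable motif.

Ψ is configurable; the default large-hydrophobic set is {I, L, V, M, F}.
The terminus pad character "_" never matches any pattern class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

DEFAULT_HYDROPHOBIC = frozenset("ILVMF")
ACIDIC_RESIDUES = frozenset("ED")


class MotifCategory(str, Enum):
    HYDROPHOBIC_VARIANT = "HYDROPHOBIC_VARIANT"
    CONSENSUS = "CONSENSUS"
    REVERSE_CONSENSUS = "REVERSE_CONSENSUS"
    ACIDIC = "ACIDIC"
    REVERSE_ACIDIC = "REVERSE_ACIDIC"
    DILYSINE = "DILYSINE"
    NONE = "NONE"


@dataclass(frozen=True)
class MotifCall:
    category: MotifCategory
    #: the −3..+2 context actually inspected (6 characters incl. central K)
    window_used: str


def _context(window: str) -> str:
    """Extract positions −3..+2 around the central K, padding with "_"."""
    if len(window) % 2 == 0:
        raise ValueError(f"sequence window must have odd length, got {len(window)}")
    c = len(window) // 2
    if window[c] != "K":
        raise ValueError(f"sequence window is not centered on K: {window!r}")
    padded = "_" * 3 + window + "_" * 2
    c += 3
    return padded[c - 3 : c + 3]


def classify_site(
    window: str, hydrophobic_set: Iterable[str] = DEFAULT_HYDROPHOBIC
) -> MotifCall:
    """Classify one site window into exactly one motif category.

    ``window`` is an odd-length sequence window centered on the modified K
    (any half-width ≥ 0; positions beyond the window never match).
    """
    hydro = frozenset(hydrophobic_set)
    ctx = _context(window)
    m3, m2, m1, _k, p1, p2 = ctx

    if m3 in hydro and m2 in hydro and m1 in hydro and p2 in ACIDIC_RESIDUES:
        cat = MotifCategory.HYDROPHOBIC_VARIANT
    elif m1 in hydro and p2 in ACIDIC_RESIDUES:
        cat = MotifCategory.CONSENSUS
    elif m2 in ACIDIC_RESIDUES and p1 in hydro:
        cat = MotifCategory.REVERSE_CONSENSUS
    elif p2 in ACIDIC_RESIDUES:
        cat = MotifCategory.ACIDIC
    elif m2 in ACIDIC_RESIDUES:
        cat = MotifCategory.REVERSE_ACIDIC
    elif m1 == "K" or p1 == "K":
        cat = MotifCategory.DILYSINE
    else:
        cat = MotifCategory.NONE
    return MotifCall(category=cat, window_used=ctx)


def motif_composition(
    sites: Sequence,
    hydrophobic_set: Iterable[str] = DEFAULT_HYDROPHOBIC,
) -> dict[MotifCategory, float]:
    """Fraction of sites in each motif category (fractions sum to 1).

    ``sites`` may be SiteRecord objects (their ``sequence_window`` is used)
    or plain window strings.
    """
    if len(sites) == 0:
        raise ValueError("motif composition of an empty site set is undefined")
    counts: Counter[MotifCategory] = Counter()
    for s in sites:
        window = s if isinstance(s, str) else s.sequence_window
        counts[classify_site(window, hydrophobic_set).category] += 1
    n = len(sites)
    return {cat: counts.get(cat, 0) / n for cat in MotifCategory}


def motif_counts(
    sites: Sequence,
    hydrophobic_set: Iterable[str] = DEFAULT_HYDROPHOBIC,
) -> dict[MotifCategory, int]:
    """Absolute category counts, same conventions as :func:`motif_composition`."""
    counts: Counter[MotifCategory] = Counter()
    for s in sites:
        window = s if isinstance(s, str) else s.sequence_window
        counts[classify_site(window, hydrophobic_set).category] += 1
    return {cat: counts.get(cat, 0) for cat in MotifCategory}
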
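"""Per-protein site-count statistics, adjacent-site spacing, and
distance-resolved SUMOylation-probability curves.

SUMO sites cluster along the sequence of multiply-modified proteins.  The
distance curve quantifies this: for every anchor (each SUMO site, or each
lysine for the baseline), every *other* lysine of the same protein
contributes one pair at distance |Δposition| rounded to the nearest 10
residues; the curve is the fraction of pairs whose partner lysine is itself
a SUMO site, per distance bin, pooled pair-weighted across all proteins that
carry at least one site.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from sumoscape.tables_io import ProteinRecord, SiteRecord


class CurveReference(str, Enum):
    FROM_SUMO_K = "FROM_SUMO_K"
    FROM_ANY_K = "FROM_ANY_K"


@dataclass
class DistanceCurve:
    bin_centers: list[int]          # multiples of 10 residues
    fraction_sumo: list[float]      # per-bin probability that the partner K is a site
    n_pairs: list[int]
    reference: CurveReference

    def as_dict(self) -> dict[int, tuple[float, int]]:
        return {
            b: (f, n)
            for b, f, n in zip(self.bin_centers, self.fraction_sumo, self.n_pairs)
        }


@dataclass
class SiteCountSummary:
    histogram: dict[int, int]       # sites-per-protein -> number of proteins
    n_proteins: int                 # proteins with >= 1 site
    n_ge2: int
    n_ge5: int
    n_ge30: int


def _sites_by_protein(sites: Sequence[SiteRecord]) -> dict[str, list[int]]:
    by: dict[str, list[int]] = defaultdict(list)
    for s in sites:
        by[s.protein_id].append(s.position)
    return {pid: sorted(set(pos)) for pid, pos in by.items()}


def site_count_distribution(sites: Sequence[SiteRecord]) -> SiteCountSummary:
    """Histogram of sites per protein (over proteins with ≥1 site)."""
    by = _sites_by_protein(sites)
    counts = Counter(len(v) for v in by.values())
    n_ge = lambda t: sum(c for k, c in counts.items() if k >= t)
    return SiteCountSummary(
        histogram=dict(sorted(counts.items())),
        n_proteins=len(by),
        n_ge2=n_ge(2),
        n_ge5=n_ge(5),
        n_ge30=n_ge(30),
    )


def adjacent_spacing(
    sites: Sequence[SiteRecord], per_protein: bool = False
) -> list[int] | dict[str, list[int]]:
    """Successive differences of sorted site positions, pooled across proteins.

    With ``per_protein=True`` the spacings are returned keyed by protein
    instead of pooled.  Raises if no protein carries ≥2 sites.
    """
    by = _sites_by_protein(sites)
    spaced = {
        pid: list(np.diff(pos)) for pid, pos in by.items() if len(pos) >= 2
    }
    if not spaced:
        raise ValueError("no protein carries two or more sites; spacings undefined")
    if per_protein:
        return {pid: [int(d) for d in ds] for pid, ds in spaced.items()}
    return [int(d) for ds in spaced.values() for d in ds]


def fraction_below(
    spacings: Sequence[int], threshold: int, per_protein_mean: bool = False
) -> float:
    """Share of adjacent-site spacings strictly below ``threshold``.

    Default is pair-pooled (every spacing counts once).  When ``spacings``
    is the per-protein mapping from ``adjacent_spacing(per_protein=True)``
    and ``per_protein_mean`` is set, the per-protein fractions are averaged
    instead.
    """
    if per_protein_mean:
        if not isinstance(spacings, Mapping):
            raise TypeError("per_protein_mean needs the per-protein spacing mapping")
        fracs = [
            sum(d < threshold for d in ds) / len(ds) for ds in spacings.values()
        ]
        return float(np.mean(fracs))
    if len(spacings) == 0:
        raise ValueError("empty spacing list")
    return sum(d < threshold for d in spacings) / len(spacings)


def _round_to_10(d: np.ndarray, mode: str) -> np.ndarray:
    """Round distances to the nearest multiple of 10 residues."""
    if mode == "half_away":
        return (np.floor(d / 10.0 + 0.5) * 10).astype(int)
    if mode == "half_even":
        return (np.round(d / 10.0) * 10).astype(int)
    raise ValueError(f"unknown rounding mode {mode!r}")


def distance_curve(
    sites: Sequence[SiteRecord],
    proteins: Sequence[ProteinRecord],
    reference: CurveReference | str = CurveReference.FROM_SUMO_K,
    rounding: str = "half_away",
) -> DistanceCurve:
    """Probability that a lysine is SUMOylated as a function of its distance
    from an anchor.

    Anchors are the SUMO sites (``FROM_SUMO_K``) or all lysines
    (``FROM_ANY_K``); only proteins with at least one identified site are
    considered, and an anchor never pairs with itself.  Distances are
    rounded to the nearest 10 residues (half-away-from-zero by default, so
    distances 1–4 fall in bin 0 and 5–14 in bin 10).
    """
    reference = CurveReference(reference)
    by_site = _sites_by_protein(sites)
    seq_of = {p.protein_id: p for p in proteins}

    sumo_pairs: Counter[int] = Counter()
    all_pairs: Counter[int] = Counter()
    for pid, site_pos in by_site.items():
        prot = seq_of.get(pid)
        if prot is None or not prot.sequence:
            continue
        lys = np.asarray(prot.lysine_positions, dtype=int)
        if lys.size < 2 and reference is CurveReference.FROM_ANY_K:
            continue
        sumo_set = set(site_pos)
        is_sumo = np.isin(lys, site_pos)
        anchors = np.asarray(sorted(sumo_set), dtype=int) if reference is CurveReference.FROM_SUMO_K else lys
        # vectorized pair enumeration: anchors x all lysines, self-pairs removed
        dmat = np.abs(anchors[:, None] - lys[None, :])
        mask = dmat > 0
        bins = _round_to_10(dmat[mask], rounding)
        partner_sumo = np.broadcast_to(is_sumo, dmat.shape)[mask]
        ubins, inv = np.unique(bins, return_inverse=True)
        totals = np.bincount(inv)
        sumo_totals = np.bincount(inv, weights=partner_sumo.astype(float))
        for b, t, sv in zip(ubins, totals, sumo_totals):
            all_pairs[int(b)] += int(t)
            sumo_pairs[int(b)] += int(round(sv))

    centers = sorted(all_pairs)
    return DistanceCurve(
        bin_centers=centers,
        fraction_sumo=[sumo_pairs.get(b, 0) / all_pairs[b] for b in centers],
        n_pairs=[all_pairs[b] for b in centers],
        reference=reference,
    )
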
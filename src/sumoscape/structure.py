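"""Structural context of SUMO sites: composite structure classes, per-class
fold enrichment, and disorder-score distributions.

Per-residue predictor tracks (globular / long-disorder / short-disorder score
/ solvent exposure / coiled-coil / transmembrane, of the kind produced by
IUPred, ACCpro, ncoils and HMMTOP) are consumed from a TSV — the predictors
themselves are never run here — and combined into composite classes:

* ``DISORDERED`` — (long- or short-)disordered and not inside a globular
  domain;
* ``GLOBULAR_EXPOSED`` / ``GLOBULAR_BURIED`` — globular split by solvent
  accessibility;
* ``DISORDERED_NOT_CC`` — disordered and outside coiled-coil regions;
* ``DISORDERED_TERMINUS`` — in a disordered region that extends to the N- or
  C-terminus;
* ``DISORDER_NEAR_TERMINUS`` — in a DISORDERED_NOT_CC region and within 100
  residues of either terminus.

The fold enrichment of a class is the percentage of SUMO-modified lysines in
the class divided by the percentage of all lysines (in site-bearing
proteins) in the class.  Because that statistic normalizes by class
prevalence, the planted relative *rate* of modification between a class and
its complement is recovered by :func:`rate_ratio`, not by the enrichment of
the class alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from sumoscape.tables_io import ProteinRecord, SiteRecord

DEFAULT_DISORDER_THRESHOLD = 0.5
TERMINUS_WINDOW = 100


@dataclass
class ResidueAnnotation:
    """Per-residue predictor tracks for one protein (arrays of length L)."""

    protein_id: str
    length: int
    globular: np.ndarray
    long_disorder: np.ndarray
    short_disorder_score: np.ndarray
    exposed: np.ndarray
    buried: np.ndarray
    coiled_coil: np.ndarray
    transmembrane: np.ndarray

    def __post_init__(self) -> None:
        for name in ("globular", "long_disorder", "short_disorder_score",
                     "exposed", "buried", "coiled_coil", "transmembrane"):
            track = np.asarray(getattr(self, name))
            if track.shape != (self.length,):
                raise ValueError(
                    f"{self.protein_id}: track {name!r} has length {track.shape}, "
                    f"expected ({self.length},)"
                )
            setattr(self, name, track)
        if np.any(self.exposed & self.buried):
            raise ValueError(f"{self.protein_id}: residue marked both exposed and buried")


class StructureClass(str, Enum):
    GLOBULAR = "GLOBULAR"
    LONG_DISORDER = "LONG_DISORDER"
    SHORT_DISORDER = "SHORT_DISORDER"
    DISORDERED = "DISORDERED"
    GLOBULAR_EXPOSED = "GLOBULAR_EXPOSED"
    GLOBULAR_BURIED = "GLOBULAR_BURIED"
    COILED_COIL = "COILED_COIL"
    TRANSMEMBRANE = "TRANSMEMBRANE"
    DISORDERED_NOT_CC = "DISORDERED_NOT_CC"
    DISORDERED_TERMINUS = "DISORDERED_TERMINUS"
    DISORDER_NEAR_TERMINUS = "DISORDER_NEAR_TERMINUS"


@dataclass
class StructureClassTable:
    """Boolean per-residue membership for each composite structure class."""

    protein_id: str
    length: int
    membership: dict[StructureClass, np.ndarray]

    def __getitem__(self, cls: StructureClass) -> np.ndarray:
        return self.membership[cls]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as 0-based half-open (start, stop) intervals."""
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


def derive_classes(
    ann: ResidueAnnotation,
    disorder_threshold: float = DEFAULT_DISORDER_THRESHOLD,
    terminus_window: int = TERMINUS_WINDOW,
    terminus_by_region: bool = True,
) -> StructureClassTable:
    """Derive composite structure classes from raw predictor tracks.

    A residue is SHORT_DISORDER when its continuous short-disorder score is
    at or above ``disorder_threshold`` (0.5, the conventional IUPred decision
    boundary).  DISORDERED_TERMINUS marks residues of disordered regions
    that touch a terminus (set ``terminus_by_region=False`` to instead mark
    only the terminal residues themselves).  DISORDER_NEAR_TERMINUS uses a
    strict distance < ``terminus_window`` from the nearest terminal residue.
    """
    L = ann.length
    short_dis = ann.short_disorder_score >= disorder_threshold
    disordered = (ann.long_disorder | short_dis) & ~ann.globular
    dis_not_cc = disordered & ~ann.coiled_coil

    dis_terminus = np.zeros(L, dtype=bool)
    if terminus_by_region:
        for start, stop in _runs(disordered):
            if start == 0 or stop == L:
                dis_terminus[start:stop] = True
    else:
        if L and disordered[0]:
            dis_terminus[0] = True
        if L and disordered[-1]:
            dis_terminus[-1] = True

    # distance of residue i (1-based) to nearest terminus: min(i-1, L-i)
    idx = np.arange(1, L + 1)
    near_term = np.minimum(idx - 1, L - idx) < terminus_window
    dis_near_terminus = dis_not_cc & near_term

    membership = {
        StructureClass.GLOBULAR: ann.globular.astype(bool),
        StructureClass.LONG_DISORDER: ann.long_disorder.astype(bool),
        StructureClass.SHORT_DISORDER: short_dis,
        StructureClass.DISORDERED: disordered,
        StructureClass.GLOBULAR_EXPOSED: ann.globular & ann.exposed,
        StructureClass.GLOBULAR_BURIED: ann.globular & ann.buried,
        StructureClass.COILED_COIL: ann.coiled_coil.astype(bool),
        StructureClass.TRANSMEMBRANE: ann.transmembrane.astype(bool),
        StructureClass.DISORDERED_NOT_CC: dis_not_cc,
        StructureClass.DISORDERED_TERMINUS: dis_terminus,
        StructureClass.DISORDER_NEAR_TERMINUS: dis_near_terminus,
    }
    return StructureClassTable(protein_id=ann.protein_id, length=L, membership=membership)


@dataclass
class EnrichmentResult:
    enrichment: float | None    # None when the class holds no lysines
    n_sumo_k: int
    n_all_k: int


@dataclass
class FoldEnrichmentTable:
    """Mapping class → :class:`EnrichmentResult` plus the shared totals."""

    per_class: dict[StructureClass, EnrichmentResult]
    n_sumo_total: int
    n_k_total: int

    def __getitem__(self, cls: StructureClass) -> EnrichmentResult:
        return self.per_class[cls]

    def __iter__(self):
        return iter(self.per_class)

    def items(self):
        return self.per_class.items()


def _collect_lysine_masks(
    sites: Sequence[SiteRecord],
    proteins: Sequence[ProteinRecord],
) -> tuple[list[tuple[ProteinRecord, np.ndarray, np.ndarray]], int, int]:
    """Per site-bearing protein: (protein, lysine index array 0-based, is-sumo mask)."""
    site_pos: dict[str, set[int]] = {}
    for s in sites:
        site_pos.setdefault(s.protein_id, set()).add(s.position)
    rows = []
    n_sumo = n_k = 0
    for p in proteins:
        if p.protein_id not in site_pos or not p.sequence:
            continue
        lys0 = np.asarray(p.lysine_positions, dtype=int) - 1
        is_sumo = np.isin(lys0 + 1, sorted(site_pos[p.protein_id]))
        rows.append((p, lys0, is_sumo))
        n_k += lys0.size
        n_sumo += int(is_sumo.sum())
    return rows, n_sumo, n_k


def fold_enrichment(
    sites: Sequence[SiteRecord],
    proteins: Sequence[ProteinRecord],
    classes: Mapping[str, StructureClassTable],
) -> FoldEnrichmentTable:
    """Per-class fold enrichment of SUMO-modified lysines.

    enrichment(c) = (SUMO-K in c / all SUMO-K) / (K in c / all K), restricted
    to proteins carrying at least one identified site.  ``None`` when the
    class contains no lysines at all.
    """
    rows, n_sumo_total, n_k_total = _collect_lysine_masks(sites, proteins)
    out: dict[StructureClass, EnrichmentResult] = {}
    for cls in StructureClass:
        n_sumo_c = n_k_c = 0
        for p, lys0, is_sumo in rows:
            table = classes.get(p.protein_id)
            if table is None:
                continue
            in_c = table[cls][lys0]
            n_k_c += int(in_c.sum())
            n_sumo_c += int((in_c & is_sumo).sum())
        if n_k_c == 0 or n_k_total == 0 or n_sumo_total == 0:
            out[cls] = EnrichmentResult(None, n_sumo_c, n_k_c)
        else:
            enr = (n_sumo_c / n_sumo_total) / (n_k_c / n_k_total)
            out[cls] = EnrichmentResult(enr, n_sumo_c, n_k_c)
    return FoldEnrichmentTable(out, n_sumo_total, n_k_total)


def rate_ratio(result: FoldEnrichmentTable, cls: StructureClass) -> float:
    """Relative modification rate of a class versus its complement.

    (SUMO-K/K inside the class) / (SUMO-K/K outside it).  This is the
    quantity a planted per-lysine odds multiplier corresponds to; the
    fold-enrichment statistic of the class alone is attenuated by class
    prevalence.
    """
    r = result[cls]
    n_sumo_out = result.n_sumo_total - r.n_sumo_k
    n_k_out = result.n_k_total - r.n_all_k
    if r.n_all_k == 0 or n_k_out == 0 or n_sumo_out == 0:
        raise ZeroDivisionError("degenerate class for rate ratio")
    return (r.n_sumo_k / r.n_all_k) / (n_sumo_out / n_k_out)


@dataclass
class DisorderDistributions:
    sumo_scores: np.ndarray
    nonsumo_scores: np.ndarray
    sumo_quantiles: dict[int, float]
    nonsumo_quantiles: dict[int, float]


def disorder_distributions(
    sites: Sequence[SiteRecord],
    proteins: Sequence[ProteinRecord],
    annotations: Mapping[str, ResidueAnnotation],
) -> DisorderDistributions:
    """Short-disorder score distributions of SUMO-K versus non-SUMO K.

    Restricted to proteins with at least one identified site; together the
    two vectors partition all lysines of those proteins.
    """
    rows, _, _ = _collect_lysine_masks(sites, proteins)
    sumo_scores: list[np.ndarray] = []
    non_scores: list[np.ndarray] = []
    for p, lys0, is_sumo in rows:
        ann = annotations.get(p.protein_id)
        if ann is None:
            continue
        scores = ann.short_disorder_score[lys0]
        sumo_scores.append(scores[is_sumo])
        non_scores.append(scores[~is_sumo])
    sumo = np.concatenate(sumo_scores) if sumo_scores else np.empty(0)
    non = np.concatenate(non_scores) if non_scores else np.empty(0)
    qlevels = (10, 25, 50, 75, 90)
    qs = lambda v: (
        {q: float(np.percentile(v, q)) for q in qlevels} if v.size else {q: float("nan") for q in qlevels}
    )
    return DisorderDistributions(sumo, non, qs(sumo), qs(non))
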
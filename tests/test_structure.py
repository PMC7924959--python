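"""Composite structure classes, fold enrichment, disorder distributions."""

import numpy as np
import pytest

from sumoscape import (
    ProteinRecord,
    ResidueAnnotation,
    SiteRecord,
    StructureClass,
    derive_classes,
    disorder_distributions,
    fold_enrichment,
    rate_ratio,
)


def _ann(pid="P", **tracks):
    L = len(next(iter(tracks.values())))
    zeros = np.zeros(L, dtype=bool)
    defaults = dict(
        globular=zeros.copy(),
        long_disorder=zeros.copy(),
        short_disorder_score=np.zeros(L),
        exposed=zeros.copy(),
        buried=zeros.copy(),
        coiled_coil=zeros.copy(),
        transmembrane=zeros.copy(),
    )
    defaults.update({k: np.asarray(v) for k, v in tracks.items()})
    return ResidueAnnotation(protein_id=pid, length=L, **defaults)


def _site(pid, pos):
    return SiteRecord(
        site_id=f"{pid}_K{pos}", protein_id=pid, position=pos,
        localization_prob=1.0, sequence_window="AAAKAAA", intensities={},
    )


def _protein_with_K(pid, length, k_positions):
    seq = ["A"] * length
    for k in k_positions:
        seq[k - 1] = "K"
    return ProteinRecord(protein_id=pid, sequence="".join(seq))


def test_fully_globular_protein_has_no_disorder():
    ann = _ann(globular=np.ones(50, dtype=bool), long_disorder=np.ones(50, dtype=bool))
    table = derive_classes(ann)
    assert not table[StructureClass.DISORDERED].any()


def test_disorder_near_terminus_uses_100_residue_window():
    L = 300
    dis = np.zeros(L, dtype=bool)
    dis[49] = True    # residue 50 (1-based)
    dis[149] = True   # residue 150
    table = derive_classes(_ann(long_disorder=dis))
    near = table[StructureClass.DISORDER_NEAR_TERMINUS]
    assert near[49] and not near[149]


def test_disordered_terminus_region_must_touch_terminus():
    L = 100
    dis = np.zeros(L, dtype=bool)
    dis[:10] = True     # N-terminal region
    dis[40:50] = True   # internal region
    table = derive_classes(_ann(long_disorder=dis))
    dt = table[StructureClass.DISORDERED_TERMINUS]
    assert dt[:10].all() and not dt[40:50].any()


def test_short_disorder_threshold_inclusive():
    score = np.array([0.49, 0.5, 0.51])
    table = derive_classes(_ann(short_disorder_score=score))
    assert list(table[StructureClass.SHORT_DISORDER]) == [False, True, True]


def test_track_length_mismatch_rejected():
    with pytest.raises(ValueError, match="length"):
        ResidueAnnotation(
            protein_id="P", length=5,
            globular=np.zeros(4, dtype=bool),
            long_disorder=np.zeros(5, dtype=bool),
            short_disorder_score=np.zeros(5),
            exposed=np.zeros(5, dtype=bool),
            buried=np.zeros(5, dtype=bool),
            coiled_coil=np.zeros(5, dtype=bool),
            transmembrane=np.zeros(5, dtype=bool),
        )


def _brute_force_classes(ann, thr=0.5):
    """Independent per-residue re-derivation of every composite class."""
    L = ann.length
    out = {c: np.zeros(L, dtype=bool) for c in StructureClass}
    # disordered runs for the terminus rule
    dis = [
        (ann.long_disorder[i] or ann.short_disorder_score[i] >= thr)
        and not ann.globular[i]
        for i in range(L)
    ]
    touches = [False] * L
    i = 0
    while i < L:
        if dis[i]:
            j = i
            while j < L and dis[j]:
                j += 1
            if i == 0 or j == L:
                for t in range(i, j):
                    touches[t] = True
            i = j
        else:
            i += 1
    for i in range(L):
        short = ann.short_disorder_score[i] >= thr
        d = dis[i]
        dncc = d and not ann.coiled_coil[i]
        out[StructureClass.GLOBULAR][i] = ann.globular[i]
        out[StructureClass.LONG_DISORDER][i] = ann.long_disorder[i]
        out[StructureClass.SHORT_DISORDER][i] = short
        out[StructureClass.DISORDERED][i] = d
        out[StructureClass.GLOBULAR_EXPOSED][i] = ann.globular[i] and ann.exposed[i]
        out[StructureClass.GLOBULAR_BURIED][i] = ann.globular[i] and ann.buried[i]
        out[StructureClass.COILED_COIL][i] = ann.coiled_coil[i]
        out[StructureClass.TRANSMEMBRANE][i] = ann.transmembrane[i]
        out[StructureClass.DISORDERED_NOT_CC][i] = dncc
        out[StructureClass.DISORDERED_TERMINUS][i] = touches[i]
        out[StructureClass.DISORDER_NEAR_TERMINUS][i] = dncc and min(i, L - 1 - i) < 100
    return out


def test_classes_equal_brute_force_on_random_annotations():
    rng = np.random.default_rng(3)
    for _ in range(10):
        L = int(rng.integers(30, 300))
        exposed = rng.random(L) < 0.5
        ann = _ann(
            globular=rng.random(L) < 0.5,
            long_disorder=rng.random(L) < 0.3,
            short_disorder_score=rng.random(L),
            exposed=exposed,
            buried=~exposed,
            coiled_coil=rng.random(L) < 0.1,
            transmembrane=rng.random(L) < 0.05,
        )
        table = derive_classes(ann)
        oracle = _brute_force_classes(ann)
        for cls in StructureClass:
            assert np.array_equal(table[cls], oracle[cls]), cls


def test_class_invariants_hold(small_study):
    for ann in small_study.annotations.values():
        t = derive_classes(ann)
        assert not (t[StructureClass.DISORDERED] & t[StructureClass.GLOBULAR]).any()
        assert not (
            t[StructureClass.GLOBULAR_EXPOSED] & ~t[StructureClass.GLOBULAR]
        ).any()
        assert not (
            t[StructureClass.DISORDERED_NOT_CC]
            & (~t[StructureClass.DISORDERED] | t[StructureClass.COILED_COIL])
        ).any()
        assert not (
            t[StructureClass.DISORDER_NEAR_TERMINUS]
            & ~t[StructureClass.DISORDERED_NOT_CC]
        ).any()


def _two_class_setup():
    """100 K, 40 disordered; 10 sites, 8 in disorder -> enrichment 2.0."""
    L = 400
    seq = ["A"] * L
    k_positions = list(range(2, 2 + 4 * 100, 4))  # 100 lysines
    for k in k_positions:
        seq[k - 1] = "K"
    prot = ProteinRecord(protein_id="P", sequence="".join(seq))
    dis = np.zeros(L, dtype=bool)
    for k in k_positions[:40]:
        dis[k - 1] = True
    ann = _ann(long_disorder=dis)
    sites = [_site("P", k) for k in k_positions[:8]] + [
        _site("P", k) for k in k_positions[40:42]
    ]
    return prot, ann, sites


def test_fold_enrichment_formula():
    prot, ann, sites = _two_class_setup()
    enr = fold_enrichment(sites, [prot], {"P": derive_classes(ann)})
    r = enr[StructureClass.DISORDERED]
    assert (r.n_sumo_k, r.n_all_k) == (8, 40)
    assert r.enrichment == pytest.approx((8 / 10) / (40 / 100))


def test_class_covering_everything_has_unit_enrichment():
    prot, ann, sites = _two_class_setup()
    ann.long_disorder[:] = True
    enr = fold_enrichment(sites, [prot], {"P": derive_classes(ann)})
    assert enr[StructureClass.DISORDERED].enrichment == pytest.approx(1.0)


def test_empty_class_reported_missing():
    prot, ann, sites = _two_class_setup()
    enr = fold_enrichment(sites, [prot], {"P": derive_classes(ann)})
    assert enr[StructureClass.TRANSMEMBRANE].enrichment is None
    assert enr[StructureClass.TRANSMEMBRANE].n_all_k == 0


def test_complementary_classes_bracket_unity(small_study):
    """GLOBULAR and DISORDERED partition the synthetic residues: counts are
    conserved and their enrichments bracket 1."""
    sites = small_study.true_site_records
    classes = {pid: derive_classes(a) for pid, a in small_study.annotations.items()}
    enr = fold_enrichment(sites, small_study.proteins, classes)
    a = enr[StructureClass.DISORDERED]
    b = enr[StructureClass.GLOBULAR]
    assert a.n_sumo_k + b.n_sumo_k == enr.n_sumo_total
    assert a.n_all_k + b.n_all_k == enr.n_k_total
    lo, hi = sorted([a.enrichment, b.enrichment])
    assert lo <= 1.0 <= hi


def test_enrichment_scale_invariance():
    prot, ann, sites = _two_class_setup()
    classes = {"P": derive_classes(ann)}
    single = fold_enrichment(sites, [prot], classes)

    prot2 = ProteinRecord(protein_id="Q", sequence=prot.sequence)
    ann2 = _ann(pid="Q", long_disorder=ann.long_disorder)
    sites2 = sites + [_site("Q", s.position) for s in sites]
    doubled = fold_enrichment(
        sites2, [prot, prot2], {"P": derive_classes(ann), "Q": derive_classes(ann2)}
    )
    for cls in StructureClass:
        e1, e2 = single[cls].enrichment, doubled[cls].enrichment
        if e1 is None:
            assert e2 is None
        else:
            assert e2 == pytest.approx(e1)


def test_rate_ratio_identifies_relative_rate():
    prot, ann, sites = _two_class_setup()
    enr = fold_enrichment(sites, [prot], {"P": derive_classes(ann)})
    # 8/40 inside vs 2/60 outside
    assert rate_ratio(enr, StructureClass.DISORDERED) == pytest.approx(
        (8 / 40) / (2 / 60)
    )


def test_disorder_distribution_partition(small_study):
    sites = small_study.true_site_records
    d = disorder_distributions(sites, small_study.proteins, small_study.annotations)
    site_pids = {s.protein_id for s in sites}
    total_k = sum(
        len(p.lysine_positions)
        for p in small_study.proteins
        if p.protein_id in site_pids
    )
    assert d.sumo_scores.size + d.nonsumo_scores.size == total_k


def test_disorder_bias_planted_shifts_median(small_study):
    """Disorder-enriched sites have higher short-disorder scores."""
    sites = small_study.true_site_records
    d = disorder_distributions(sites, small_study.proteins, small_study.annotations)
    assert d.sumo_quantiles[50] > d.nonsumo_quantiles[50]


def test_disorder_distribution_constant_scores():
    prot = _protein_with_K("P", 20, [4, 8, 12])
    ann = _ann(pid="P", short_disorder_score=np.full(20, 0.5))
    d = disorder_distributions([_site("P", 4)], [prot], {"P": ann})
    assert d.sumo_quantiles[50] == 0.5
    assert d.nonsumo_quantiles[50] == 0.5
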
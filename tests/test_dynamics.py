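"""The LFQ pipeline: averaging, log2, imputation, z-scoring, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from sumoscape import (
    MatrixState,
    ProfileMatrix,
    SampleDesign,
    SiteRecord,
    average_replicates,
    count_identified,
    cumulative_site_intensity,
    hierarchical_cluster,
    impute_downshift,
    log2_transform,
    matrix_from_sites,
    normalized_profile,
    similarity_matrix,
    zscore_rows,
)
from sumoscape.dynamics import PipelineStateError, rank_sites_within_protein

DESIGN = SampleDesign.from_layout(("T1", "T2"), 3)


def _raw(rows, index=None, design=DESIGN):
    return ProfileMatrix(
        pd.DataFrame(
            rows,
            index=index or [f"r{i}" for i in range(len(rows))],
            columns=design.samples,
            dtype=float,
        ),
        MatrixState.RAW,
    )


def _avg(rows, index=None, columns=None):
    ncol = len(rows[0])
    cols = list(columns) if columns is not None else [f"T{i + 1}" for i in range(ncol)]
    return ProfileMatrix(
        pd.DataFrame(
            rows,
            index=index or [f"r{i}" for i in range(len(rows))],
            columns=cols[:ncol],
            dtype=float,
        ),
        MatrixState.AVERAGED,
    )


def test_average_skips_missing_replicates():
    m = _raw([[2, 4, np.nan, 1, 1, 1]])
    out = average_replicates(m, DESIGN)
    assert out.state is MatrixState.AVERAGED
    assert out.data.loc["r0", "T1"] == pytest.approx(3.0)


def test_average_all_missing_stays_missing():
    m = _raw([[np.nan, np.nan, np.nan, 1, 2, 3]])
    out = average_replicates(m, DESIGN)
    assert np.isnan(out.data.loc["r0", "T1"])
    assert out.data.loc["r0", "T2"] == pytest.approx(2.0)


def test_average_matches_brute_force(small_study):
    m = matrix_from_sites(small_study.true_site_records, small_study.design)
    out = average_replicates(m, small_study.design)
    s = small_study.true_site_records[0]
    for tp in small_study.design.timepoints:
        reps = [
            s.intensities[c]
            for c in small_study.design.replicates_of(tp)
            if s.intensities[c] is not None
        ]
        expect = np.mean(reps) if reps else np.nan
        got = out.data.loc[s.site_id, tp]
        assert (np.isnan(expect) and np.isnan(got)) or got == pytest.approx(expect)


def test_log2_basic_and_missing():
    m = _avg([[8.0, np.nan, 2.0]])
    out = log2_transform(m)
    assert out.data.iloc[0, 0] == pytest.approx(3.0)
    assert np.isnan(out.data.iloc[0, 1])
    assert out.data.iloc[0, 2] == pytest.approx(1.0)


def test_log2_roundtrip_powers_of_two():
    x = np.array([[0.5, 1, 2, 4, 1024]])
    out = log2_transform(_avg(x, columns=[f"T{i}" for i in range(5)]))
    assert np.allclose(2.0 ** out.data.to_numpy(), x)


def test_log2_rejects_nonpositive_naming_row():
    with pytest.raises(ValueError, match="bad_row"):
        log2_transform(_avg([[1.0, 0.0, 2.0]], index=["bad_row"]))


def _log2m(rows, **kw):
    m = _avg(rows, **kw)
    return ProfileMatrix(m.data, MatrixState.LOG2)


def test_impute_identity_without_missing():
    m = _log2m([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    out = impute_downshift(m, seed=1)
    assert out.data.equals(m.data)


def test_impute_deterministic_given_seed():
    rows = [[20.0, np.nan, 22.0], [21.0, 23.0, np.nan], [19.0, 22.0, 21.0]]
    a = impute_downshift(_log2m(rows), seed=9).data
    b = impute_downshift(_log2m(rows), seed=9).data
    assert a.equals(b)
    c = impute_downshift(_log2m(rows), seed=10).data
    assert not c.equals(a)


def test_impute_rejects_underobserved_column():
    rows = [[np.nan, 1.0, 1.0], [np.nan, 2.0, 3.0], [1.0, 2.0, 3.0]]
    # column T1 has 1 observed value only
    with pytest.raises(ValueError, match="observed"):
        impute_downshift(_log2m(rows), seed=0)


def test_impute_recovers_downshifted_normal():
    """Imputed cells follow Normal(m - 1.8 s, (0.3 s)^2) per column."""
    rng = np.random.default_rng(4)
    n = 20_000
    observed = rng.normal(25.0, 2.0, size=n)
    col = np.concatenate([observed, np.full(10_000, np.nan)])
    m = ProfileMatrix(
        pd.DataFrame({"T1": col, "T2": np.ones(n + 10_000)}), MatrixState.LOG2
    )
    out = impute_downshift(m, seed=8)
    imputed = out.data["T1"].to_numpy()[n:]
    m_c, s_c = observed.mean(), observed.std(ddof=1)
    k = imputed.size
    assert abs(imputed.mean() - (m_c - 1.8 * s_c)) < 3 * (0.3 * s_c) / np.sqrt(k)
    sd_se = (0.3 * s_c) / np.sqrt(2 * (k - 1))
    assert abs(imputed.std(ddof=1) - 0.3 * s_c) < 3 * sd_se


def _imputed(rows, **kw):
    m = _avg(rows, **kw)
    return ProfileMatrix(m.data, MatrixState.IMPUTED)


def test_zscore_example_row():
    out = zscore_rows(_imputed([[1.0, 2.0, 3.0]]))
    assert np.allclose(out.data.to_numpy(), [[-1.0, 0.0, 1.0]])


def test_zscore_flags_constant_rows():
    out = zscore_rows(_imputed([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]], index=["flat", "ok"]))
    assert out.flagged_rows == ["flat"]
    assert np.allclose(out.data.loc["flat"].to_numpy(), 2.0)


def test_zscore_rows_mean_zero_sd_one_property():
    rng = np.random.default_rng(0)
    m = _imputed(rng.normal(20, 3, size=(50, 3)).tolist())
    out = zscore_rows(m)
    vals = out.data.to_numpy()
    assert np.allclose(vals.mean(axis=1), 0.0, atol=1e-9)
    assert np.allclose(vals.std(axis=1, ddof=1), 1.0, atol=1e-9)


def test_pipeline_state_enforced():
    raw = _raw([[1, 2, 3, 4, 5, 6]])
    with pytest.raises(PipelineStateError):
        log2_transform(raw)
    with pytest.raises(PipelineStateError):
        zscore_rows(raw)
    with pytest.raises(PipelineStateError):
        hierarchical_cluster(raw)


def _zscored(rows, index=None):
    m = _imputed(rows, index=index)
    return zscore_rows(m)


def test_identical_rows_have_zero_distance():
    z = _zscored([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
    res = hierarchical_cluster(z)
    assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_anticorrelated_rows_have_distance_two():
    z = _zscored([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
    res = hierarchical_cluster(z)
    assert res.linkage[0, 2] == pytest.approx(2.0)


def test_clustering_invariant_to_row_order():
    rng = np.random.default_rng(2)
    rows = rng.normal(size=(12, 5)).tolist()
    ids = [f"r{i}" for i in range(12)]
    z1 = _zscored(rows, index=ids)
    perm = list(reversed(range(12)))
    z2 = _zscored([rows[i] for i in perm], index=[ids[i] for i in perm])
    f1 = hierarchical_cluster(z1).flat_clusters(3)
    f2 = hierarchical_cluster(z2).flat_clusters(3)
    # same partition up to label permutation
    group1 = {}
    for rid, lab in f1.items():
        group1.setdefault(lab, set()).add(rid)
    group2 = {}
    for rid, lab in f2.items():
        group2.setdefault(lab, set()).add(rid)
    assert set(map(frozenset, group1.values())) == set(map(frozenset, group2.values()))


def test_newick_export_has_all_leaves():
    z = _zscored([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [1.0, 3.0, 2.0]],
                 index=["a", "b", "c"])
    nwk = hierarchical_cluster(z).to_newick()
    assert nwk.endswith(";")
    for leaf in ("a", "b", "c"):
        assert leaf in nwk


def test_similarity_matrix_properties():
    z = _zscored([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [1.0, 3.0, 2.0]])
    sim = similarity_matrix(z)
    arr = sim.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 1.0)
    # similarity = 1 - (1 - Pearson) distance
    from scipy.spatial.distance import squareform

    from sumoscape.dynamics import _pearson_condensed

    dist = squareform(_pearson_condensed(z.data.to_numpy()))
    assert np.allclose(arr, 1.0 - dist)


def test_normalized_profile_examples():
    assert np.allclose(normalized_profile([2, 4, 6]), [0, 0.5, 1])
    scaled = normalized_profile([0.0, 0.25, 1.0])
    assert np.allclose(normalized_profile(scaled), scaled)
    mono = normalized_profile([1, 3, 7, 20])
    assert np.all(np.diff(mono) > 0)
    with pytest.raises(ValueError, match="constant"):
        normalized_profile([5, 5, 5])


def _site_with(intensities, sid="P_K4", pid="P"):
    return SiteRecord(
        site_id=sid, protein_id=pid, position=4, localization_prob=1.0,
        sequence_window="AAAKAAA", intensities=intensities,
    )


def test_cumulative_intensity_sums_non_missing():
    s = _site_with({"a": 1e6, "b": None, "c": 3e6})
    totals, flagged = cumulative_site_intensity([s])
    assert totals["P_K4"] == pytest.approx(4e6)
    assert not flagged


def test_cumulative_intensity_all_missing_flagged():
    s = _site_with({"a": None, "b": None})
    totals, flagged = cumulative_site_intensity([s])
    assert totals["P_K4"] == 0.0
    assert flagged == {"P_K4"}


def test_site_ranking_matches_brute_force(small_study):
    sites = small_study.true_site_records
    ranking = rank_sites_within_protein(sites)
    totals, _ = cumulative_site_intensity(sites)
    for pid, order in ranking.items():
        vals = [totals[sid] for sid in order]
        assert vals == sorted(vals, reverse=True)
        expected = {s.site_id for s in sites if s.protein_id == pid}
        assert set(order) == expected


def test_count_identified_example():
    m = _raw([[1, np.nan, np.nan, np.nan, np.nan, np.nan],
              [1, 2, 3, 4, np.nan, np.nan]], index=["r1", "r2"])
    assert count_identified(m, DESIGN) == {"T1": 2, "T2": 1}
    assert count_identified(m, DESIGN, mode="all") == {"T1": 1, "T2": 0}


def test_count_identified_matches_truth(small_study):
    m = matrix_from_sites(small_study.true_site_records, small_study.design)
    counts = count_identified(m, small_study.design)
    for tp in small_study.design.timepoints:
        reps = small_study.design.replicates_of(tp)
        expected = sum(
            any(s.intensities[r] is not None for r in reps)
            for s in small_study.true_site_records
        )
        assert counts[tp] == expected
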
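"""Pairwise Spearman correlations and distance-matrix construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cooccurnet import (
    bray_curtis_matrix,
    preset_null,
    replicate_correlations,
    simulate_study,
    spearman_distance_matrix,
)
from tests.conftest import balanced_study


def _two_taxa_study(x, y, eco="E1", rep="R1"):
    return balanced_study({(eco, rep): np.array([x, y])})


@pytest.mark.parametrize(
    "x,y,expected_rho",
    [
        ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),     # identical ranks
        ([1, 2, 3, 4], [8, 6, 4, 2], -1.0),    # reversed ranks
        ([1, 2, 3], [2, 1, 3], 0.5),           # hand-computed on 3 points
    ],
)
def test_spearman_known_values(x, y, expected_rho):
    cs = replicate_correlations(_two_taxa_study(x, y), "E1", "R1")
    rho, p, n = cs.pairs[("T1", "T2")]
    assert rho == pytest.approx(expected_rho)
    assert n == len(x)
    assert 0 <= p <= 1


def test_all_zero_taxon_excluded():
    study = balanced_study(
        {("E1", "R1"): np.array([[1, 2, 3], [0, 0, 0], [3, 1, 2]])}
    )
    cs = replicate_correlations(study, "E1", "R1")
    assert ("T1", "T2") not in cs.pairs  # T2 is the all-zero taxon
    assert ("T2", "T3") not in cs.pairs
    assert ("T1", "T3") in cs.pairs


def test_constant_vector_pair_excluded():
    study = balanced_study(
        {("E1", "R1"): np.array([[1, 2, 3], [5, 5, 5]])}
    )
    cs = replicate_correlations(study, "E1", "R1")
    assert cs.pairs == {}


def test_too_few_samples_rejected():
    study = balanced_study({("E1", "R1"): np.array([[1, 2], [3, 4]])})
    with pytest.raises(ValueError, match=">= 3"):
        replicate_correlations(study, "E1", "R1")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 1000), min_size=5, max_size=20, unique=True).filter(
        lambda v: len(v) >= 5
    ),
    st.permutations(range(5)),
)
def test_spearman_invariant_under_monotone_transform(values, perm):
    """rho depends only on ranks: x -> 3x^2 + 7 (strictly monotone on
    non-negative integers) must leave every correlation unchanged."""
    x = np.array(values[:5])
    y = np.array([values[i] for i in perm])
    base = replicate_correlations(_two_taxa_study(x, y), "E1", "R1")
    trans = replicate_correlations(
        _two_taxa_study(3 * x**2 + 7, y), "E1", "R1"
    )
    if ("T1", "T2") in base.pairs:
        assert base.pairs[("T1", "T2")][0] == pytest.approx(
            trans.pairs[("T1", "T2")][0]
        )


def test_distance_matrix_extremes():
    block = np.array([[1, 5, 2, 9], [2, 10, 4, 18], [9, 2, 8, 1]])
    dm = spearman_distance_matrix(balanced_study({("E1", "R1"): block}))
    ids = dm.object_ids
    d = dict()
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            d[(a, b)] = dm.d[i, j]
    # T1 and T2 share ranks -> d = 0; T3 reverses them -> d = 2
    assert d[("T1|E1|R1", "T2|E1|R1")] == pytest.approx(0.0, abs=1e-12)
    assert d[("T1|E1|R1", "T3|E1|R1")] == pytest.approx(2.0, abs=1e-12)
    assert np.allclose(dm.d, dm.d.T)
    assert np.allclose(np.diag(dm.d), 0)


def test_independent_profiles_are_at_null_distance():
    rng = np.random.default_rng(5)
    block = rng.integers(0, 10_000, size=(2, 1000))
    dm = spearman_distance_matrix(balanced_study({("E1", "R1"): block}))
    assert abs(dm.d[0, 1] - 1.0) < 0.1


def test_unbalanced_replicates_rejected():
    study = balanced_study({("E1", "R1"): np.arange(6).reshape(2, 3)})
    bigger = np.arange(8).reshape(2, 4)
    import numpy as _np
    from cooccurnet import AbundanceStudy

    counts = _np.hstack([study.counts, bigger])
    ids = study.sample_ids + [f"E1_R2_S{k}" for k in range(4)]
    meta = dict(study.sample_meta)
    meta.update({f"E1_R2_S{k}": ("E1", "R2") for k in range(4)})
    unb = AbundanceStudy(counts, study.taxon_ids, ids, meta)
    with pytest.raises(ValueError, match="unbalanced"):
        spearman_distance_matrix(unb)


def test_null_study_within_equals_between_distance():
    """With independent taxa everywhere, mean within-ecosystem distance must
    match mean between-ecosystem distance (both ~1)."""
    dm = spearman_distance_matrix(simulate_study(preset_null(3)))
    lab = dm.group_labels()
    mask = ~np.eye(len(lab), dtype=bool)
    within = dm.d[np.ix_(lab == "E1", lab == "E1")]
    between = dm.d[np.ix_(lab == "E1", lab == "E2")]
    w = within[mask[: within.shape[0], : within.shape[1]]].mean()
    assert abs(w - between.mean()) < 0.02


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([4, 1, 3], [4, 1, 3], 0.0),  # identical samples
        ([1, 0], [0, 1], 1.0),        # disjoint composition
        ([6, 4], [2, 8], 0.4),        # (|6-2| + |4-8|) / (8 + 12)
    ],
)
def test_bray_curtis_known_values(x, y, expected):
    from cooccurnet import AbundanceStudy

    study = AbundanceStudy(
        np.column_stack([x, y]),  # taxa x 2 samples
        [f"T{i}" for i in range(len(x))],
        ["S1", "S2"],
        {"S1": ("E1", "R1"), "S2": ("E1", "R1")},
    )
    dm = bray_curtis_matrix(study, scale=False)
    assert dm.d[0, 1] == pytest.approx(expected)


def test_bray_curtis_scaling_bounds():
    rng = np.random.default_rng(0)
    study = balanced_study({("E1", "R1"): rng.integers(0, 50, (5, 8))})
    dm = bray_curtis_matrix(study, scale=True)
    assert dm.metric_name == "bray_curtis"
    assert (dm.d >= 0).all() and (dm.d <= 1 + 1e-12).all()
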
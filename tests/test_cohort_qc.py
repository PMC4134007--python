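"""Genotype QC thresholds, relatedness pruning, BMI cleaning and LD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phewaskit.cohort_qc import (GenotypeSet, LdGroup, MonomorphicError,
                                 clean_bmi, hard_call, ld_group, ld_r2,
                                 minor_allele_freq, prune_related, qc_filter)


def _gset(dosage_rows, info=None):
    snps = list(dosage_rows)
    n = len(next(iter(dosage_rows.values())))
    dosages = pd.DataFrame(dosage_rows, index=[f"i{k}" for k in range(n)]).T
    meta = pd.DataFrame({
        "effect_allele": "A", "other_allele": "C",
        "info": [np.nan if info is None else info.get(s, np.nan) for s in snps],
    }, index=snps)
    return GenotypeSet(dosages, meta)


# -- MAF ---------------------------------------------------------------------

@pytest.mark.parametrize("dosages, expected", [
    ([0, 1, 2, 2], 0.375),
    ([0, np.nan, 2], 0.5),
    ([0, 0, 0, 0], 0.0),
])
def test_minor_allele_freq(dosages, expected):
    assert minor_allele_freq(dosages) == pytest.approx(expected)


def test_minor_allele_freq_all_missing_is_error():
    with pytest.raises(ValueError):
        minor_allele_freq([np.nan, np.nan])


@given(st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=1, max_size=30))
def test_maf_invariant_under_allele_relabeling(dosages):
    flipped = [2.0 - d for d in dosages]
    assert minor_allele_freq(dosages) == pytest.approx(minor_allele_freq(flipped))
    assert 0.0 <= minor_allele_freq(dosages) <= 0.5


# -- QC filter ---------------------------------------------------------------

def test_qc_filter_thresholds_and_boundaries():
    n = 200
    rng = np.random.default_rng(0)
    common = rng.binomial(2, 0.41, n).astype(float)
    maf_boundary = np.r_[np.ones(4), np.zeros(n - 4)]  # maf exactly 0.01
    low_call = common.copy()
    low_call[:2] = np.nan  # call rate 0.99 exactly -> not > 0.99
    gset = _gset(
        {"keep": common, "maf001": maf_boundary, "lowcall": low_call,
         "lowinfo": common},
        info={"lowinfo": 0.65, "keep": np.nan},
    )
    kept, log = qc_filter(gset)
    assert kept.snp_ids == ["keep"]
    assert set(log["snp_id"]) == {"maf001", "lowcall", "lowinfo"}


def test_qc_filter_idempotent_and_order_invariant():
    rng = np.random.default_rng(1)
    rows = {f"s{i}": rng.binomial(2, 0.3, 100).astype(float) for i in range(5)}
    rows["bad"] = np.zeros(100)
    gset = _gset(rows)
    once, _ = qc_filter(gset)
    twice, log2 = qc_filter(once)
    assert twice.snp_ids == once.snp_ids and len(log2) == 0
    reordered = GenotypeSet(gset.dosages.iloc[::-1], gset.meta.iloc[::-1])
    kept_r, _ = qc_filter(reordered)
    assert set(kept_r.snp_ids) == set(once.snp_ids)


def test_common_well_typed_snp_passes_qc():
    rng = np.random.default_rng(2)
    dos = rng.binomial(2, 0.41, 1000).astype(float)
    dos[:5] = np.nan  # call rate 0.995
    kept, _ = qc_filter(_gset({"rs": dos}))
    assert kept.snp_ids == ["rs"]


# -- hard calls --------------------------------------------------------------

@pytest.mark.parametrize("post, expected", [
    ((0.99, 0.01, 0.0), 0),
    ((0.2, 0.3, 0.5), 2),
    ((0.5, 0.5, 0.0), 0),  # tie broken toward the lower dosage
])
def test_hard_call(post, expected):
    assert hard_call(post) == expected


@pytest.mark.parametrize("bad", [(0.5, 0.2, 0.2), (-0.1, 0.6, 0.5), (1, 1, 1)])
def test_hard_call_rejects_invalid_simplex(bad):
    with pytest.raises(ValueError):
        hard_call(bad)


# -- relatedness pruning -----------------------------------------------------

def _pairs(rows):
    return pd.DataFrame(rows, columns=["id_a", "id_b", "pi_hat"])


def test_prune_keeps_one_of_related_pair():
    kept = prune_related(["A", "B", "C"], _pairs([("A", "B", 0.30)]), rng=0)
    assert "C" in kept and len(kept & {"A", "B"}) == 1


def test_prune_boundary_pi_hat_keeps_both():
    kept = prune_related(["A", "B"], _pairs([("A", "B", 0.25)]), rng=0)
    assert kept == {"A", "B"}


def test_prune_chain_keeps_one_per_component():
    kept = prune_related(["A", "B", "C", "D"],
                         _pairs([("A", "B", 0.5), ("B", "C", 0.4)]), rng=3)
    assert len(kept & {"A", "B", "C"}) == 1 and "D" in kept


def test_prune_reproducible_and_valid():
    ids = [f"p{i}" for i in range(20)]
    pairs = _pairs([("p0", "p1", 0.5), ("p2", "p3", 0.45), ("p3", "p4", 0.3),
                    ("p5", "p6", 0.2)])
    k1 = prune_related(ids, pairs, rng=42)
    k2 = prune_related(ids, pairs, rng=42)
    assert k1 == k2
    high = pairs[pairs.pi_hat > 0.25]
    for row in high.itertuples():
        assert not (row.id_a in k1 and row.id_b in k1)


def test_prune_unknown_individual_is_error():
    with pytest.raises(ValueError):
        prune_related(["A"], _pairs([("A", "Z", 0.5)]))


# -- BMI cleaning ------------------------------------------------------------

@pytest.mark.parametrize("values, expected", [
    ([14, 25, 30, 80], 27.5),
    ([15, 70], 42.5),   # inclusive bounds
    ([], np.nan),
    ([14.9, 70.1], np.nan),
])
def test_clean_bmi(values, expected):
    got = clean_bmi(values)
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == pytest.approx(expected)


# -- LD ----------------------------------------------------------------------

def test_ld_r2_identical_and_flipped_vectors():
    a = np.array([0, 1, 2, 1, 0, 2], dtype=float)
    assert ld_r2(a, a) == pytest.approx(1.0)
    assert ld_r2(a, 2 - a) == pytest.approx(1.0)


def test_ld_r2_independent_snps_near_zero():
    rng = np.random.default_rng(99)
    a = rng.binomial(2, 0.4, 10_000).astype(float)
    b = rng.binomial(2, 0.4, 10_000).astype(float)
    assert ld_r2(a, b) < 0.01


def test_ld_r2_pairwise_complete_and_errors():
    a = np.array([0, 1, 2, np.nan], dtype=float)
    b = np.array([0, 1, 2, 2], dtype=float)
    assert ld_r2(a, b) == pytest.approx(1.0)
    with pytest.raises(MonomorphicError):
        ld_r2(np.array([1.0, 1.0, 1.0]), b[:3])


@given(st.integers(0, 1_000_000))
def test_ld_r2_symmetric(seed):
    rng = np.random.default_rng(seed)
    a = rng.binomial(2, 0.3, 50).astype(float)
    b = rng.binomial(2, 0.5, 50).astype(float)
    if a.std() == 0 or b.std() == 0:
        return
    assert ld_r2(a, b) == pytest.approx(ld_r2(b, a))


@pytest.mark.parametrize("r2, expected", [
    (0.92, LdGroup.HIGH),
    (0.81, LdGroup.HIGH),
    (0.80, LdGroup.MODERATE),  # boundary: 0.80 >= r2 > 0.60 is moderate
    (0.61, LdGroup.MODERATE),
    (0.60, LdGroup.LOW),       # boundary: r2 <= 0.60 is low
    (0.0, LdGroup.LOW),
])
def test_ld_group_boundaries(r2, expected):
    assert ld_group(r2) == expected


def test_ld_group_out_of_range():
    with pytest.raises(ValueError):
        ld_group(1.2)
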
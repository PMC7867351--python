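import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilmatch import (
    DimensionError,
    QuerySample,
    ReferenceDatabase,
    SoilRecord,
    euclidean_distance,
    features_of,
    find_reference,
    normalize_for_display,
)

from conftest import TABLE2_ROWS, row_vector

coord = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False)
vec8 = st.lists(coord, min_size=8, max_size=8)


def query_from_vector(v, name=None):
    return QuerySample(ra=abs(v[0]), t2=abs(v[1]), t3=abs(v[2]), d250=abs(v[3]),
                       humus=abs(v[4]), ph=min(abs(v[5]) % 14, 14), clay=abs(v[6]),
                       sand=abs(v[7]), name=name)


def brute_force_match(db, query):
    """Independent exhaustive scan: plain python, first minimal index."""
    qv = [getattr(query, f) for f in ("ra", "t2", "t3", "d250", "humus", "ph", "clay", "sand")]
    best_i, best_d = 0, float("inf")
    for i, r in enumerate(db):
        rv = [getattr(r, f) for f in ("ra", "t2", "t3", "d250", "humus", "ph", "clay", "sand")]
        d = math.sqrt(sum((a - b) ** 2 for a, b in zip(rv, qv)))
        if d < best_d:
            best_i, best_d = i, d
    return best_i, best_d


class TestFeaturesOf:
    def test_canonical_order(self, table2_db):
        assert features_of(table2_db[0]).tolist() == [
            108.79, 90.78, 78.55, 0.25, 0.38, 8.0, 6.7, 90.4
        ]

    def test_name_excluded(self, table2_db):
        a = table2_db[0]
        b = SoilRecord(ra=a.ra, t2=a.t2, t3=a.t3, d250=a.d250, humus=a.humus,
                       ph=a.ph, clay=a.clay, sand=a.sand, name="other")
        assert np.array_equal(features_of(a), features_of(b))


class TestEuclideanDistance:
    def test_identity(self, table2_db):
        v = features_of(table2_db[0])
        assert euclidean_distance(v, v) == 0.0

    def test_three_four_five(self):
        p = [0.0] * 8
        q = [3.0, 4.0, 0, 0, 0, 0, 0, 0]
        assert euclidean_distance(p, q) == 5.0

    def test_table2_rows_1_2(self):
        # independent term-by-term oracle, frozen: sum of squares = 297.8991
        p, q = row_vector(TABLE2_ROWS[0]), row_vector(TABLE2_ROWS[1])
        sumsq = sum((a - b) ** 2 for a, b in zip(p, q))
        assert sumsq == pytest.approx(297.8991, rel=1e-12)
        d = euclidean_distance(p, q)
        assert d == pytest.approx(math.sqrt(297.8991), rel=1e-12)
        assert round(d, 2) == 17.26

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            euclidean_distance([1, 2, 3], [1, 2])

    @given(vec8, vec8)
    @settings(max_examples=300)
    def test_symmetry_and_nonnegativity(self, p, q):
        d = euclidean_distance(p, q)
        assert d >= 0.0
        assert d == euclidean_distance(q, p)
        if p == q:
            assert d == 0.0

    @given(vec8, vec8, vec8)
    @settings(max_examples=300)
    def test_triangle_inequality(self, p, q, r):
        assert euclidean_distance(p, r) <= (
            euclidean_distance(p, q) + euclidean_distance(q, r) + 1e-7
        )


class TestFindReference:
    def test_self_match_each_row(self, table2_db):
        for i, record in enumerate(table2_db):
            q = QuerySample(**{f: getattr(record, f) for f in
                               ("ra", "t2", "t3", "d250", "humus", "ph", "clay", "sand")})
            result = find_reference(table2_db, q)
            # duplicated feature vectors match the earliest holder
            expected_i, _ = brute_force_match(table2_db, q)
            assert result.index == expected_i
            assert result.distance == 0.0

    def test_identity_match_row4(self, table2_db):
        q = QuerySample(ra=104.95, t2=101.59, t3=71.93, d250=0.48, humus=0.55,
                        ph=5.3, clay=8.5, sand=81.7)
        result = find_reference(table2_db, q)
        assert result.index == 3
        assert result.reference.name == "light loam"
        assert result.distance == 0.0

    def test_perturbed_query_still_sand(self, table2_db):
        q = QuerySample(ra=109.0, t2=90.78, t3=78.55, d250=0.25, humus=0.38,
                        ph=8.0, clay=6.7, sand=90.4)
        result = find_reference(table2_db, q)
        bf_i, bf_d = brute_force_match(table2_db, q)
        assert (result.index, result.distance) == (bf_i, pytest.approx(bf_d))
        assert result.index == 0
        assert result.reference.name == "sand"
        assert result.distance == pytest.approx(0.21)

    def test_tie_breaks_to_lowest_index(self, table2_db):
        dup = table2_db[1]
        db = ReferenceDatabase(records=(table2_db[0], dup, table2_db[2], dup))
        q = QuerySample(**{f: getattr(dup, f) for f in
                           ("ra", "t2", "t3", "d250", "humus", "ph", "clay", "sand")})
        result = find_reference(db, q)
        assert result.index == 1
        assert result.distance == 0.0

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(1, 30)
            records = tuple(
                SoilRecord(ra=rng.uniform(0, 200), t2=rng.uniform(0, 150),
                           t3=rng.uniform(0, 150), d250=rng.uniform(0, 3),
                           humus=rng.uniform(0, 10), ph=rng.uniform(3, 9),
                           clay=rng.uniform(0, 60), sand=rng.uniform(0, 95),
                           name=f"r{i}")
                for i in range(n)
            )
            db = ReferenceDatabase(records=records)
            q = QuerySample(ra=rng.uniform(0, 200), t2=rng.uniform(0, 150),
                            t3=rng.uniform(0, 150), d250=rng.uniform(0, 3),
                            humus=rng.uniform(0, 10), ph=rng.uniform(3, 9),
                            clay=rng.uniform(0, 60), sand=rng.uniform(0, 95))
            result = find_reference(db, q)
            bf_i, bf_d = brute_force_match(db, q)
            assert result.index == bf_i
            assert result.distance == pytest.approx(bf_d, rel=1e-12)

    def test_permutation_covariance(self, table2_db):
        q = QuerySample(ra=109.0, t2=90.78, t3=78.55, d250=0.25, humus=0.38,
                        ph=8.0, clay=6.7, sand=90.4)
        base = find_reference(table2_db, q)
        perm = [2, 0, 3, 1]
        db2 = ReferenceDatabase(records=tuple(table2_db[i] for i in perm))
        result = find_reference(db2, q)
        assert result.index == perm.index(base.index)
        assert result.reference == base.reference

    def test_standardize_changes_scaling_not_contract(self, table2_db):
        q = QuerySample(ra=104.95, t2=101.59, t3=71.93, d250=0.48, humus=0.55,
                        ph=5.3, clay=8.5, sand=81.7)
        result = find_reference(table2_db, q, standardize=True)
        assert result.index == 3 and result.distance == pytest.approx(0.0, abs=1e-12)

    def test_standardize_zero_variance_dropped(self, caplog):
        records = tuple(
            SoilRecord(ra=100.0, t2=t2, t3=80.0, d250=0.3, humus=1.0, ph=7.0,
                       clay=10.0, sand=70.0, name=f"r{i}")
            for i, t2 in enumerate([60.0, 90.0])
        )
        db = ReferenceDatabase(records=records)
        q = QuerySample(ra=100.0, t2=88.0, t3=80.0, d250=0.3, humus=1.0, ph=7.0,
                        clay=10.0, sand=70.0)
        with caplog.at_level("WARNING", logger="soilmatch.matcher"):
            result = find_reference(db, q, standardize=True)
        assert result.index == 1
        assert any("zero-variance" in m for m in caplog.messages)


class TestNormalizeForDisplay:
    def test_self_normalization(self, table2_db):
        pairs = normalize_for_display(table2_db[0], table2_db[0])
        for p in pairs:
            assert p.reference_pct == 100.0
            assert p.query_pct == 100.0

    def test_doubled_d250(self, table2_db):
        q = QuerySample(ra=108.79, t2=90.78, t3=78.55, d250=0.50, humus=0.38,
                        ph=8.0, clay=6.7, sand=90.4)
        pairs = {p.feature: p for p in normalize_for_display(table2_db[0], q)}
        assert pairs["d250"].reference_pct == 100.0
        assert pairs["d250"].query_pct == pytest.approx(200.0)

    def test_zero_reference_flagged(self):
        ref = SoilRecord(ra=100.0, t2=90.0, t3=80.0, d250=0.3, humus=0.0, ph=7.0,
                         clay=10.0, sand=70.0, name="degenerate")
        q = QuerySample(ra=100.0, t2=90.0, t3=80.0, d250=0.3, humus=2.0, ph=7.0,
                        clay=10.0, sand=70.0)
        pairs = {p.feature: p for p in normalize_for_display(ref, q)}
        hp = pairs["humus"]
        assert not hp.normalizable
        assert hp.reference_pct is None and hp.query_pct is None
        assert hp.reference == 0.0 and hp.query == 2.0
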
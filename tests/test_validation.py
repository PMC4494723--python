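"""Point-in-polygon validation, sample sizing, QA sampling and error rates."""

import math
from statistics import NormalDist

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_record
from tweetregion.triangulation import classify_users, default_criteria
from tweetregion.validation import (
    QASample,
    ValidationReport,
    draw_sample,
    gps_validation_report,
    load_region_polygons,
    point_in_region,
    qa_error_rate,
    required_sample_size,
)

UNIT_SQUARE = {
    "type": "FeatureCollection",
    "features": [
        {
            "type": "Feature",
            "properties": {"region_id": "sq"},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]],
            },
        }
    ],
}

# a square with a square hole, to exercise even-odd ring nesting
HOLED = {
    "type": "FeatureCollection",
    "features": [
        {
            "type": "Feature",
            "properties": {"region_id": "ring"},
            "geometry": {
                "type": "Polygon",
                "coordinates": [
                    [[0, 0], [4, 0], [4, 4], [0, 4], [0, 0]],
                    [[1, 1], [3, 1], [3, 3], [1, 3], [1, 1]],
                ],
            },
        }
    ],
}


def brute_force_inside(x, y, coordinates):
    """Independent even-odd ray casting over raw GeoJSON rings (boundary in)."""
    inside = False
    for ring in coordinates:
        pts = ring
        for (x1, y1), (x2, y2) in zip(pts, pts[1:]):
            cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
            if (
                abs(cross) < 1e-12
                and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12
            ):
                return True
            if (y1 > y) != (y2 > y) and x < x1 + (y - y1) * (x2 - x1) / (y2 - y1):
                inside = not inside
    return inside


class TestPointInRegion:
    def test_centroid_of_unit_square_inside(self):
        polys = load_region_polygons(UNIT_SQUARE)
        assert point_in_region(0.5, 0.5, polys) == "sq"

    def test_origin_outside_two_state_fixtures(self, region_polygons):
        assert point_in_region(0.0, 0.0, region_polygons) is None

    def test_boundary_point_counts_as_inside(self):
        polys = load_region_polygons(UNIT_SQUARE)
        assert point_in_region(0.0, 0.5, polys) == "sq"
        assert point_in_region(1.0, 1.0, polys) == "sq"

    def test_hole_is_outside(self):
        polys = load_region_polygons(HOLED)
        assert point_in_region(2.0, 2.0, polys) is None
        assert point_in_region(0.5, 0.5, polys) == "ring"
        assert point_in_region(1.0, 2.0, polys) == "ring"  # hole boundary

    def test_out_of_range_coordinates_rejected(self, region_polygons):
        with pytest.raises(ValueError):
            point_in_region(0.0, 95.0, region_polygons)

    def test_matches_brute_force_on_random_points(self, region_polygons):
        rng = np.random.default_rng(123)
        fixtures = {
            "holed": HOLED["features"][0]["geometry"]["coordinates"],
        }
        polys = load_region_polygons(HOLED)
        for _ in range(1000):
            x = float(rng.uniform(-1, 5))
            y = float(rng.uniform(-1, 5))
            expected = brute_force_inside(x, y, fixtures["holed"])
            got = point_in_region(x, y, polys) is not None
            assert got == expected, (x, y)

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        base = load_region_polygons(UNIT_SQUARE)
        dx, dy = 7.25, -3.5
        shifted_geo = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"region_id": "sq"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[x + dx, y + dy] for x, y in [[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]]
                        ],
                    },
                }
            ],
        }
        shifted = load_region_polygons(shifted_geo)
        for _ in range(200):
            x, y = float(rng.uniform(-1, 2)), float(rng.uniform(-1, 2))
            assert (point_in_region(x, y, base) is None) == (
                point_in_region(x + dx, y + dy, shifted) is None
            )


class TestValidationReport:
    def test_printed_tallies_combine_to_likely_regional(self):
        rep = ValidationReport.from_counts(
            gps_users=515, gps_confirmed_users=463, location_consistent_users=39
        )
        assert rep.likely_regional_users == 502
        assert rep.likely_regional_accuracy_pct == pytest.approx(100 * 502 / 515)

    def test_all_confirmed_is_hundred_percent(self):
        rep = ValidationReport.from_counts(10, 10, 0)
        assert rep.likely_regional_accuracy_pct == 100.0

    def test_zero_gps_users_flags_undefined_accuracy(self):
        rep = ValidationReport.from_counts(0, 0, 0)
        assert rep.likely_regional_accuracy_pct is None

    def test_count_inequalities_enforced(self):
        with pytest.raises(ValueError):
            ValidationReport.from_counts(5, 6, 0)
        with pytest.raises(ValueError):
            ValidationReport.from_counts(5, 3, 4)
        with pytest.raises(ValueError):
            ValidationReport.from_counts(5, 5, 0, gps_tweets=1, gps_tweets_in_region=2)


class TestGpsValidationReport:
    def test_planted_corpus_bookkeeping(self, region_polygons):
        criteria = default_criteria()
        recs = [
            # confirmed: geotag inside MS
            make_record(tweet_id="1", user_id="a", bio="Hattiesburg", geo=(31.3, -89.3)),
            make_record(tweet_id="2", user_id="a", geo=(40.0, -97.0)),
            # unconfirmed but location-consistent
            make_record(
                tweet_id="3",
                user_id="b",
                bio="Hattiesburg",
                location_string="Hattiesburg, MS",
                geo=(40.0, -97.0),
            ),
            # unconfirmed, inconsistent
            make_record(
                tweet_id="4", user_id="c", bio="Alabama", location_string="Oslo",
                geo=(40.0, -97.0),
            ),
            # regional but no geotags at all
            make_record(tweet_id="5", user_id="d", bio="Mississippi"),
        ]
        assignments = classify_users(recs, criteria)
        assert all(a.is_regional for a in assignments)
        rep = gps_validation_report(assignments, recs, region_polygons, criteria)
        assert rep.gps_users == 3
        assert rep.gps_confirmed_users == 1
        assert rep.location_consistent_users == 1
        assert rep.likely_regional_users == 2
        assert rep.gps_tweets == 4
        assert rep.gps_tweets_in_region == 1
        assert rep.likely_regional_accuracy_pct == pytest.approx(100 * 2 / 3)


class TestRequiredSampleSize:
    def test_matches_independent_quantile_closed_form(self):
        # stdlib NormalDist is the independent quantile oracle
        z = NormalDist().inv_cdf(0.995)
        n0 = z * z * 0.25 / 0.03**2
        assert math.ceil(n0) == 1844
        assert required_sample_size(10**9, 0.99, 0.03) == 1844

    @pytest.mark.parametrize(
        "population,confidence,moe",
        [
            (100, 0.95, 0.05),
            (1000, 0.95, 0.03),
            (8423, 0.99, 0.03),
            (41458, 0.90, 0.01),
            (515, 0.99, 0.03),
        ],
    )
    def test_grid_against_closed_form(self, population, confidence, moe):
        z = NormalDist().inv_cdf(0.5 + confidence / 2)
        n0 = z * z * 0.25 / moe**2
        n = n0 / (1 + (n0 - 1) / population)
        assert required_sample_size(population, confidence, moe) == min(
            population, math.ceil(n)
        )

    def test_capped_at_population(self):
        assert required_sample_size(100, 0.99, 0.03) <= 100

    def test_fpc_vanishes_for_large_populations(self):
        z = NormalDist().inv_cdf(0.995)
        n0 = math.ceil(z * z * 0.25 / 0.03**2)
        assert required_sample_size(10**12, 0.99, 0.03) == n0

    @settings(max_examples=50, deadline=None)
    @given(
        population=st.integers(10, 10**6),
        confidence=st.floats(0.5, 0.999),
        moe=st.floats(0.005, 0.2),
    )
    def test_monotone_in_moe_and_confidence(self, population, confidence, moe):
        n = required_sample_size(population, confidence, moe)
        assert required_sample_size(population, confidence, min(0.4, moe * 2)) <= n
        assert required_sample_size(population, confidence**2, moe) <= n

    def test_out_of_range_arguments_rejected(self):
        for args in [(0, 0.99, 0.03), (10, 1.0, 0.03), (10, 0.99, 0.0), (10, 0.99, 0.03, 1.5)]:
            with pytest.raises(ValueError):
                required_sample_size(*args)


class TestDrawSample:
    IDS = [f"u{i}" for i in range(20)]

    def test_full_draw_returns_every_id(self):
        s = draw_sample(self.IDS, len(self.IDS), seed=3)
        assert sorted(s.sampled_user_ids) == sorted(self.IDS)

    def test_same_seed_reproduces_sample(self):
        a = draw_sample(self.IDS, 7, seed=42)
        b = draw_sample(self.IDS, 7, seed=42)
        assert a.sampled_user_ids == b.sampled_user_ids

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            draw_sample(self.IDS, 21, seed=0)

    def test_inclusion_probability_is_uniform(self):
        ids = [f"u{i}" for i in range(5)]
        hits = {u: 0 for u in ids}
        n_draws = 10_000
        for seed in range(n_draws):
            for u in draw_sample(ids, 2, seed=seed).sampled_user_ids:
                hits[u] += 1
        expected = n_draws * 2 / 5
        for u, h in hits.items():
            assert abs(h - expected) < 4 * math.sqrt(expected), (u, h)


class TestQaErrorRate:
    def _sample(self, n, fails):
        ids = tuple(f"u{i}" for i in range(n))
        judgments = {u: ("fail" if i < fails else "pass") for i, u in enumerate(ids)}
        return QASample(ids, "regional", seed=0, judgments=judgments)

    def test_zero_fails_is_zero_rate(self):
        rate, (lo, hi) = qa_error_rate(self._sample(900, 0))
        assert rate == 0.0
        assert lo == pytest.approx(0.0, abs=1e-12) and hi > 0.0

    def test_two_fails_of_900(self):
        rate, _ = qa_error_rate(self._sample(900, 2))
        assert rate == pytest.approx(2 / 900)

    def test_single_fail_sample(self):
        rate, _ = qa_error_rate(self._sample(1, 1))
        assert rate == 1.0

    def test_wilson_interval_matches_closed_form(self):
        n, k, conf = 900, 2, 0.99
        rate, (lo, hi) = qa_error_rate(self._sample(n, k), confidence=conf)
        z = NormalDist().inv_cdf(0.5 + conf / 2)
        p = k / n
        centre = (p + z * z / (2 * n)) / (1 + z * z / n)
        half = (
            z
            * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
            / (1 + z * z / n)
        )
        assert lo == pytest.approx(centre - half, abs=1e-10)
        assert hi == pytest.approx(centre + half, abs=1e-10)

    def test_missing_judgments_rejected(self):
        s = QASample(("a", "b"), "regional", 0, {"a": "pass"})
        with pytest.raises(ValueError, match="missing judgments"):
            qa_error_rate(s)
        with pytest.raises(ValueError, match="no judgments"):
            qa_error_rate(QASample(("a",), "regional", 0))
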
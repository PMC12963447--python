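"""Pair/triplet risk ratios, exact test, filters, timing, network builders."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from morbinet.networks import (
    FilterConfig,
    apply_filters,
    build_disease_centred,
    build_general_network,
    chronic_onsets,
    classify_timing,
    compute_pair_stats,
    count_pairs,
    count_triplet,
    onset_summary,
    pair_frequency_table,
    pair_pvalue,
    rr_pair,
    rr_triplet,
    triad_frequency_table,
)


def _onsets(rows):
    frame = pd.DataFrame(rows, columns=["patient_id", "group_id", "onset_date"])
    frame["onset_date"] = pd.to_datetime(frame["onset_date"])
    return frame


def _random_onsets(rng, n_patients, groups, p=0.3):
    rows = []
    for i in range(n_patients):
        for g in groups:
            if rng.random() < p:
                day = rng.integers(0, 3650)
                rows.append((f"p{i}", g, pd.Timestamp("2010-01-01") + pd.Timedelta(int(day), "D")))
    return _onsets(rows)


def brute_force_pairs(onsets, n_total):
    """Independent per-patient enumeration of all pair counts."""
    by_patient = {
        pid: dict(zip(g["group_id"], g["onset_date"]))
        for pid, g in onsets.groupby("patient_id")
    }
    groups = sorted(onsets["group_id"].unique())
    margin = {g: sum(g in d for d in by_patient.values()) for g in groups}
    rows = []
    for a, b in itertools.combinations(groups, 2):
        n_ab = n_ab_dir = n_ba_dir = 0
        for d in by_patient.values():
            if a in d and b in d:
                n_ab += 1
                if d[a] < d[b]:
                    n_ab_dir += 1
                elif d[b] < d[a]:
                    n_ba_dir += 1
        if n_ab:
            rows.append((a, b, margin[a], margin[b], n_ab, n_ab_dir, n_ba_dir, n_total))
    return pd.DataFrame(
        rows, columns=["a", "b", "n_a", "n_b", "n_ab", "n_dir_ab", "n_dir_ba", "n_total"]
    )


class TestCountPairs:
    def test_hand_counted_example(self):
        ons = _onsets(
            [
                ("p1", "A", "2014-01-01"),
                ("p1", "B", "2015-01-01"),
                ("p2", "A", "2013-05-01"),
                ("p2", "B", "2016-01-01"),
                ("p3", "B", "2014-01-01"),
            ]
        )
        stats = count_pairs(ons, 3)
        row = stats.iloc[0]
        assert (row["n_ab"], row["n_dir_ab"], row["n_dir_ba"]) == (2, 2, 0)
        assert (row["n_a"], row["n_b"]) == (2, 3)

    def test_same_day_tie_counts_cooccurrence_only(self):
        ons = _onsets([("p1", "A", "2014-01-01"), ("p1", "B", "2014-01-01")])
        row = count_pairs(ons, 1).iloc[0]
        assert row["n_ab"] == 1 and row["n_dir_ab"] == 0 and row["n_dir_ba"] == 0

    def test_duplicate_onset_rejected(self):
        ons = _onsets([("p1", "A", "2014-01-01"), ("p1", "A", "2015-01-01")])
        with pytest.raises(ValueError, match="duplicate"):
            count_pairs(ons, 1)

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(3)
        ons = _random_onsets(rng, 50, [f"G{i}" for i in range(8)])
        got = count_pairs(ons, 50).sort_values(["a", "b"]).reset_index(drop=True)
        want = brute_force_pairs(ons, 50).sort_values(["a", "b"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want, check_dtype=False)


class TestRiskRatios:
    def test_independence_expectation_is_one(self):
        assert rr_pair(10, 100, 100, 1000) == pytest.approx(1.0)

    def test_direct_substitution(self):
        assert rr_pair(20, 40, 50, 200) == pytest.approx(2.0)

    def test_empty_overlap_zero(self):
        assert rr_pair(0, 40, 50, 200) == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            rr_pair(0, 0, 50, 200)

    def test_triplet_unit_expectation(self):
        assert rr_triplet(1, 100, 100, 100, 1000) == pytest.approx(1.0)

    def test_triplet_zero_and_random_fixtures_match_rational_oracle(self):
        assert rr_triplet(0, 10, 10, 10, 100) == 0.0
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(10, 10_000))
            na, nb, nc = (int(rng.integers(1, n)) for _ in range(3))
            nabc = int(rng.integers(0, min(na, nb, nc) + 1))
            oracle = Fraction(nabc) * Fraction(n) ** 2 / (Fraction(na) * nb * nc)
            assert rr_triplet(nabc, na, nb, nc, n) == pytest.approx(float(oracle), rel=1e-12)

    def test_pair_rr_matches_rational_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(10, 10_000))
            na, nb = int(rng.integers(1, n)), int(rng.integers(1, n))
            nab = int(rng.integers(0, min(na, nb) + 1))
            oracle = Fraction(nab) * n / (Fraction(na) * nb)
            assert rr_pair(nab, na, nb, n) == pytest.approx(float(oracle), rel=1e-12)


class TestPairPvalue:
    def test_forced_cooccurrence_p_one(self):
        # everyone has A, so observing n_ab = n_b is certain
        assert pair_pvalue(10, 20, 10, 20) == pytest.approx(1.0)

    def test_maximal_overlap_equals_point_mass(self):
        from scipy.stats import hypergeom

        p = pair_pvalue(10, 10, 10, 20)
        assert p == pytest.approx(hypergeom.pmf(10, 20, 10, 10))

    def test_tail_matches_pmf_enumeration(self):
        from scipy.stats import hypergeom

        N, na, nb = 30, 12, 9
        for nab in range(0, 10):
            enum = sum(hypergeom.pmf(k, N, na, nb) for k in range(nab, min(na, nb) + 1))
            assert pair_pvalue(nab, na, nb, N) == pytest.approx(enum, rel=1e-10)

    def test_monotone_non_increasing_in_overlap(self):
        ps = [float(pair_pvalue(k, 12, 9, 30)) for k in range(10)]
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


class TestFilters:
    def _stats(self, rows):
        frame = pd.DataFrame(rows, columns=["a", "b", "n_ab", "p"])
        frame["n_a"] = frame["n_b"] = 1000
        frame["n_total"] = 10_000
        frame["rr"] = 1.0
        return frame

    def test_min_count_strictly_more_than_50(self):
        stats = self._stats([("A", "B", 50, 1e-10), ("A", "C", 51, 1e-10)])
        retained, meta = apply_filters(stats)
        assert list(retained["b"]) == ["C"]

    def test_bonferroni_threshold_is_alpha_over_m(self):
        stats = self._stats([("A", f"G{i}", 60, 0.5) for i in range(10)])
        _, meta = apply_filters(stats, FilterConfig(alpha=0.05))
        assert meta["m"] == 10
        assert meta["threshold"] == pytest.approx(0.005)

    def test_null_fixture_false_retention_rate_below_alpha(self):
        """Independent conditions: across replicates, the rate of pairs that
        survive the Bonferroni screen stays at or below alpha."""
        rng = np.random.default_rng(8)
        n_retained = n_evaluated = 0
        for _ in range(15):
            ons = _random_onsets(rng, 400, [f"G{i}" for i in range(6)], p=0.4)
            stats = compute_pair_stats(ons, 400)
            retained, _ = apply_filters(stats, FilterConfig(alpha=0.05, min_n=0))
            n_retained += len(retained)
            n_evaluated += len(stats)
        assert n_retained / n_evaluated <= 0.05


class TestTiming:
    def _transitions(self, mapping):
        return pd.DataFrame(
            {
                "patient_id": list(mapping),
                "transition_date": pd.to_datetime([mapping[k] for k in mapping]),
            }
        )

    def test_unanimous_pre(self):
        ons = _onsets(
            [
                ("p1", "A", "2014-01-01"),
                ("p1", "B", "2015-01-01"),
                ("p2", "A", "2013-01-01"),
                ("p2", "B", "2014-06-01"),
            ]
        )
        tr = self._transitions({"p1": "2018-01-01", "p2": "2016-01-01"})
        label, fr = classify_timing(ons, tr, "A", "B")
        assert label == "pre" and fr["pre"] == 1.0 and fr["n"] == 2

    def test_even_split_is_mixed(self):
        ons = _onsets(
            [
                ("p1", "A", "2014-01-01"),
                ("p1", "B", "2015-01-01"),
                ("p2", "A", "2019-01-01"),
                ("p2", "B", "2020-01-01"),
            ]
        )
        tr = self._transitions({"p1": "2018-01-01", "p2": "2016-01-01"})
        label, fr = classify_timing(ons, tr, "A", "B", theta=2 / 3)
        assert label == "mixed"
        assert fr["pre"] == fr["post"] == 0.5

    def test_spanning_and_never_transition(self):
        ons = _onsets(
            [
                ("p1", "A", "2014-01-01"),
                ("p1", "B", "2019-01-01"),  # spans p1's 2016 transition
                ("p2", "A", "2014-01-01"),
                ("p2", "B", "2015-01-01"),  # p2 never transitions -> pre
            ]
        )
        tr = self._transitions({"p1": "2016-01-01"})
        label, fr = classify_timing(ons, tr, "A", "B")
        assert fr["spanning"] == 0.5 and fr["pre"] == 0.5
        label_drop, fr_drop = classify_timing(
            ons, tr, "A", "B", never_transition="drop"
        )
        assert fr_drop["spanning"] == 1.0 and label_drop == "mixed"

    def test_fractions_match_hand_scan_on_random_fixture(self):
        rng = np.random.default_rng(5)
        ons = _random_onsets(rng, 30, ["A", "B", "C"], p=0.7)
        tdates = {
            f"p{i}": pd.Timestamp("2012-01-01") + pd.Timedelta(int(rng.integers(0, 3000)), "D")
            for i in range(30)
            if rng.random() < 0.5
        }
        tr = self._transitions({k: str(v.date()) for k, v in tdates.items()})
        label, fr = classify_timing(ons, tr, "A", "B")
        # independent scan
        by_patient = {
            pid: dict(zip(g["group_id"], g["onset_date"]))
            for pid, g in ons.groupby("patient_id")
        }
        pre = post = span = n = 0
        for pid, d in by_patient.items():
            if "A" in d and "B" in d and d["A"] < d["B"]:
                n += 1
                t = tdates.get(pid)
                if t is None or d["B"] < t:
                    pre += 1
                elif d["A"] >= t:
                    post += 1
                else:
                    span += 1
        assert n == fr["n"]
        assert fr["pre"] == pytest.approx(pre / n)
        assert fr["post"] == pytest.approx(post / n)
        assert fr["spanning"] == pytest.approx(span / n)

    def test_no_support_returns_none(self):
        ons = _onsets([("p1", "A", "2014-01-01"), ("p2", "B", "2014-01-01")])
        label, fr = classify_timing(ons, self._transitions({}), "A", "B")
        assert label is None and fr["n"] == 0


@pytest.fixture(scope="module")
def planted_cohort_stats():
    rng = np.random.default_rng(17)
    groups = [f"G{i}" for i in range(10)]
    rows = []
    for i in range(800):
        has_g0 = rng.random() < 0.5
        for g in groups:
            p = 0.35
            if g == "G0":
                p = 1.0 if has_g0 else 0.0
            elif g == "G1" and has_g0:
                p = 0.9  # planted dominant pair G0 -> G1
            if rng.random() < p:
                base_day = 0 if g == "G0" else 1000
                day = base_day + int(rng.integers(0, 1000))
                rows.append((f"p{i}", g, pd.Timestamp("2008-01-01") + pd.Timedelta(day, "D")))
    ons = _onsets(rows)
    stats = compute_pair_stats(ons, 800)
    return ons, stats


class TestNetworkBuilders:
    def test_shortfall_emits_all_with_warning(self, caplog):
        ons = _onsets(
            [
                ("p1", "A", "2014-01-01"),
                ("p1", "B", "2015-01-01"),
                ("p2", "B", "2013-01-01"),
                ("p2", "C", "2015-01-01"),
            ]
        )
        stats = compute_pair_stats(ons, 2)
        with caplog.at_level("WARNING"):
            net = build_general_network(stats, ons, 2, k_primary=30)
        assert len(net.edges) == 2
        assert "30 primary slots" in caplog.text

    def test_secondary_tier_requires_primary_disease(self, planted_cohort_stats):
        ons, stats = planted_cohort_stats
        retained, _ = apply_filters(stats, FilterConfig(min_n=0, alpha=1e9))
        net = build_general_network(retained, ons, 800, k_primary=3, k_secondary=5)
        tier1 = net.edges.loc[net.edges["tier"] == "primary"]
        primary = set(tier1["source"]) | set(tier1["target"])
        tier2 = net.edges.loc[net.edges["tier"] == "secondary"]
        assert all(
            (r.source in primary) or (r.target in primary) for r in tier2.itertuples()
        )

    def test_width_endpoints_normalised_1_to_10(self, planted_cohort_stats):
        ons, stats = planted_cohort_stats
        retained, _ = apply_filters(stats, FilterConfig(min_n=0, alpha=1e9))
        net = build_general_network(retained, ons, 800, k_primary=10, k_secondary=10)
        counts = net.edges["n_directed"]
        widths = net.edges["width"]
        assert widths[counts.idxmax()] == pytest.approx(10.0)
        assert widths[counts.idxmin()] == pytest.approx(1.0)
        assert widths.between(1, 10).all()

    def test_graphml_and_json_exports(self, planted_cohort_stats, tmp_path):
        import networkx as nx

        ons, stats = planted_cohort_stats
        retained, _ = apply_filters(stats, FilterConfig(min_n=0, alpha=1e9))
        net = build_general_network(retained, ons, 800, k_primary=5, k_secondary=5)
        path = tmp_path / "net.graphml"
        net.write_graphml(path)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == len(net.edges)
        d = net.to_json_dict()
        assert set(d) == {"meta", "nodes", "edges"}

    def test_disease_centred_secondary_count_and_exclusions(self, planted_cohort_stats):
        ons, stats = planted_cohort_stats
        retained, _ = apply_filters(stats, FilterConfig(min_n=0, alpha=1e9))
        net = build_disease_centred("G0", retained, ons, 800, k_secondary=3, k_tertiary=5)
        sec = net.edges.loc[net.edges["tier"] == "secondary"]
        assert len(sec) == 3
        ter = net.edges.loc[net.edges["tier"] == "tertiary"]
        assert not ((ter["source"] == "G0") | (ter["target"] == "G0")).any()

    def test_disease_centred_absent_central_rejected(self, planted_cohort_stats):
        ons, stats = planted_cohort_stats
        with pytest.raises(ValueError, match="absent"):
            build_disease_centred("ZZ", stats, ons, 800)

    def test_tertiary_ranking_matches_exhaustive_triplet_sort(self, planted_cohort_stats):
        ons, stats = planted_cohort_stats
        retained, _ = apply_filters(stats, FilterConfig(min_n=0, alpha=1e9))
        central = "G0"
        net = build_disease_centred(central, retained, ons, 800, k_secondary=3, k_tertiary=5)
        secondary_ids = {
            (r.source if r.target == central else r.target)
            for r in net.edges.loc[net.edges["tier"] == "secondary"].itertuples()
        }
        wide = ons.pivot(index="patient_id", columns="group_id", values="onset_date")
        margins = {g: int(wide[g].notna().sum()) for g in wide.columns}
        # brute-force: every directed pair touching a secondary, not central
        cands = []
        for r in retained.itertuples():
            for s, t, nd in ((r.a, r.b, r.n_dir_ab), (r.b, r.a, r.n_dir_ba)):
                if nd == 0 or central in (s, t):
                    continue
                if s not in secondary_ids and t not in secondary_ids:
                    continue
                n_abc = count_triplet(wide, central, s, t)
                trr = float(
                    rr_triplet(n_abc, margins[central], margins[s], margins[t], 800)
                )
                cands.append((trr, nd, s, t))
        cands.sort(key=lambda x: (-x[0], -x[1], x[2], x[3]))
        expected = [(s, t) for _, _, s, t in cands[:5]]
        ter = net.edges.loc[net.edges["tier"] == "tertiary"]
        assert list(zip(ter["source"], ter["target"])) == expected


class TestFrequencyTables:
    def test_pair_table_tie_break_lexicographic(self):
        stats = pd.DataFrame(
            {
                "a": ["B", "A"],
                "b": ["C", "D"],
                "n_ab": [5, 5],
                "n_a": [10, 10],
                "n_b": [10, 10],
                "n_total": [100, 100],
            }
        )
        table = pair_frequency_table(stats, 100, top_k=2)
        assert list(zip(table["a"], table["b"])) == [("A", "D"), ("B", "C")]
        assert table["pct"].tolist() == [5.0, 5.0]

    def test_triad_table_counts_and_percentages(self):
        ons = _onsets(
            [
                ("p1", "A", "2014-01-01"),
                ("p1", "B", "2015-01-01"),
                ("p1", "C", "2016-01-01"),
                ("p2", "A", "2014-01-01"),
                ("p2", "B", "2015-01-01"),
            ]
        )
        table = triad_frequency_table(ons, 4)
        assert len(table) == 1
        assert table.loc[0, "n_abc"] == 1
        assert table.loc[0, "pct"] == pytest.approx(25.0)

    def test_planted_pair_tops_the_table(self, planted_cohort_stats):
        ons, stats = planted_cohort_stats
        table = pair_frequency_table(stats, 800, top_k=3)
        assert (table.loc[0, "a"], table.loc[0, "b"]) == ("G0", "G1")


class TestOnsetSummary:
    def test_single_onset_single_cell(self, codemap):
        patients = pd.DataFrame(
            {
                "patient_id": ["p1"],
                "sex": ["F"],
                "birth_date": pd.to_datetime(["1970-01-01"]),
            }
        )
        ons = _onsets([("p1", "HTN", "2015-06-01")])  # age 45
        table = onset_summary(ons, patients, codemap)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["organ_system"], row["age_band"], row["sex"]) == (
            "circulatory",
            "40-60",
            "F",
        )
        assert row["n_onsets"] == 1

    def test_totals_conserved(self, cohort, mapped_events, codemap):
        patients, _ = cohort
        ons = chronic_onsets(mapped_events)
        table = onset_summary(ons, patients, codemap)
        assert table["n_onsets"].sum() == len(ons)
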
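"""Set-algebra screens: oracle equivalence and definitional examples."""

import numpy as np
import pandas as pd
import pytest

from conftest import deg_table_from_dict, random_deg_tables
from tsdnet.screens import (
    DEV_INTERVALS,
    SEX_DAYS,
    candidate_sexdev_screen,
    classify_timespan,
    development_dependent_degs,
    dimorphism_zscore_matrix,
    hierarchical_cluster,
    persistent_dimorphic,
    sex_dependent_degs,
    temperature_responsive_screen,
)


def _empty_dev_tables(universe):
    return {
        iv: deg_table_from_dict(f"iv{iv}", {}, universe) for iv in DEV_INTERVALS
    }


class TestDevelopmentScreen:
    def test_empty_tables_empty_sets(self):
        screen = development_dependent_degs(_empty_dev_tables(["g1", "g2"]))
        assert screen.union.genes == set()
        assert screen.multi_occasion == set()

    def test_two_interval_gene_is_multi_occasion(self):
        tables = _empty_dev_tables(["g1", "g2"])
        tables[(0, 3)] = deg_table_from_dict("a", {"g1": "up"}, ["g1", "g2"])
        tables[(6, 12)] = deg_table_from_dict("c", {"g1": "down"}, ["g1", "g2"])
        screen = development_dependent_degs(tables)
        assert screen.multi_occasion == {"g1"}
        assert screen.union.genes == {"g1"}

    def test_missing_interval_rejected(self):
        tables = _empty_dev_tables(["g1"])
        del tables[(3, 6)]
        with pytest.raises(ValueError):
            development_dependent_degs(tables)

    def test_matches_bruteforce_on_random_tables(self):
        """Union and multi-occasion sets equal naive re-derivation."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            universe, dev, _ = random_deg_tables(rng)
            screen = development_dependent_degs(dev["MPT"])
            sig = {
                iv: set(
                    dev["MPT"][iv].records.loc[
                        dev["MPT"][iv].records["significant"], "gene_id"
                    ]
                )
                for iv in DEV_INTERVALS
            }
            union = sig[(0, 3)] | sig[(3, 6)] | sig[(6, 12)]
            multi = {
                g for g in union
                if sum(g in sig[iv] for iv in DEV_INTERVALS) >= 2
            }
            assert screen.union.genes == union
            assert screen.multi_occasion == multi


class TestSexScreen:
    def test_day0_rejected(self):
        table = deg_table_from_dict("d0", {}, ["g"], ("FPT", 0), ("MPT", 0))
        with pytest.raises(ValueError):
            sex_dependent_degs({0: table})

    def test_direction_maps_to_temperature_bias(self):
        table = deg_table_from_dict(
            "d3", {"g1": "up", "g2": "down"}, ["g1", "g2", "g3"],
            ("FPT", 3), ("MPT", 3),
        )
        screen = sex_dependent_degs({3: table})[3]
        assert screen.directions == {"g1": "MPT-biased", "g2": "FPT-biased"}

    def test_wrong_orientation_rejected(self):
        table = deg_table_from_dict("d3", {}, ["g"], ("MPT", 3), ("FPT", 3))
        with pytest.raises(ValueError):
            sex_dependent_degs({3: table})


class TestPersistentDimorphic:
    def test_gene_missing_one_day_excluded(self):
        _, _, sex = random_deg_tables(np.random.default_rng(0))
        sets = sex_dependent_degs(sex)
        inter, _ = persistent_dimorphic(sets)
        for g in inter:
            assert all(g in sets[d] for d in SEX_DAYS)

    def test_matches_triple_loop(self):
        for seed in range(30):
            _, _, sex = random_deg_tables(np.random.default_rng(seed))
            sets = sex_dependent_degs(sex)
            inter, consistent = persistent_dimorphic(sets)
            brute = set()
            brute_consistent = set()
            for g in sets[3].genes:
                for h in sets[6].genes:
                    for k in sets[12].genes:
                        if g == h == k:
                            brute.add(g)
                            dirs = {sets[d].directions[g] for d in SEX_DAYS}
                            if len(dirs) == 1:
                                brute_consistent.add(g)
            assert inter == brute
            assert consistent == brute_consistent

    def test_empty_day_gives_empty_intersection(self):
        universe = ["g1", "g2"]
        sets = sex_dependent_degs(
            {
                3: deg_table_from_dict("a", {"g1": "up"}, universe, ("FPT", 3), ("MPT", 3)),
                6: deg_table_from_dict("b", {}, universe, ("FPT", 6), ("MPT", 6)),
                12: deg_table_from_dict("c", {"g1": "up"}, universe, ("FPT", 12), ("MPT", 12)),
            }
        )
        inter, _ = persistent_dimorphic(sets)
        assert inter == set()


class TestTemperatureResponsiveScreen:
    def test_gene_moving_in_both_arms_excluded(self):
        universe = ["g1", "g2"]
        mpt = deg_table_from_dict("m", {"g1": "up", "g2": "up"}, universe)
        fpt = deg_table_from_dict("f", {"g1": "up"}, universe, ("FPT", 0), ("FPT", 3))
        dim = sex_dependent_degs(
            {3: deg_table_from_dict("s", {"g2": "up"}, universe, ("FPT", 3), ("MPT", 3))}
        )[3]
        screen = temperature_responsive_screen(mpt, fpt, dim)
        assert screen.mpt_specific.genes == {"g2"}
        assert screen.responsive.genes == {"g2"}

    def test_subset_chain(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            universe, dev, sex = random_deg_tables(rng)
            dim = sex_dependent_degs(sex)[3]
            screen = temperature_responsive_screen(
                dev["MPT"][(0, 3)], dev["FPT"][(0, 3)], dim
            )
            mpt_sig = set(
                dev["MPT"][(0, 3)].records.loc[
                    dev["MPT"][(0, 3)].records["significant"], "gene_id"
                ]
            )
            assert screen.responsive.genes <= screen.mpt_specific.genes <= mpt_sig

    def test_mismatched_universes_rejected(self):
        mpt = deg_table_from_dict("m", {}, ["g1"])
        fpt = deg_table_from_dict("f", {}, ["g2"], ("FPT", 0), ("FPT", 3))
        dim = deg_table_from_dict("s", {}, ["g1"], ("FPT", 3), ("MPT", 3))
        with pytest.raises(ValueError):
            temperature_responsive_screen(
                mpt, fpt, sex_dependent_degs({3: dim})[3]
            )

    def test_matches_bruteforce(self):
        """mpt_specific and responsive equal the naive set expressions."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            universe, dev, sex = random_deg_tables(rng)
            dim = sex_dependent_degs(sex)[3]
            screen = temperature_responsive_screen(
                dev["MPT"][(0, 3)], dev["FPT"][(0, 3)], dim
            )
            m = dev["MPT"][(0, 3)].records
            f = dev["FPT"][(0, 3)].records
            sig_m = set(m.loc[m["significant"], "gene_id"])
            sig_f = set(f.loc[f["significant"], "gene_id"])
            assert screen.mpt_specific.genes == sig_m - sig_f
            assert screen.responsive.genes == (sig_m - sig_f) & dim.genes


class TestCandidateScreen:
    def test_empty_sex_sets_give_no_candidates(self):
        rng = np.random.default_rng(1)
        universe, dev, _ = random_deg_tables(rng)
        empty_sex = {
            d: sex_dependent_degs(
                {d: deg_table_from_dict(f"s{d}", {}, universe, ("FPT", d), ("MPT", d))}
            )[d]
            for d in SEX_DAYS
        }
        screens = {c: development_dependent_degs(dev[c]) for c in dev}
        result = candidate_sexdev_screen(screens, empty_sex)
        assert result.candidates.genes == set()

    def test_matches_bruteforce_enumeration(self):
        """Candidates equal the naive loop over (condition, interval)."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            universe, dev, sex = random_deg_tables(rng)
            dev_screens = {c: development_dependent_degs(dev[c]) for c in dev}
            sex_screens = sex_dependent_degs(sex)
            result = candidate_sexdev_screen(dev_screens, sex_screens)
            brute = set()
            for cond in ("MPT", "FPT"):
                for iv in DEV_INTERVALS:
                    recs = dev[cond][iv].records
                    sig = set(recs.loc[recs["significant"], "gene_id"])
                    brute |= sig & sex_screens[iv[1]].genes
            assert result.candidates.genes == brute

    def test_development_only_genes_excluded(self, small_dataset):
        """Planted development genes move in both arms: never dimorphic."""
        from tsdnet.diffexpr import ComparisonSpec, test_differential_expression as run_de
        from tsdnet.pipeline import adjacent_comparisons

        matrix, truth = small_dataset
        dev = {
            cond: {
                iv: run_de(matrix, spec)
                for spec, iv in zip(adjacent_comparisons(cond), DEV_INTERVALS)
            }
            for cond in ("MPT", "FPT")
        }
        sex = {
            d: run_de(matrix, ComparisonSpec(f"s{d}", ("FPT", d), ("MPT", d)))
            for d in SEX_DAYS
        }
        dev_screens = {c: development_dependent_degs(dev[c]) for c in dev}
        result = candidate_sexdev_screen(dev_screens, sex_dependent_degs(sex))
        dev_only = truth.genes_of_class("development_dependent")
        planted_both = truth.genes_of_class("candidate_both")
        assert len(result.candidates.genes & dev_only) == 0
        assert len(result.candidates.genes & planted_both) >= 0.9 * len(planted_both)


class TestClassifyTimespan:
    @pytest.mark.parametrize(
        "flags, expected",
        [
            ([1, 1, 1, 1, 1, 1], "Long"),
            ([1, 0, 0, 0, 0, 0], "Short"),
            ([1, 0, 1, 0, 0, 0], "Ambiguous"),
            ([0, 0, 0, 1, 1, 1], "Long"),
            ([0, 1, 1, 0, 0, 0], "Short"),
            ([0, 0, 0, 0, 0, 0], "none"),
        ],
    )
    def test_label_rules(self, flags, expected):
        frame = pd.DataFrame([flags], columns=[3, 6, 12, 18, 24, 30], index=["g"])
        assert classify_timespan(frame)["g"] == expected


class TestZScoreAndClustering:
    def test_row_123_standardizes_to_unit_steps(self):
        frame = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=[3, 6, 12])
        z = dimorphism_zscore_matrix(frame)
        np.testing.assert_allclose(z.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_and_infinite_rows_excluded(self):
        frame = pd.DataFrame(
            [[1.0, 1.0, 1.0], [np.inf, 0.0, 1.0], [0.0, 1.0, 2.0]],
            index=["flat", "inf", "ok"],
            columns=[3, 6, 12],
        )
        with pytest.warns(UserWarning):
            z = dimorphism_zscore_matrix(frame)
        assert list(z.index) == ["ok"]

    def test_identical_rows_merge_first(self):
        frame = pd.DataFrame(
            [[0.0, 1.0], [0.0, 1.0], [5.0, -3.0]],
            index=["a", "b", "c"],
            columns=[3, 6],
        )
        _, linkage, _ = hierarchical_cluster(frame)
        assert linkage[0, 2] == 0.0  # first merge at distance zero
        assert {int(linkage[0, 0]), int(linkage[0, 1])} == {0, 1}

    def test_matches_bruteforce_average_linkage(self):
        """scipy linkage equals a naive agglomerative implementation."""
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            rng.normal(size=(5, 3)),
            index=[f"g{i}" for i in range(5)],
            columns=[3, 6, 12],
        )
        _, linkage, _ = hierarchical_cluster(frame)

        # naive agglomeration: average linkage on Euclidean distance
        points = {i: [i] for i in range(5)}
        d = {
            (i, j): float(np.linalg.norm(frame.iloc[i] - frame.iloc[j]))
            for i in range(5)
            for j in range(i + 1, 5)
        }
        X = frame.to_numpy()

        def avg_dist(members_a, members_b):
            return float(
                np.mean(
                    [
                        np.linalg.norm(X[i] - X[j])
                        for i in members_a
                        for j in members_b
                    ]
                )
            )

        merges = []
        next_id = 5
        while len(points) > 1:
            best = min(
                (
                    (avg_dist(points[a], points[b]), a, b)
                    for a in points
                    for b in points
                    if a < b
                ),
            )
            dist, a, b = best
            merges.append((a, b, dist, len(points[a]) + len(points[b])))
            points[next_id] = points.pop(a) + points.pop(b)
            next_id += 1

        for row, (a, b, dist, size) in zip(linkage, merges):
            assert {int(row[0]), int(row[1])} == {a, b}
            assert row[2] == pytest.approx(dist)
            assert int(row[3]) == size

    def test_single_gene_rejected(self):
        frame = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=[3, 6])
        with pytest.raises(ValueError):
            hierarchical_cluster(frame)

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame(
            rng.normal(size=(4, 3)), index=list("abcd"), columns=[3, 6, 12]
        )
        leaves, _, newick = hierarchical_cluster(frame)
        assert sorted(leaves) == list("abcd")
        for leaf in "abcd":
            assert leaf in newick
        assert newick.endswith(";")
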
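"""Recurrence/hot-spot statistics, maintenance and transgenerational
classification, tally arithmetic and sample clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epimethyl.dynamics import (
    classify_maintenance,
    classify_transgenerational,
    cluster_samples,
    dendrogram_clades,
    expected_random_recurrence,
    recurrence_analysis,
    round_half_up,
    sibling_adjacency_score,
    tally_report,
)
from epimethyl.io import DesignError, SITE_KEY


def point_events(keys, direction="hyper"):
    """Event frame from (chrom,pos,strand) tuples or bare positions."""
    rows = []
    for k in keys:
        if isinstance(k, tuple):
            chrom, pos, strand = k
        else:
            chrom, pos, strand = "chr1", int(k), "+"
        rows.append({"chrom": chrom, "pos": pos, "strand": strand,
                     "direction": direction})
    return pd.DataFrame(rows, columns=SITE_KEY + ["direction"])


class TestRecurrence:
    def test_single_comparison_nothing_recurs(self):
        out = recurrence_analysis({"a": point_events([1, 2, 3])}, eligible_n=100)
        assert out.iloc[0]["n_recurring"] == 0
        assert out.iloc[0]["observed_recurring_fraction"] == 0.0

    def test_two_set_enumeration(self):
        out = recurrence_analysis(
            {"a": point_events([1, 2, 3]), "b": point_events([2, 3, 4])},
            eligible_n=100,
        )
        row = out.iloc[0]
        assert row["n_distinct"] == 4
        assert row["n_recurring"] == 2
        assert row["observed_recurring_fraction"] == pytest.approx(0.5)

    def test_direction_must_match_for_recurrence(self):
        out = recurrence_analysis(
            {"a": point_events([1], "hyper"), "b": point_events([1], "hypo")},
            eligible_n=100,
        )
        assert (out["n_recurring"] == 0).all()

    def test_invariant_to_comparison_order(self):
        sets = {"a": point_events([1, 2]), "b": point_events([2, 5]),
                "c": point_events([5, 9])}
        fwd = recurrence_analysis(sets, 100)
        rev = recurrence_analysis(dict(reversed(list(sets.items()))), 100)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_frequencies_bounded_by_k_and_sum_to_distinct(self):
        sets = {f"c{i}": point_events([1, 2, 3, i + 10]) for i in range(4)}
        out = recurrence_analysis(sets, 100)
        row = out.iloc[0]
        assert row[[f"freq_{f}" for f in (1, 2, 3, 4)]].sum() == row["n_distinct"]

    def test_eligible_n_consistency_checked(self):
        with pytest.raises(DesignError):
            recurrence_analysis(
                {"a": point_events(range(1, 12)), "b": point_events([1])},
                eligible_n=10,
            )

    def test_dmr_recurrence_by_reciprocal_overlap(self):
        a = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [300],
             "direction": ["hyper"]}
        )
        b = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [150, 2000], "end": [350, 2300],
             "direction": ["hyper", "hyper"]}
        )
        out = recurrence_analysis({"a": a, "b": b}, eligible_n=1000, kind="DMR")
        row = out.iloc[0]
        assert row["n_distinct"] == 2 and row["n_recurring"] == 1


class TestExpectedRandomRecurrence:
    def test_single_comparison_zero(self):
        assert expected_random_recurrence([5], 100) == 0.0

    def test_analytic_matches_full_enumeration(self):
        """counts (2,2) over N=4: enumerate all C(4,2)^2 placements."""
        N, k = 4, 2
        inter_sum = union_sum = 0
        subsets = list(itertools.combinations(range(N), k))
        for A in subsets:
            for B in subsets:
                inter_sum += len(set(A) & set(B))
                union_sum += len(set(A) | set(B))
        exhaustive = inter_sum / union_sum  # E[#recurring] / E[#distinct]
        analytic = expected_random_recurrence([2, 2], 4)
        assert analytic == pytest.approx(exhaustive, rel=1e-12)

    def test_permutation_agrees_with_analytic(self):
        counts = [300, 250, 200, 150]
        N = 20_000
        analytic = expected_random_recurrence(counts, N)
        perm = expected_random_recurrence(
            counts, N, method="permutation", seed=1, replicates=200
        )
        # Monte-Carlo SE of the mean recurring fraction
        reps = [
            expected_random_recurrence(counts, N, "permutation", seed=s, replicates=1)
            for s in range(40)
        ]
        se = np.std(reps, ddof=1) / np.sqrt(200)
        assert abs(perm - analytic) < 3 * max(se, 1e-6)

    def test_count_exceeding_universe_rejected(self):
        with pytest.raises(DesignError):
            expected_random_recurrence([11], 10)


class TestInheritanceReports:
    def test_absent_event_not_maintained(self):
        induced = point_events([1, 2, 3])
        report = classify_maintenance(induced, {"adv": point_events([99])})
        pooled = report[report["direction"] == "pooled"].iloc[0]
        assert pooled["n_maintained"] == 0

    def test_toy_two_of_three_maintained(self):
        induced = point_events([1, 2, 3])
        report = classify_maintenance(induced, {"adv": point_events([1, 3])})
        pooled = report[report["direction"] == "pooled"].iloc[0]
        assert pooled["n_maintained"] == 2
        assert pooled["percentage"] == pytest.approx(66.67)

    def test_mode_all_requires_every_comparison(self):
        induced = point_events([1, 2])
        advanced = {"a": point_events([1, 2]), "b": point_events([1])}
        any_rep = classify_maintenance(induced, advanced, mode="any")
        all_rep = classify_maintenance(induced, advanced, mode="all")
        assert any_rep[any_rep["direction"] == "pooled"].iloc[0]["n_maintained"] == 2
        assert all_rep[all_rep["direction"] == "pooled"].iloc[0]["n_maintained"] == 1

    def test_direction_mismatch_not_maintained(self):
        induced = point_events([1], "hyper")
        report = classify_maintenance(induced, {"a": point_events([1], "hypo")})
        assert report[report["direction"] == "pooled"].iloc[0]["n_maintained"] == 0

    def test_empty_induced_set_gives_empty_report(self):
        report = classify_maintenance(point_events([]), {"a": point_events([1])})
        assert report[report["direction"] == "pooled"].iloc[0]["n_events"] == 0

    def test_transgenerational_requires_both_branches(self):
        accumulated = point_events([1, 2, 3])
        drought = {"d": point_events([1, 2])}
        recovery = {"r": point_events([2, 3])}
        report = classify_transgenerational(accumulated, drought, recovery)
        pooled = report[report["direction"] == "pooled"].iloc[0]
        assert pooled["n_transgenerational"] == 1  # only locus 2 in both

    def test_maintenance_parameter_recovery(self, sim_recovery, recovery_calls):
        """Called maintained fraction recovers maintenance_prob within
        3 binomial SE at 30x depth."""
        m = sim_recovery.design.maintenance_prob
        dmps = recovery_calls["dmps"]
        report = classify_maintenance(
            dmps["D0vsW0"],
            {k: dmps[k] for k in ("D10vsW10", "D11vsW11", "D10R1vsW10R1")},
        )
        pooled = report[report["direction"] == "pooled"].iloc[0]
        n = pooled["n_events"]
        est = pooled["n_maintained"] / n
        se = np.sqrt(m * (1 - m) / n)
        assert abs(est - m) < 3 * se


class TestTallyReport:
    def test_zero_numerator(self):
        out = tally_report({"x": (0, 10)})
        assert out[out["label"] == "x"].iloc[0]["percentage"] == 0.0

    def test_aggregate_row_is_ratio_of_sums(self):
        out = tally_report({"a": (1, 3), "b": (2, 3)})
        total = out[out["label"] == "total"].iloc[0]
        assert total["percentage"] == pytest.approx(50.0)

    def test_zero_denominator_flagged(self):
        with pytest.raises(ZeroDivisionError):
            tally_report({"x": (1, 0)})

    def test_round_half_up(self):
        assert round_half_up(3.755, 2) == 3.76
        assert round_half_up(3.754, 2) == 3.75


class TestClustering:
    def test_fewer_than_three_samples_rejected(self):
        levels = pd.DataFrame(np.zeros((2, 5)), index=["a", "b"])
        with pytest.raises(DesignError):
            cluster_samples(levels)

    def test_identical_samples_merge_at_height_zero(self):
        levels = pd.DataFrame(
            [[0.1, 0.9, 0.5]] * 2 + [[0.9, 0.1, 0.2]], index=["a", "b", "c"]
        )
        _, Z, labels = cluster_samples(levels)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_newick_reparses_to_same_heights(self):
        rng = np.random.default_rng(0)
        levels = pd.DataFrame(rng.random((6, 30)),
                              index=[f"s{i}" for i in range(6)])
        nwk, Z, labels = cluster_samples(levels)
        # leaf-to-root path length equals the root merge height for every leaf
        import io as _io
        from Bio import Phylo

        tree = Phylo.read(_io.StringIO(nwk), "newick")
        root_height = Z[-1, 2]
        for leaf in tree.get_terminals():
            assert tree.distance(leaf) == pytest.approx(root_height, rel=1e-4)

    def test_g0_samples_form_separate_clade(self, sim_recovery, recovery_calls):
        """On epimutation loci, the four G0 samples split from the
        advanced generations."""
        levels = epimutation_level_matrix(sim_recovery, recovery_calls)
        _, Z, labels = cluster_samples(levels)
        clades = dendrogram_clades(Z, labels)
        g0 = frozenset(l for l in labels if l.startswith("D0_") or l.startswith("W0_"))
        assert len(g0) == 4
        assert g0 in clades

    def test_non_epimutation_loci_degrade_sibling_adjacency(
        self, sim_recovery, recovery_calls
    ):
        epi = epimutation_level_matrix(sim_recovery, recovery_calls)
        _, Z_epi, labels = cluster_samples(epi)
        score_epi = sibling_adjacency_score(Z_epi, labels)

        rng = np.random.default_rng(2)
        event_loci = set(epi.columns)
        all_sites = sim_recovery.truth.sites
        pool = [
            (c, p, s)
            for c, p, s in zip(all_sites["chrom"], all_sites["pos"], all_sites["strand"])
            if (c, p, s) not in event_loci
        ]
        pick = [pool[i] for i in rng.choice(len(pool), size=epi.shape[1], replace=False)]
        rand = level_matrix(sim_recovery, pick)
        _, Z_rand, labels_r = cluster_samples(rand)
        score_rand = sibling_adjacency_score(Z_rand, labels_r)
        assert score_epi > score_rand


def level_matrix(exp, loci):
    idx = pd.MultiIndex.from_tuples(loci, names=SITE_KEY)
    rows = {}
    for key, table in exp.tables.items():
        sub = table.set_index(SITE_KEY).reindex(idx)
        cov = sub["meth"] + sub["unmeth"]
        rows[key.label] = (sub["meth"] / cov.where(cov > 0)).to_numpy()
    return pd.DataFrame(rows, index=idx).T


def epimutation_level_matrix(exp, calls):
    dmps = calls["dmps"]
    loci = sorted(
        set().union(
            *(
                set(zip(df["chrom"], df["pos"], df["strand"]))
                for df in (dmps["D0vsW0"], dmps["D10vsD0"])
            )
        )
    )
    return level_matrix(exp, loci)
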
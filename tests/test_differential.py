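"""DMP/SMP/DMR callers: exact-test oracle, definitions, window merging
and planted-event recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from epimethyl.calling import status_matrix
from epimethyl.differential import (
    GroupSpec,
    call_dmps,
    call_dmrs,
    call_smps,
    fisher_p,
    _merge_intervals,
)
from epimethyl.io import DesignError, SampleKey, build_eligible_set
from epimethyl.pipeline import parse_comparison

from conftest import make_table, ledger_point_loci, run_sites


# ---------------------------------------------------------------------------
# independent oracle: two-sided Fisher p by hypergeometric enumeration
# ---------------------------------------------------------------------------

def hypergeom_fisher_oracle(a, b, c, d):
    """Enumerate all 2x2 tables with the observed margins; two-sided p =
    sum of probabilities of tables no more probable than the observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)

    denom = comb(n, c1, exact=True)
    p_obs = table_prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0
    for x in range(lo, hi + 1):
        px = table_prob(x)
        # tolerance for float comparison mirrors scipy's gamma-based path
        if px <= p_obs * (1 + 1e-7):
            total += px
    return total / denom


class TestFisherOracle:
    def test_exhaustive_small_margins(self):
        """All 2x2 tables with row sums <= 8 match the enumeration oracle."""
        for r1 in range(0, 9):
            for r2 in range(0, 9):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        expect = hypergeom_fisher_oracle(a, r1 - a, c, r2 - c)
                        got = fisher_p(a, r1 - a, c, r2 - c)
                        assert got == pytest.approx(expect, rel=1e-9), (a, r1, c, r2)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    def test_random_tables_margins_to_30(self, a, b, c, d):
        assert fisher_p(a, b, c, d) == pytest.approx(
            hypergeom_fisher_oracle(a, b, c, d), rel=1e-9
        )


# ---------------------------------------------------------------------------
# DMPs
# ---------------------------------------------------------------------------

def four_sample_tables(counts_per_site):
    """counts_per_site: list of ((m,u) x 4 samples) per site; returns
    (g1, g2, tables, eligible)."""
    g1, g2 = parse_comparison("D0vsW0")
    keys = [g1.rep1, g1.rep2, g2.rep1, g2.rep2]
    tables = {}
    for j, key in enumerate(keys):
        recs = [
            ("chr1", 10 * (i + 1), "+", mu[j][0], mu[j][1], "CG", "CGA")
            for i, mu in enumerate(counts_per_site)
        ]
        tables[key] = make_table(recs)
    eligible = build_eligible_set(tables, 0)
    return g1, g2, tables, eligible


class TestCallDmps:
    def test_identical_counts_give_no_dmps(self):
        sites = [[(5, 5)] * 4 for _ in range(20)]
        g1, g2, tables, eligible = four_sample_tables(sites)
        assert len(call_dmps(g1, g2, tables, eligible)) == 0

    def test_strong_site_called_hyper_with_bonferroni_combination(self):
        sites = [[(5, 5)] * 4 for _ in range(20)]
        sites[3] = [(30, 0), (28, 1), (0, 30), (1, 29)]
        g1, g2, tables, eligible = four_sample_tables(sites)
        out = call_dmps(g1, g2, tables, eligible)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["pos"] == 40 and row["direction"] == "hyper"
        pairs = [(30, 0, 0, 30), (30, 0, 1, 29), (28, 1, 0, 30), (28, 1, 1, 29)]
        expect = min(1.0, 4 * min(hypergeom_fisher_oracle(*t) for t in pairs))
        assert row["combined_p"] == pytest.approx(expect, rel=1e-9)

    def test_discordant_replicates_filtered(self):
        sites = [[(5, 5)] * 4 for _ in range(20)]
        sites[3] = [(30, 0), (0, 30), (0, 30), (1, 29)]  # g1 reps disagree
        g1, g2, tables, eligible = four_sample_tables(sites)
        assert len(call_dmps(g1, g2, tables, eligible)) == 0

    def test_swapping_groups_swaps_directions(self, sim_recovery, recovery_calls):
        eligible = recovery_calls["eligible"]
        g1, g2 = parse_comparison("D0vsW0")
        fwd = recovery_calls["dmps"]["D0vsW0"]
        rev = call_dmps(g2, g1, sim_recovery.tables, eligible)
        key = ["chrom", "pos", "strand"]
        merged = fwd.merge(rev, on=key, suffixes=("_f", "_r"))
        assert len(merged) == len(fwd) == len(rev)
        assert (
            merged["direction_f"].map({"hyper": "hypo", "hypo": "hyper"})
            == merged["direction_r"]
        ).all()

    def test_hyper_hypo_sets_disjoint(self, recovery_calls):
        out = recovery_calls["dmps"]["D0vsW0"]
        key = list(zip(out["chrom"], out["pos"], out["strand"]))
        assert len(key) == len(set(key))

    def test_planted_recovery_and_fdr(self, sim_recovery, recovery_calls):
        """Depth-30 planted-event recovery: recall >= 0.95, FDR <= 0.05."""
        called = recovery_calls["dmps"]["D0vsW0"]
        led = sim_recovery.ledger
        truth_dir = ledger_point_loci(led, event_class="induced", induced_in="G0")
        truth_loci = {t[:3] for t in truth_dir}
        dmr_loci = {
            k for k in run_sites(led, sim_recovery.truth.sites,
                                 event_class="induced", induced_in="G0")
        }
        called_dir = set(zip(called["chrom"], called["pos"], called["strand"],
                             called["direction"]))
        called_loci = {c[:3] for c in called_dir}
        recall = len(called_dir & truth_dir) / len(truth_dir)
        fp = called_loci - truth_loci - dmr_loci
        fdr = len(fp) / max(1, len(called_loci))
        assert recall >= 0.95
        assert fdr <= 0.05


# ---------------------------------------------------------------------------
# SMPs
# ---------------------------------------------------------------------------

def status_frame(statuses_by_sample):
    idx = pd.MultiIndex.from_tuples(
        [("chr1", 10 * (i + 1), "+") for i in range(len(next(iter(statuses_by_sample.values()))))],
        names=["chrom", "pos", "strand"],
    )
    return pd.DataFrame(statuses_by_sample, index=idx)


class TestCallSmps:
    g1, g2 = parse_comparison("D0vsW0")
    cols = [str(g1.rep1), str(g1.rep2), str(g2.rep1), str(g2.rep2)]

    def frame(self, rows):
        data = {c: [r[j] for r in rows] for j, c in enumerate(self.cols)}
        return status_frame(data)

    def test_definition_re_methylated(self):
        out = call_smps(self.g1, self.g2, self.frame([["M", "M", "U", "U"]]))
        assert len(out) == 1 and out.iloc[0]["direction"] == "re_methylated"

    def test_replicate_discordance_skipped(self):
        out = call_smps(self.g1, self.g2, self.frame([["M", "U", "U", "U"]]))
        assert len(out) == 0

    def test_uncallable_site_skipped(self):
        out = call_smps(self.g1, self.g2, self.frame([["M", "M", "NC", "U"]]))
        assert len(out) == 0

    def test_panel_invariant_sites_removed(self):
        statuses = self.frame([["M", "M", "U", "U"], ["M", "M", "M", "M"]])
        panel_all_m = statuses.copy()
        panel_all_m.loc[:, :] = "M"
        extra = {f"s{i}": ["M", "M"] for i in range(12)}
        panel = pd.concat([statuses, status_frame(
            {k: v for k, v in extra.items()})], axis=1)
        out = call_smps(self.g1, self.g2, statuses, panel=panel)
        # site 2 invariant across the 16-sample panel -> excluded
        assert out["pos"].tolist() == [10]
        assert out.iloc[0]["direction"] == "re_methylated"


# ---------------------------------------------------------------------------
# DMRs
# ---------------------------------------------------------------------------

def dmr_toy(block_positions, level_high=0.9, level_low=0.2, depth=30,
            n_null=40, spacing=25):
    """Two groups differing on a block of sites; returns caller inputs."""
    g1, g2 = parse_comparison("D0vsW0")
    rng = np.random.default_rng(0)
    positions = sorted(set(block_positions) | {1000 + spacing * i for i in range(n_null)})
    tables = {}
    for key, level_block in [
        (g1.rep1, level_high), (g1.rep2, level_high),
        (g2.rep1, level_low), (g2.rep2, level_low),
    ]:
        recs = []
        for pos in positions:
            lv = level_block if pos in block_positions else 0.5
            m = int(round(depth * lv))
            recs.append(("chr1", pos, "+", m, depth - m, "CG", "CGA"))
        tables[key] = make_table(recs)
    eligible = build_eligible_set(tables, 0)
    dmps = call_dmps(g1, g2, tables, eligible)
    return g1, g2, tables, dmps, eligible


class TestCallDmrs:
    def test_no_dmps_no_dmrs(self):
        g1, g2, tables, _, eligible = dmr_toy(set())
        empty = pd.DataFrame(columns=["chrom", "pos", "strand", "direction"])
        out = call_dmrs(g1, g2, tables, empty, eligible)
        assert len(out) == 0

    def test_single_block_one_dmr_window_union_boundaries(self):
        block = {100 + 25 * i for i in range(8)}  # 8 sites in 100..275
        g1, g2, tables, dmps, eligible = dmr_toy(block)
        assert len(dmps) >= 8
        out = call_dmrs(g1, g2, tables, dmps, eligible, boundaries="windows")
        assert len(out) == 1
        row = out.iloc[0]
        assert row["direction"] == "hyper" and row["n_dmps"] >= 8
        # boundaries = union of qualifying 200-bp windows on the 50-bp grid
        assert row["start"] % 50 == 1
        assert row["start"] <= 100 and row["end"] >= 275

    def test_trimmed_boundaries_match_block(self):
        block = {100 + 25 * i for i in range(8)}
        g1, g2, tables, dmps, eligible = dmr_toy(block)
        out = call_dmrs(g1, g2, tables, dmps, eligible, boundaries="trim")
        assert len(out) == 1
        assert out.iloc[0]["start"] == 100 and out.iloc[0]["end"] == 275

    @pytest.mark.parametrize("gap,n_expected", [(150, 2), (100, 1)])
    def test_merge_gap_boundary(self, gap, n_expected):
        """Qualifying windows separated by 150 bp stay apart; by 100 bp merge."""
        windows = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "direction": ["hyper", "hyper"],
                "start": [1, 200 + gap + 1],
                "end": [200, 400 + gap],
            }
        )
        merged = _merge_intervals(windows, merge_gap=100)
        assert len(merged) == n_expected

    def test_merge_idempotent(self):
        rng = np.random.default_rng(5)
        starts = np.sort(rng.integers(1, 5000, 40))
        windows = pd.DataFrame(
            {
                "chrom": "chr1",
                "direction": rng.choice(["hyper", "hypo"], 40),
                "start": starts,
                "end": starts + 199,
            }
        )
        once = _merge_intervals(windows, 100)
        again_df = pd.DataFrame(
            [{"chrom": c, "direction": d, "start": s, "end": e}
             for c, d, s, e, _ in once]
        )
        twice = _merge_intervals(again_df, 100)
        assert [(c, d, s, e) for c, d, s, e, _ in once] == [
            (c, d, s, e) for c, d, s, e, _ in twice
        ]

    def test_opposite_direction_windows_not_merged(self):
        windows = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "direction": ["hyper", "hypo"],
                "start": [1, 250],
                "end": [200, 450],
            }
        )
        assert len(_merge_intervals(windows, 100)) == 2

    def test_planted_dmr_recovery(self, sim_recovery, recovery_calls):
        """Planted DMR runs recovered with recall >= 0.9 and boundary
        error <= 100 bp."""
        g1, g2 = parse_comparison("D0vsW0")
        out = call_dmrs(
            g1, g2, sim_recovery.tables, recovery_calls["dmps"]["D0vsW0"],
            recovery_calls["eligible"],
        )
        led = sim_recovery.ledger
        planted = led[(led["kind"] == "DMR-like") & (led["event_class"] == "induced")]
        assert len(planted) == 10
        hits = 0
        for _, ev in planted.iterrows():
            match = out[
                (out["chrom"] == ev["chrom"])
                & (out["direction"] == ev["direction"])
                & (out["end"] >= ev["start"])
                & (out["start"] <= ev["end"])
            ]
            if len(match):
                m = match.iloc[0]
                if (
                    abs(m["start"] - ev["start"]) <= 100
                    and abs(m["end"] - ev["end"]) <= 100
                ):
                    hits += 1
        assert hits / len(planted) >= 0.9


class TestGroupSpec:
    def test_mismatched_replicates_rejected(self):
        with pytest.raises(DesignError):
            GroupSpec(SampleKey("G0", "D", 1), SampleKey("G0", "W", 2))
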
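import numpy as np
import pandas as pd
import pytest

from epimethyl.io import REPORT_COLUMNS
from epimethyl.simulate import SimDesign, simulate_experiment


def make_table(records):
    """Cytosine table from (chrom, pos, strand, meth, unmeth, context, tri) tuples."""
    df = pd.DataFrame(records, columns=REPORT_COLUMNS)
    df["coverage"] = df["meth"] + df["unmeth"]
    df["low_coverage"] = df["coverage"] < 3
    return df


def uniform_table(n=50, meth=5, unmeth=5, chrom="chr1", spacing=10, start=10):
    recs = [
        (chrom, start + i * spacing, "+", meth, unmeth, "CG", "CGA")
        for i in range(n)
    ]
    return make_table(recs)


@pytest.fixture(scope="session")
def sim_default():
    """Default study-condition simulation (~13x depth)."""
    return simulate_experiment(SimDesign(n_chroms=2, sites_per_chrom=3000, seed=7))


#: deep design used by the planted-event recovery and dynamics suites:
#: 30x depth, ~2% induction, elevated accumulated rate, 10 DMR runs per class
RECOVERY_DESIGN = SimDesign(
    n_chroms=2,
    sites_per_chrom=5000,
    depth_mean=30.0,
    induction_rate_by_context={"CG": 0.02, "CHG": 0.02, "CHH": 0.02},
    accumulated_rate=0.03,
    dmr_events=10,
    seed=11,
)


@pytest.fixture(scope="session")
def sim_recovery():
    return simulate_experiment(RECOVERY_DESIGN)


@pytest.fixture(scope="session")
def recovery_calls(sim_recovery):
    """DMP calls for every comparison the dynamics analyses need."""
    from epimethyl.differential import call_dmps
    from epimethyl.io import build_eligible_set
    from epimethyl.pipeline import parse_comparison

    eligible = build_eligible_set(sim_recovery.tables, 3)
    labels = [
        "D0vsW0",
        "D10vsW10",
        "D11vsW11",
        "D10R1vsW10R1",
        "D10vsD0",
        "D11vsD0",
        "D10R1vsD0",
    ]
    dmps = {}
    for label in labels:
        g1, g2 = parse_comparison(label)
        dmps[label] = call_dmps(g1, g2, sim_recovery.tables, eligible)
    return {"eligible": eligible, "dmps": dmps}


def ledger_point_loci(ledger, event_class=None, induced_in=None, kind="DMP-like"):
    sub = ledger
    if kind is not None:
        sub = sub[sub["kind"] == kind]
    if event_class is not None:
        sub = sub[sub["event_class"] == event_class]
    if induced_in is not None:
        sub = sub[sub["induced_in"] == induced_in]
    return set(zip(sub["chrom"], sub["start"], sub["strand"], sub["direction"]))


def run_sites(ledger, sites, event_class=None, induced_in=None):
    """All site keys inside planted DMR-like runs."""
    sub = ledger[ledger["kind"] == "DMR-like"]
    if event_class is not None:
        sub = sub[sub["event_class"] == event_class]
    if induced_in is not None:
        sub = sub[sub["induced_in"] == induced_in]
    keys = set()
    for _, r in sub.iterrows():
        block = sites[
            (sites["chrom"] == r["chrom"])
            & (sites["pos"] >= r["start"])
            & (sites["pos"] <= r["end"])
        ]
        keys |= set(zip(block["chrom"], block["pos"], block["strand"]))
    return keys
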
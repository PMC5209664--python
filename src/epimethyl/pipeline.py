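"""End-to-end orchestration: simulate -> call -> compare -> dynamics ->
annotate -> report.

A run is driven by a declarative configuration (YAML file or plain
dict): simulation design parameters, calling thresholds, and a
comparison plan of labels like ``D0vsW0`` or ``D10R1vsD0`` (treatment
letter followed by the generation suffix).  All intermediates are plain
TSV/BED/JSON files so every stage can be re-run independently; a single
global seed is expanded into per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_sites, distribution_summary
from .calling import call_methylation_status, estimate_conversion, status_matrix
from .differential import GroupSpec, call_dmps, call_dmrs, call_smps, write_dmrs_bed
from .dynamics import (
    classify_maintenance,
    classify_transgenerational,
    cluster_samples,
    recurrence_analysis,
)
from .io import SITE_KEY, DesignError, SampleKey, build_eligible_set
from .simulate import SimDesign, simulate_experiment, write_experiment

_COMP_RE = re.compile(r"^([DW])(\d+(?:R\d+)?)vs([DW])(\d+(?:R\d+)?)$")

DEFAULT_THRESHOLDS = {
    "min_coverage": 3,
    "fpr": 0.05,
    "tc_error_rate": 0.001,
    "p_thresh": 0.01,
    "fdr": 0.05,
    "window": 200,
    "step": 50,
    "min_dmps": 7,
    "fold": 1.5,
    "adj_p": 0.01,
    "merge_gap": 100,
}

DEFAULT_PLAN = {
    "induced": "D0vsW0",
    "advanced": ["D10vsW10", "D11vsW11", "D10R1vsW10R1"],
    "accumulated": "D10vsD0",
    "drought_offspring": ["D11vsD0"],
    "recovery": ["D10R1vsD0"],
}


def parse_comparison(label: str, variety: str = "") -> tuple[GroupSpec, GroupSpec]:
    """``D10vsW10`` -> (drought G10 group, well-watered G10 group)."""
    m = _COMP_RE.match(label)
    if not m:
        raise DesignError(f"cannot parse comparison label {label!r}")
    t1, g1, t2, g2 = m.groups()
    spec = []
    for t, g in ((t1, g1), (t2, g2)):
        gen = f"G{g}"
        spec.append(
            GroupSpec(SampleKey(gen, t, 1, variety), SampleKey(gen, t, 2, variety))
        )
    return spec[0], spec[1]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the run report (also written
    as ``report.json``).

    ``config`` keys: ``design`` (SimDesign fields), ``thresholds``,
    ``plan`` (comparison labels), ``seed``, ``variety``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"version": __version__, "stages": {}, "parameters": {}}

    thresholds = {**DEFAULT_THRESHOLDS, **(config.get("thresholds") or {})}
    plan = {**DEFAULT_PLAN, **(config.get("plan") or {})}
    seed = int(config.get("seed", 0))
    variety = str(config.get("variety", ""))
    design = SimDesign(**{**(config.get("design") or {}), "seed": seed})
    report["parameters"] = {
        "design": {k: str(v) for k, v in design.__dict__.items()},
        "thresholds": thresholds,
        "plan": plan,
        "seed": seed,
    }

    # -- simulate ----------------------------------------------------------
    t = time.time()
    exp = simulate_experiment(design, variety)
    sim_dir = outdir / "simulated"
    write_experiment(exp, sim_dir)
    report["stages"]["simulate"] = {
        "n_sites": exp.truth.n_sites,
        "n_planted_events": int(len(exp.ledger)),
        "seconds": round(time.time() - t, 2),
    }

    # -- methylation calling ----------------------------------------------
    t = time.time()
    calls = {}
    conversion = {}
    for key, table in exp.tables.items():
        est = estimate_conversion(
            exp.lambda_tables[key], tc_error_rate=thresholds["tc_error_rate"]
        )
        conversion[key.label] = est.nonconversion_rate
        calls[key.label] = call_methylation_status(
            table,
            est,
            fpr=thresholds["fpr"],
            min_coverage=thresholds["min_coverage"],
        )
    eligible = build_eligible_set(exp.tables, thresholds["min_coverage"])
    statuses = status_matrix(calls, eligible)
    statuses.to_csv(outdir / "status_matrix.tsv", sep="\t")
    report["stages"]["callmc"] = {
        "n_eligible": int(len(eligible)),
        "nonconversion_estimates": conversion,
        "seconds": round(time.time() - t, 2),
    }

    # -- differential calling ----------------------------------------------
    t = time.time()
    labels = sorted(
        {plan["induced"], plan["accumulated"], *plan["advanced"],
         *plan["drought_offspring"], *plan["recovery"]}
    )
    dmps: dict[str, pd.DataFrame] = {}
    smps: dict[str, pd.DataFrame] = {}
    dmrs: dict[str, pd.DataFrame] = {}
    for label in labels:
        gs1, gs2 = parse_comparison(label, variety)
        for g in (gs1.rep1, gs1.rep2, gs2.rep1, gs2.rep2):
            if g not in exp.tables:
                raise DesignError(f"comparison {label}: sample {g.label} missing")
        dmps[label] = call_dmps(
            gs1, gs2, exp.tables, eligible,
            p_thresh=thresholds["p_thresh"], fdr=thresholds["fdr"],
        )
        smps[label] = call_smps(gs1, gs2, statuses, panel=statuses)
        dmrs[label] = call_dmrs(
            gs1, gs2, exp.tables, dmps[label], eligible,
            window=thresholds["window"], step=thresholds["step"],
            min_dmps=thresholds["min_dmps"], fold=thresholds["fold"],
            adj_p=thresholds["adj_p"], merge_gap=thresholds["merge_gap"],
        )
        dmps[label].to_csv(outdir / f"dmp_{label}.tsv", sep="\t", index=False)
        smps[label].to_csv(outdir / f"smp_{label}.tsv", sep="\t", index=False)
        write_dmrs_bed(dmrs[label], outdir / f"dmr_{label}.bed")
    report["stages"]["differential"] = {
        label: {
            "dmps": int(len(dmps[label])),
            "smps": int(len(smps[label])),
            "dmrs": int(len(dmrs[label])),
        }
        for label in labels
    }
    report["stages"]["differential"]["seconds"] = round(time.time() - t, 2)

    # -- dynamics -----------------------------------------------------------
    t = time.time()
    dvw = [plan["induced"], *plan["advanced"]]
    recur = recurrence_analysis(
        {lab: dmps[lab] for lab in dvw}, eligible_n=len(eligible),
        kind="DMP", seed=seed,
    )
    recur.to_csv(outdir / "recurrence_dmp.tsv", sep="\t", index=False)
    maint = classify_maintenance(
        dmps[plan["induced"]], {lab: dmps[lab] for lab in plan["advanced"]}
    )
    maint.to_csv(outdir / "maintenance_dmp.tsv", sep="\t", index=False)
    trans = classify_transgenerational(
        dmps[plan["accumulated"]],
        {lab: dmps[lab] for lab in plan["drought_offspring"]},
        {lab: dmps[lab] for lab in plan["recovery"]},
    )
    trans.to_csv(outdir / "transgenerational_dmp.tsv", sep="\t", index=False)

    loci = pd.concat(
        [dmps[lab][SITE_KEY] for lab in labels], ignore_index=True
    ).drop_duplicates()
    levels = {}
    for key, table in exp.tables.items():
        sub = table.set_index(SITE_KEY).reindex(pd.MultiIndex.from_frame(loci))
        cov = sub["meth"] + sub["unmeth"]
        levels[key.label] = (sub["meth"] / cov.where(cov > 0)).to_numpy()
    level_df = pd.DataFrame(levels).T
    newick = None
    if len(loci) and level_df.shape[0] >= 3:
        newick, _, _ = cluster_samples(level_df)
        (outdir / "dendrogram.nwk").write_text(newick + "\n")
    report["stages"]["dynamics"] = {
        "n_epimutation_loci": int(len(loci)),
        "recurrence_rows": int(len(recur)),
        "seconds": round(time.time() - t, 2),
    }

    # -- annotate -----------------------------------------------------------
    t = time.time()
    induced = dmps[plan["induced"]].copy()
    if len(induced):
        induced["region"] = annotate_sites(induced, exp.truth.features)
        dist = distribution_summary(induced)
        dist.to_csv(outdir / "distribution_induced_dmp.tsv", sep="\t", index=False)
        report["stages"]["annotate"] = {
            "n_annotated": int(len(induced)),
            "seconds": round(time.time() - t, 2),
        }
    else:
        report["stages"]["annotate"] = {"n_annotated": 0,
                                        "seconds": round(time.time() - t, 2)}

    # -- manifest -----------------------------------------------------------
    manifest = {}
    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "report.json":
            manifest[str(f.relative_to(outdir))] = _sha256(f)
    report["manifest"] = manifest
    report["total_seconds"] = round(time.time() - t0, 2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
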
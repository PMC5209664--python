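"""Synthetic methylome generator for the drought epi-MA study design.

Generates per-cytosine bisulfite count tables for the 16 samples of one
variety (four generations {G0, G10, G11, G10R1} x two treatments {D, W}
x two sibling replicates), together with a reference sequence, a gene/TE
annotation and a truth ledger of every planted epimutation, so that each
downstream stage can be tested against known ground truth.

Two event classes are planted:

* *induced* events express as a drought-vs-control (D vs W) shift of the
  true methylation level within the inducing generation.  With
  probability ``maintenance_prob`` per transmission step the changed
  status is re-established in the drought samples of descendant
  generations (G0 -> G10 -> {G11, G10R1}), which is what the maintenance
  analysis measures.
* *accumulated* events are fixed along the line between G0 and G10 and
  are inherited by both treatments of every descendant generation
  (including the well-watered recovery generation G10R1); these drive
  the accumulated (D10 vs D0) and transgenerational analyses and the
  separation of G0 from advanced generations in sample clustering.

A configurable fraction of sites are "hot spots" with a multiplied
induction rate, so recurrence concentrates on them.  Sibling replicates
share identical truth and differ only by count sampling.  Coverage is
Poisson (negative binomial behind a switch); methylated read counts are
binomial with the observed success probability
``p_true * (1 - conversion_failure_rate) + (1 - p_true) * nonconversion_rate``.
An unmethylated lambda spike-in (true level 0 everywhere) is emitted per
sample for conversion-rate calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    GENERATIONS,
    REPORT_COLUMNS,
    DesignError,
    FeatureSet,
    SampleKey,
    design_keys,
    write_cytosine_report,
    write_features_gff3,
)

#: lineage of the epi-MA line: generation -> parent generation sampled
PARENT = {"G10": "G0", "G11": "G10", "G10R1": "G10"}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one simulated variety.

    Defaults emulate the study conditions: ~13x strand-specific depth,
    high mCG / low mCHH baselines, TE-dense methylation, drought-induced
    events concentrated in hot spots, and heritable status changes with
    a configurable maintenance probability.
    """

    n_chroms: int = 2
    sites_per_chrom: int = 3000
    depth_mean: float = 13.0
    coverage_model: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 5.0
    nonconversion_rate: float = 0.005
    conversion_failure_rate: float = 0.0  # over-conversion of true mC
    context_mix: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.22, "CHG": 0.17, "CHH": 0.61}
    )
    te_fraction: float = 0.35
    hotspot_fraction: float = 0.01
    hotspot_multiplier: float = 10.0
    induction_rate_by_context: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.004, "CHG": 0.004, "CHH": 0.004}
    )
    accumulated_rate: float = 0.004
    effect_size: float = 0.6
    maintenance_prob: float = 0.7
    dmr_events: int = 4  # DMR-like runs planted per event class
    dmr_run_sites: int = 8
    dmr_max_span: int = 200
    lambda_sites: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.context_mix.values())
        if not np.isclose(total, 1.0):
            raise DesignError(f"context_mix must sum to 1, got {total}")
        for name in (
            "nonconversion_rate",
            "conversion_failure_rate",
            "te_fraction",
            "hotspot_fraction",
            "maintenance_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DesignError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.effect_size <= 1.0:
            raise DesignError("effect_size must be in (0, 1]")
        if self.depth_mean < 0:
            raise DesignError("depth_mean must be non-negative")


@dataclass
class TrueMethylome:
    """Per-site truth: context, region label and true level per
    (generation, treatment)."""

    sites: pd.DataFrame  # chrom, pos, strand, context, trinucleotide, region, base
    levels: dict[tuple[str, str], np.ndarray]
    reference: dict[str, str]
    features: FeatureSet

    @property
    def n_sites(self) -> int:
        return len(self.sites)


LEDGER_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "kind",
    "event_class",
    "direction",
    "induced_in",
    "hotspot",
    "maintained_G10",
    "maintained_G11",
    "maintained_G10R1",
    "clamped",
]


def _base_level(rng: np.random.Generator, context: str, in_te: bool) -> float:
    """Baseline true level: bimodal high-mode CG, intermediate CHG,
    low CHH; TEs methylated in all contexts."""
    if in_te:
        if context == "CG":
            return rng.beta(16, 3)
        if context == "CHG":
            return rng.beta(10, 4)
        return rng.beta(4, 9)
    if context == "CG":
        return rng.beta(16, 4) if rng.random() < 0.55 else rng.beta(1, 30)
    if context == "CHG":
        return rng.beta(8, 6) if rng.random() < 0.30 else rng.beta(1, 30)
    return rng.beta(1.5, 25)


def build_reference_methylome(design: SimDesign) -> TrueMethylome:
    """Lay out cytosine sites, a consistent reference sequence, gene/TE
    features and baseline true methylation levels.

    Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 101]))
    contexts = list(design.context_mix)
    probs = np.array([design.context_mix[c] for c in contexts], dtype=float)
    probs = probs / probs.sum()

    site_rows: list[dict] = []
    reference: dict[str, str] = {}
    feat_rows: list[dict] = []

    for ci in range(design.n_chroms):
        chrom = f"chr{ci + 1}"
        gaps = rng.integers(5, 26, size=design.sites_per_chrom)
        positions = 10 + np.cumsum(gaps)
        length = int(positions[-1]) + 10
        seq = np.full(length + 3, b"T", dtype="S1")

        # gene/TE tiling: repeating unit of gene, TE and intergenic spacers
        unit = 6000
        te_w = max(200, int(round(design.te_fraction * unit)))
        gene_w = max(200, int(round(0.30 * unit)))
        start = 1
        gi = ti = 0
        while start + gene_w + te_w < length:
            gi += 1
            g_start, g_end = start, start + gene_w - 1
            feat_rows.append(
                {
                    "chrom": chrom,
                    "start": g_start,
                    "end": g_end,
                    "strand": "+" if gi % 2 else "-",
                    "kind": "gene",
                    "id": f"{chrom}.g{gi}",
                }
            )
            ti += 1
            t_start = g_end + (unit - gene_w - te_w) // 2
            feat_rows.append(
                {
                    "chrom": chrom,
                    "start": t_start,
                    "end": t_start + te_w - 1,
                    "strand": "+",
                    "kind": "TE",
                    "id": f"{chrom}.te{ti}",
                }
            )
            start += unit

        chrom_feats = [f for f in feat_rows if f["chrom"] == chrom]
        te_iv = [(f["start"], f["end"]) for f in chrom_feats if f["kind"] == "TE"]
        gene_iv = [(f["start"], f["end"]) for f in chrom_feats if f["kind"] == "gene"]

        def region_of(pos: int) -> str:
            for s, e in te_iv:
                if s <= pos <= e:
                    return "TE"
            for s, e in gene_iv:
                if s <= pos <= e:
                    return "gene"
            return "intergenic"

        ctx_idx = rng.choice(len(contexts), size=design.sites_per_chrom, p=probs)
        strands = np.where(rng.random(design.sites_per_chrom) < 0.5, "+", "-")
        h_choices = np.array(["A", "C", "T"])
        for pos, k, strand in zip(positions, ctx_idx, strands):
            pos = int(pos)
            context = contexts[int(k)]
            if context == "CG":
                tri = "CG" + rng.choice(h_choices)
            elif context == "CHG":
                tri = "C" + rng.choice(h_choices) + "G"
            else:
                tri = "C" + rng.choice(h_choices) + rng.choice(h_choices)
            if strand == "+":
                for off, b in enumerate(tri):
                    seq[pos + off] = b.encode()
            else:
                rc = revcomp(tri)  # occupies pos-2..pos on the plus strand
                for off, b in enumerate(rc):
                    seq[pos - 2 + off] = b.encode()
            region = region_of(pos)
            site_rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": strand,
                    "context": context,
                    "trinucleotide": tri,
                    "region": region,
                    "base": _base_level(rng, context, region == "TE"),
                }
            )
        reference[chrom] = seq[1:length + 1].tobytes().decode()

    sites = pd.DataFrame(site_rows)
    sites = sites.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )
    base = sites["base"].to_numpy(dtype=float)
    levels = {
        (g, t): base.copy() for g in GENERATIONS for t in ("D", "W")
    }
    return TrueMethylome(
        sites=sites,
        levels=levels,
        reference=reference,
        features=FeatureSet(pd.DataFrame(feat_rows)),
    )


def _direction_for(base: float) -> str:
    """Plant hyper events where there is headroom, hypo where there is
    methylation to lose."""
    return "hyper" if base <= 0.5 else "hypo"


def _shift(level: np.ndarray, idx: np.ndarray, direction: str, e: float) -> bool:
    """Apply a +-e shift, clamping into [0, 1]; returns True if any
    value was clamped."""
    delta = e if direction == "hyper" else -e
    target = level[idx] + delta
    clamped = bool(((target < 0) | (target > 1)).any())
    level[idx] = np.clip(target, 0.0, 1.0)
    return clamped


def plant_epimutations(
    truth: TrueMethylome, design: SimDesign
) -> tuple[TrueMethylome, pd.DataFrame]:
    """Plant induced and accumulated epimutations; return the per-
    generation truth and the truth ledger.

    The input truth's baseline levels are not modified in place.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 202]))
    n = truth.n_sites
    sites = truth.sites.copy()
    base = sites["base"].to_numpy(dtype=float)
    levels = {k: v.copy() for k, v in truth.levels.items()}

    hotspot = rng.random(n) < design.hotspot_fraction
    rate = np.array(
        [design.induction_rate_by_context.get(c, 0.0) for c in sites["context"]]
    )
    site_rate = np.minimum(1.0, rate * np.where(hotspot, design.hotspot_multiplier, 1.0))
    acc_rate = np.minimum(
        1.0, design.accumulated_rate * np.where(hotspot, design.hotspot_multiplier, 1.0)
    )

    used_for_acc = np.zeros(n, dtype=bool)
    used_for_dmr = np.zeros(n, dtype=bool)
    events: list[dict] = []
    e = design.effect_size
    m = design.maintenance_prob

    # ---- DMR-like runs: contiguous site runs within a short span -------
    pos = sites["pos"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()

    run_regions: list[tuple[str, int, int]] = []

    def plant_dmr_runs(event_class: str) -> None:
        planted = 0
        order = rng.permutation(n - design.dmr_run_sites)
        for start_i in order:
            if planted >= design.dmr_events:
                break
            stop_i = start_i + design.dmr_run_sites
            if chrom_arr[start_i] != chrom_arr[stop_i - 1]:
                continue
            span = pos[stop_i - 1] - pos[start_i] + 1
            if span > design.dmr_max_span:
                continue
            idx = np.arange(start_i, stop_i)
            if used_for_dmr[idx].any() or used_for_acc[idx].any():
                continue
            # keep planted regions well separated so each is its own DMR
            near = any(
                c == chrom_arr[start_i]
                and pos[start_i] - 1000 <= e
                and pos[stop_i - 1] + 1000 >= s
                for c, s, e in run_regions
            )
            if near:
                continue
            direction = _direction_for(float(base[idx].mean()))
            # regional events arise in regions of homogeneous methylation:
            # give every run site headroom for the full effect size
            if direction == "hyper":
                base[idx] = np.minimum(base[idx], 1.0 - design.effect_size)
            else:
                base[idx] = np.maximum(base[idx], design.effect_size)
            for lv in levels.values():
                lv[idx] = base[idx]
            run_regions.append(
                (chrom_arr[start_i], int(pos[start_i]), int(pos[stop_i - 1]))
            )
            used_for_dmr[idx] = True
            clamped = False
            if event_class == "induced":
                clamped |= _shift(levels[("G0", "D")], idx, direction, e)
                m_g10 = bool(rng.random() < m)
                m_g11 = m_g10 and bool(rng.random() < m)
                m_g10r1 = m_g10 and bool(rng.random() < m)
                for gen, flag in (("G10", m_g10), ("G11", m_g11), ("G10R1", m_g10r1)):
                    if flag:
                        clamped |= _shift(levels[(gen, "D")], idx, direction, e)
                induced_in = "G0"
            else:
                m_g10 = True
                m_g11 = bool(rng.random() < m)
                m_g10r1 = bool(rng.random() < m)
                for gen, flag in (("G10", True), ("G11", m_g11), ("G10R1", m_g10r1)):
                    if flag:
                        clamped |= _shift(levels[(gen, "D")], idx, direction, e)
                        clamped |= _shift(levels[(gen, "W")], idx, direction, e)
                induced_in = "G10"
            events.append(
                {
                    "chrom": chrom_arr[start_i],
                    "start": int(pos[start_i]),
                    "end": int(pos[stop_i - 1]),
                    "strand": ".",
                    "kind": "DMR-like",
                    "event_class": event_class,
                    "direction": direction,
                    "induced_in": induced_in,
                    "hotspot": bool(hotspot[idx].any()),
                    "maintained_G10": m_g10,
                    "maintained_G11": m_g11,
                    "maintained_G10R1": m_g10r1,
                    "clamped": clamped,
                }
            )
            planted += 1

    if design.dmr_events > 0 and n > design.dmr_run_sites:
        plant_dmr_runs("induced")
        plant_dmr_runs("accumulated")

    free = ~used_for_dmr

    # ---- accumulated point events (inherited by both treatments) ------
    acc_mask = (rng.random(n) < acc_rate) & free
    used_for_acc |= acc_mask
    for i in np.flatnonzero(acc_mask):
        direction = _direction_for(float(base[i]))
        idx = np.array([i])
        m_g11 = bool(rng.random() < m)
        m_g10r1 = bool(rng.random() < m)
        clamped = False
        for gen, flag in (("G10", True), ("G11", m_g11), ("G10R1", m_g10r1)):
            if flag:
                clamped |= _shift(levels[(gen, "D")], idx, direction, e)
                clamped |= _shift(levels[(gen, "W")], idx, direction, e)
        events.append(
            {
                "chrom": sites.at[i, "chrom"],
                "start": int(sites.at[i, "pos"]),
                "end": int(sites.at[i, "pos"]),
                "strand": sites.at[i, "strand"],
                "kind": "DMP-like",
                "event_class": "accumulated",
                "direction": direction,
                "induced_in": "G10",
                "hotspot": bool(hotspot[i]),
                "maintained_G10": True,
                "maintained_G11": m_g11,
                "maintained_G10R1": m_g10r1,
                "clamped": clamped,
            }
        )

    # ---- induced point events (D vs W within a generation) ------------
    eligible = free & ~used_for_acc
    for gen in GENERATIONS:
        induced_mask = (rng.random(n) < site_rate) & eligible
        for i in np.flatnonzero(induced_mask):
            direction = _direction_for(float(base[i]))
            idx = np.array([i])
            clamped = _shift(levels[(gen, "D")], idx, direction, e)
            flags = {"maintained_G10": False, "maintained_G11": False,
                     "maintained_G10R1": False}
            if gen == "G0":
                f10 = bool(rng.random() < m)
                f11 = f10 and bool(rng.random() < m)
                f10r1 = f10 and bool(rng.random() < m)
                for g2, flag in (("G10", f10), ("G11", f11), ("G10R1", f10r1)):
                    if flag:
                        clamped |= _shift(levels[(g2, "D")], idx, direction, e)
                flags = {"maintained_G10": f10, "maintained_G11": f11,
                         "maintained_G10R1": f10r1}
            elif gen == "G10":
                f11 = bool(rng.random() < m)
                f10r1 = bool(rng.random() < m)
                for g2, flag in (("G11", f11), ("G10R1", f10r1)):
                    if flag:
                        clamped |= _shift(levels[(g2, "D")], idx, direction, e)
                flags = {"maintained_G10": True, "maintained_G11": f11,
                         "maintained_G10R1": f10r1}
            events.append(
                {
                    "chrom": sites.at[i, "chrom"],
                    "start": int(sites.at[i, "pos"]),
                    "end": int(sites.at[i, "pos"]),
                    "strand": sites.at[i, "strand"],
                    "kind": "DMP-like",
                    "event_class": "induced",
                    "direction": direction,
                    "induced_in": gen,
                    "hotspot": bool(hotspot[i]),
                    **flags,
                    "clamped": clamped,
                }
            )

    sites["base"] = base
    ledger = pd.DataFrame(events, columns=LEDGER_COLUMNS)
    planted = TrueMethylome(
        sites=sites, levels=levels, reference=truth.reference, features=truth.features
    )
    return planted, ledger


def _draw_coverage(
    rng: np.random.Generator, design: SimDesign, size: int
) -> np.ndarray:
    if design.depth_mean == 0:
        return np.zeros(size, dtype=int)
    if design.coverage_model == "negative_binomial":
        r = design.nb_dispersion
        p = r / (r + design.depth_mean)
        return rng.negative_binomial(r, p, size=size)
    return rng.poisson(design.depth_mean, size=size)


def _sample_rng(design: SimDesign, sample: SampleKey) -> np.random.Generator:
    keys = design_keys(sample.variety)
    return np.random.default_rng(
        np.random.SeedSequence([design.seed, 303, keys.index(sample)])
    )


def simulate_sample_counts(
    truth: TrueMethylome, sample: SampleKey, design: SimDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one sample's cytosine table and its lambda spike-in records.

    Coverage is Poisson(depth_mean) per site; methylated reads are
    binomial with the conversion-error-adjusted success probability.
    Returns ``(genome_table, lambda_table)``.
    """
    key = (sample.generation, sample.treatment)
    if key not in truth.levels:
        raise DesignError(f"truth does not cover generation/treatment {key}")
    rng = _sample_rng(design, sample)
    p_true = truth.levels[key]
    n = len(p_true)
    cov = _draw_coverage(rng, design, n)
    p_obs = p_true * (1.0 - design.conversion_failure_rate) + (
        1.0 - p_true
    ) * design.nonconversion_rate
    meth = rng.binomial(cov, p_obs)
    table = truth.sites[["chrom", "pos", "strand", "context", "trinucleotide"]].copy()
    table["meth"] = meth
    table["unmeth"] = cov - meth
    table = table[REPORT_COLUMNS]
    table["coverage"] = cov
    table["low_coverage"] = table["coverage"] < 3

    lam_cov = _draw_coverage(rng, design, design.lambda_sites)
    lam_meth = rng.binomial(lam_cov, design.nonconversion_rate)
    lam = pd.DataFrame(
        {
            "chrom": "lambda",
            "pos": np.arange(1, design.lambda_sites + 1) * 3,
            "strand": "+",
            "meth": lam_meth,
            "unmeth": lam_cov - lam_meth,
            "context": "CHH",
            "trinucleotide": "CTT",
        }
    )
    lam["coverage"] = lam_cov
    lam["low_coverage"] = lam["coverage"] < 3
    return table, lam


@dataclass
class SimulatedExperiment:
    design: SimDesign
    truth: TrueMethylome
    ledger: pd.DataFrame
    tables: dict[SampleKey, pd.DataFrame]
    lambda_tables: dict[SampleKey, pd.DataFrame]


def simulate_experiment(design: SimDesign, variety: str = "") -> SimulatedExperiment:
    """Full 16-sample experiment for one variety: truth, planted events
    and per-sample count tables.  Byte-identical for identical design."""
    ref = build_reference_methylome(design)
    truth, ledger = plant_epimutations(ref, design)
    tables: dict[SampleKey, pd.DataFrame] = {}
    lambdas: dict[SampleKey, pd.DataFrame] = {}
    for key in design_keys(variety):
        tables[key], lambdas[key] = simulate_sample_counts(truth, key, design)
    return SimulatedExperiment(design, truth, ledger, tables, lambdas)


def write_experiment(exp: SimulatedExperiment, outdir: str | Path) -> dict[str, str]:
    """Write reports, reference FASTA, GFF3 and ledger; return manifest
    of relative path -> description."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for key, df in exp.tables.items():
        name = f"{key.label}.cx.tsv"
        write_cytosine_report(df, outdir / name, {"sample": key.label})
        manifest[name] = "cytosine report"
    for key, df in exp.lambda_tables.items():
        name = f"{key.label}.lambda.cx.tsv"
        write_cytosine_report(df, outdir / name, {"sample": key.label, "spikein": "lambda"})
        manifest[name] = "lambda spike-in report"
    fasta = outdir / "reference.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in exp.truth.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    manifest["reference.fa"] = "reference sequence"
    write_features_gff3(exp.truth.features, outdir / "features.gff3")
    manifest["features.gff3"] = "gene/TE annotation"
    exp.ledger.to_csv(outdir / "truth_ledger.tsv", sep="\t", index=False)
    manifest["truth_ledger.tsv"] = "planted-event truth ledger"
    return manifest


def with_seed(design: SimDesign, seed: int) -> SimDesign:
    return replace(design, seed=seed)
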
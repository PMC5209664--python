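"""Sequence-context assignment, genic-region labelling, event
distribution summaries, DMR-gene overlap and metagene profiles.

Context is read from the reference on the cytosine's own strand: the
next base 3' decides CG, the next-but-one decides CHG, otherwise CHH
(H = A, C or T; contexts touching N or the chromosome end are
undefined).  Region labels follow a configurable precedence, by default
TE > CDS > 5'UTR > 3'UTR > intron > promoter > intergenic, with the
promoter as a fixed-length window upstream of the gene start on the
gene's strand.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FeatureSet

def load_reference(path) -> Mapping[str, str]:
    """Open a FASTA reference for random access (pyfaidx-backed)."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


DEFAULT_PRECEDENCE = (
    "TE",
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "intron",
    "promoter",
    "intergenic",
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class ContextError(ValueError):
    """The queried base is not a cytosine on the requested strand."""


def _base(reference: Mapping[str, str], chrom: str, pos: int) -> str | None:
    """Reference base at a 1-based position, or None outside bounds.

    ``reference`` is any mapping of chromosome name to sequence
    (a plain dict of strings or a pyfaidx.Fasta both work).
    """
    seq = reference[chrom]
    if pos < 1 or pos > len(seq):
        return None
    return str(seq[pos - 1]).upper()


def assign_context(
    reference: Mapping[str, str], chrom: str, pos: int, strand: str
) -> str | None:
    """CG/CHG/CHH context of the cytosine at (chrom, pos, strand).

    Reads the two downstream bases 5'->3' on the cytosine's strand;
    returns None when the context is undefined (N or chromosome end).
    """
    b0 = _base(reference, chrom, pos)
    expected_c = "C" if strand == "+" else "G"
    if b0 != expected_c:
        raise ContextError(
            f"{chrom}:{pos}({strand}) is {b0!r}, not a cytosine on that strand"
        )
    if strand == "+":
        b1 = _base(reference, chrom, pos + 1)
        b2 = _base(reference, chrom, pos + 2)
    else:
        b1 = _base(reference, chrom, pos - 1)
        b2 = _base(reference, chrom, pos - 2)
        b1 = _COMPLEMENT.get(b1) if b1 else None
        b2 = _COMPLEMENT.get(b2) if b2 else None
    if b1 is None or b1 == "N":
        return None
    if b1 == "G":
        return "CG"
    if b2 is None or b2 == "N":
        return None
    if b2 == "G":
        return "CHG"
    return "CHH"


def _promoter_intervals(features: FeatureSet, promoter_length: int) -> pd.DataFrame:
    genes = features.of_kind("gene")
    rows = []
    for _, g in genes.iterrows():
        if g["strand"] == "-":
            s, e = g["end"] + 1, g["end"] + promoter_length
        else:
            s, e = max(1, g["start"] - promoter_length), g["start"] - 1
        if e >= s:
            rows.append(
                {"chrom": g["chrom"], "start": s, "end": e, "strand": g["strand"],
                 "kind": "promoter", "id": f"{g['id']}.promoter"}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "kind", "id"])


def assign_region(
    chrom: str,
    pos: int,
    features: FeatureSet,
    promoter_length: int = 1000,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> str:
    """Region label of a single site (see :func:`annotate_sites`)."""
    sites = pd.DataFrame({"chrom": [chrom], "pos": [pos]})
    return annotate_sites(sites, features, promoter_length, precedence)[0]


def annotate_sites(
    sites: pd.DataFrame,
    features: FeatureSet,
    promoter_length: int = 1000,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> np.ndarray:
    """Vectorised region labelling of (chrom, pos) sites.

    Each site gets the highest-precedence feature kind containing it;
    sites inside a gene but outside any annotated gene part are
    labelled ``intron`` when introns are annotated, otherwise the gene
    itself ranks like an intron.  Sites covered by nothing are
    ``intergenic``.
    """
    prec = list(precedence)
    if "intergenic" not in prec:
        prec.append("intergenic")
    rank = {k: i for i, k in enumerate(prec)}
    n = len(sites)
    best = np.full(n, rank["intergenic"])

    feat = features.df.copy()
    promoters = _promoter_intervals(features, promoter_length)
    if len(promoters):
        feat = pd.concat([feat, promoters], ignore_index=True)
    # a bare gene interval ranks at intron level: gene-body fallback
    feat["kind_eff"] = feat["kind"].where(feat["kind"] != "gene", "intron")

    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        cmask = chrom_arr == chrom
        cpos = pos_arr[cmask]
        cbest = best[cmask]
        for _, f in feat[feat["chrom"] == chrom].iterrows():
            r = rank.get(f["kind_eff"])
            if r is None:
                continue
            inside = (cpos >= f["start"]) & (cpos <= f["end"])
            cbest = np.where(inside & (r < cbest), r, cbest)
        best[cmask] = cbest
    inv = {i: k for k, i in rank.items()}
    return np.array([inv[i] for i in best], dtype=object)


def distribution_summary(
    events: pd.DataFrame,
    contexts: Sequence[str] = ("CG", "CHG", "CHH"),
    regions: Sequence[str] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Counts of events by (context, region, direction).

    Events must carry ``context``, ``region`` and ``direction``
    columns; unknown values are tallied under "unknown" so that the
    marginals conserve the event total exactly.
    """
    ev = events.copy()
    ev["context"] = ev["context"].where(ev["context"].isin(contexts), "unknown")
    ev["region"] = ev["region"].where(ev["region"].isin(regions), "unknown")
    out = (
        ev.groupby(["context", "region", "direction"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def overlap_dmrs_genes(
    dmrs: pd.DataFrame, features: FeatureSet, promoter_length: int = 1000
) -> pd.DataFrame:
    """(gene, DMR) associations with location promoter/body.

    One row per overlapping pair; the location is whichever of the
    gene's promoter window or body covers the larger share of the DMR
    (ties go to body).
    """
    genes = features.of_kind("gene")
    promoters = _promoter_intervals(features, promoter_length)
    rows = []
    for di, d in dmrs.iterrows():
        dmr_id = d.get("id", f"DMR{di + 1}")
        for _, g in genes.iterrows():
            if g["chrom"] != d["chrom"]:
                continue
            body_ov = max(
                0, min(d["end"], g["end"]) - max(d["start"], g["start"]) + 1
            )
            prom = promoters[promoters["id"] == f"{g['id']}.promoter"]
            prom_ov = 0
            if len(prom):
                p = prom.iloc[0]
                prom_ov = max(
                    0, min(d["end"], p["end"]) - max(d["start"], p["start"]) + 1
                )
            if body_ov == 0 and prom_ov == 0:
                continue
            rows.append(
                {
                    "gene_id": g["id"],
                    "dmr_id": dmr_id,
                    "location": "promoter" if prom_ov > body_ov else "body",
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "dmr_id", "location"])


def metagene_profile(
    levels: pd.DataFrame,
    features: FeatureSet,
    kind: str = "gene",
    flank: int = 1000,
    body_bins: int = 60,
    flank_bins: int = 20,
) -> pd.DataFrame:
    """Mean methylation level along scaled feature bodies and absolute
    1-kb flanks, strand-aware (TSS on the left).

    ``levels`` carries chrom, pos and level columns (one context or
    sample).  Per feature, sites falling in each bin are averaged; the
    profile is the unweighted mean across features per bin.  Returns a
    frame with bin index, segment (upstream/body/downstream) and mean
    level.
    """
    feats = features.of_kind(kind)
    if len(feats) == 0:
        raise ValueError(f"no features of kind {kind!r}")
    n_bins = 2 * flank_bins + body_bins
    sums = np.zeros(n_bins)
    cnts = np.zeros(n_bins)
    by_chrom = {c: g.sort_values("pos") for c, g in levels.groupby("chrom")}
    for _, f in feats.iterrows():
        g = by_chrom.get(f["chrom"])
        if g is None:
            continue
        pos = g["pos"].to_numpy()
        lvl = g["level"].to_numpy(dtype=float)
        lo = np.searchsorted(pos, f["start"] - flank, side="left")
        hi = np.searchsorted(pos, f["end"] + flank, side="right")
        if hi <= lo:
            continue
        p = pos[lo:hi].astype(float)
        v = lvl[lo:hi]
        start, end = float(f["start"]), float(f["end"])
        length = end - start + 1.0
        bins = np.empty(len(p), dtype=int)
        upstream = p < start
        downstream = p > end
        body = ~upstream & ~downstream
        bins[upstream] = np.clip(
            ((p[upstream] - (start - flank)) / flank * flank_bins).astype(int),
            0,
            flank_bins - 1,
        )
        bins[body] = flank_bins + np.clip(
            ((p[body] - start) / length * body_bins).astype(int), 0, body_bins - 1
        )
        bins[downstream] = flank_bins + body_bins + np.clip(
            ((p[downstream] - end - 1) / flank * flank_bins).astype(int),
            0,
            flank_bins - 1,
        )
        if f["strand"] == "-":
            bins = n_bins - 1 - bins
        feat_sum = np.bincount(bins, weights=v, minlength=n_bins)
        feat_cnt = np.bincount(bins, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            feat_mean = feat_sum / feat_cnt
        hit = feat_cnt > 0
        sums[hit] += feat_mean[hit]
        cnts[hit] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    segment = (
        ["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins
    )
    return pd.DataFrame({"bin": np.arange(n_bins), "segment": segment, "mean_level": mean})
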
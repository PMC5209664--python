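"""DMP, SMP and DMR identification between two sample groups.

A *group* is the pair of sibling replicates of one (generation,
treatment).  DMPs are cytosines whose methylation LEVEL differs:
Fisher's exact test on the (meth, unmeth) 2x2 table for each of the
four cross-group replicate pairings, combined conservatively by
Bonferroni (min p x 4); candidate sites additionally require both
within-group replicate tests to be non-significant (the replicate-DMP
filter) and pass genome-wide Benjamini-Hochberg FDR control.  SMPs are
cytosines whose binary STATUS differs with full replicate concordance.
DMRs are DMP-clustered regions found with a 200-bp window / 50-bp step
scan, window-level Fisher tests on pooled counts, BH adjustment, a
1.5-fold level-change requirement and at least seven concordant DMPs,
with qualifying windows merged across gaps of at most 100 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SITE_KEY, DesignError, SampleKey

DMP_COLUMNS = [
    "chrom", "pos", "strand", "context", "direction",
    "combined_p", "q", "level_g1", "level_g2",
]
SMP_COLUMNS = ["chrom", "pos", "strand", "context", "direction"]
DMR_COLUMNS = [
    "chrom", "start", "end", "direction", "n_dmps",
    "level_g1", "level_g2", "fold", "adj_p",
]


@dataclass(frozen=True)
class GroupSpec:
    """The two sibling replicates of one (generation, treatment)."""

    rep1: SampleKey
    rep2: SampleKey

    def __post_init__(self) -> None:
        same = (
            self.rep1.generation == self.rep2.generation
            and self.rep1.treatment == self.rep2.treatment
        )
        if not same:
            raise DesignError("group replicates must share generation and treatment")

    @property
    def label(self) -> str:
        return f"{self.rep1.treatment}{self.rep1.generation[1:]}"


@lru_cache(maxsize=1_000_000)
def fisher_p(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Cached Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def _fisher_batch(tables: np.ndarray, alternative: str = "two-sided") -> np.ndarray:
    """Fisher p-values for an (n, 4) array of tables, deduplicated."""
    if len(tables) == 0:
        return np.empty(0)
    uniq, inverse = np.unique(tables, axis=0, return_inverse=True)
    p_uniq = np.array(
        [fisher_p(int(a), int(b), int(c), int(d), alternative) for a, b, c, d in uniq]
    )
    return p_uniq[inverse]


def _aligned_counts(
    tables: dict, keys: list[SampleKey], eligible: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """(n_sites, n_samples) meth and unmeth arrays on the eligible set."""
    idx = pd.MultiIndex.from_frame(eligible[SITE_KEY])
    meth = np.empty((len(idx), len(keys)), dtype=int)
    unmeth = np.empty_like(meth)
    for j, k in enumerate(keys):
        df = tables[k].set_index(SITE_KEY)
        sub = df.reindex(idx)
        if sub["meth"].isna().any():
            missing = int(sub["meth"].isna().sum())
            raise DesignError(
                f"sample {k.label}: {missing} eligible sites absent from table"
            )
        meth[:, j] = sub["meth"].to_numpy(dtype=int)
        unmeth[:, j] = sub["unmeth"].to_numpy(dtype=int)
    return meth, unmeth


def call_dmps(
    g1: GroupSpec,
    g2: GroupSpec,
    tables: dict,
    eligible: pd.DataFrame,
    p_thresh: float = 0.01,
    fdr: float = 0.05,
    combine: str = "cross-pair",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Differentially methylated positions, group 1 relative to group 2.

    ``combine="cross-pair"`` (default) runs the four replicate-pair
    Fisher tests and Bonferroni-combines them; ``combine="pooled"``
    pools replicate counts into a single test per site.  Direction is
    ``hyper`` when the pooled level of group 1 exceeds group 2.
    """
    if combine not in ("cross-pair", "pooled"):
        raise ValueError(f"unknown combine mode {combine!r}")
    keys = [g1.rep1, g1.rep2, g2.rep1, g2.rep2]
    meth, unmeth = _aligned_counts(tables, keys, eligible)

    if combine == "cross-pair":
        pair_ps = []
        for i in (0, 1):
            for j in (2, 3):
                t = np.column_stack(
                    [meth[:, i], unmeth[:, i], meth[:, j], unmeth[:, j]]
                )
                pair_ps.append(_fisher_batch(t, alternative))
        combined = np.minimum(1.0, 4.0 * np.min(np.column_stack(pair_ps), axis=1))
    else:
        t = np.column_stack(
            [
                meth[:, 0] + meth[:, 1],
                unmeth[:, 0] + unmeth[:, 1],
                meth[:, 2] + meth[:, 3],
                unmeth[:, 2] + unmeth[:, 3],
            ]
        )
        combined = _fisher_batch(t, alternative)

    # replicate-DMP filter: within-group tests must be non-significant
    w1 = _fisher_batch(
        np.column_stack([meth[:, 0], unmeth[:, 0], meth[:, 1], unmeth[:, 1]]),
        alternative,
    )
    w2 = _fisher_batch(
        np.column_stack([meth[:, 2], unmeth[:, 2], meth[:, 3], unmeth[:, 3]]),
        alternative,
    )
    concordant = (w1 >= p_thresh) & (w2 >= p_thresh)

    # genome-wide FDR control: BH over all eligible sites
    q = np.ones(len(combined))
    if len(combined):
        _, q, _, _ = multipletests(combined, method="fdr_bh")
    keep = (combined < p_thresh) & concordant & (q <= fdr)

    cov1 = meth[:, :2].sum(axis=1) + unmeth[:, :2].sum(axis=1)
    cov2 = meth[:, 2:].sum(axis=1) + unmeth[:, 2:].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lvl1 = np.where(cov1 > 0, meth[:, :2].sum(axis=1) / cov1, np.nan)
        lvl2 = np.where(cov2 > 0, meth[:, 2:].sum(axis=1) / cov2, np.nan)
    keep &= lvl1 != lvl2  # no direction for exactly equal pooled levels

    out = eligible.loc[keep, SITE_KEY].reset_index(drop=True)
    ctx = tables[keys[0]].set_index(SITE_KEY)["context"]
    out["context"] = ctx.reindex(pd.MultiIndex.from_frame(out[SITE_KEY])).to_numpy()
    out["direction"] = np.where(lvl1[keep] > lvl2[keep], "hyper", "hypo")
    out["combined_p"] = combined[keep]
    out["q"] = q[keep]
    out["level_g1"] = lvl1[keep]
    out["level_g2"] = lvl2[keep]
    return out[DMP_COLUMNS]


def call_smps(
    g1: GroupSpec,
    g2: GroupSpec,
    statuses: pd.DataFrame,
    panel: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Single-cytosine methylation polymorphisms between two groups.

    ``statuses`` is a status matrix (sites x samples, values M/U/NC).
    A site is an SMP when both group-1 replicates share one status,
    both group-2 replicates share the other, and (when the full
    16-sample ``panel`` matrix is given) the site is not invariant
    across the whole panel.  Direction is ``re_methylated`` when group 1
    is methylated and group 2 unmethylated.
    """
    cols1 = [str(g1.rep1), str(g1.rep2)]
    cols2 = [str(g2.rep1), str(g2.rep2)]
    s11, s12 = statuses[cols1[0]], statuses[cols1[1]]
    s21, s22 = statuses[cols2[0]], statuses[cols2[1]]
    callable_mask = pd.concat([s11, s12, s21, s22], axis=1).isin(["M", "U"]).all(axis=1)
    concordant = (s11 == s12) & (s21 == s22)
    differs = s11 != s21
    keep = callable_mask & concordant & differs
    if panel is not None:
        statuses_p = panel.reindex(statuses.index)
        invariant = statuses_p.nunique(axis=1) == 1
        fully_callable = statuses_p.isin(["M", "U"]).all(axis=1)
        keep &= ~(invariant & fully_callable)
        keep &= fully_callable
    out = statuses.index[keep].to_frame(index=False)
    out.columns = SITE_KEY
    out["context"] = np.nan
    out["direction"] = np.where(
        s11[keep] == "M", "re_methylated", "de_methylated"
    )
    return out[SMP_COLUMNS]


# ---------------------------------------------------------------------------
# DMRs
# ---------------------------------------------------------------------------

def _merge_intervals(
    windows: pd.DataFrame, merge_gap: int
) -> list[tuple[str, str, int, int, list[int]]]:
    """Merge same-direction windows whose gap is <= merge_gap.

    Returns (chrom, direction, start, end, member row indices); merging
    is idempotent: re-merging the output changes nothing.
    """
    merged: list[tuple[str, str, int, int, list[int]]] = []
    for (chrom, direction), grp in windows.groupby(["chrom", "direction"], sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_s = cur_e = None
        members: list[int] = []
        for ridx, row in grp.iterrows():
            s, e = int(row["start"]), int(row["end"])
            if cur_s is None:
                cur_s, cur_e, members = s, e, [ridx]
            elif s - cur_e - 1 <= merge_gap:
                cur_e = max(cur_e, e)
                members.append(ridx)
            else:
                merged.append((chrom, direction, cur_s, cur_e, members))
                cur_s, cur_e, members = s, e, [ridx]
        if cur_s is not None:
            merged.append((chrom, direction, cur_s, cur_e, members))
    return merged


def call_dmrs(
    g1: GroupSpec,
    g2: GroupSpec,
    tables: dict,
    dmps: pd.DataFrame,
    eligible: pd.DataFrame,
    window: int = 200,
    step: int = 50,
    min_dmps: int = 7,
    fold: float = 1.5,
    adj_p: float = 0.01,
    merge_gap: int = 100,
    boundaries: str = "trim",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Differentially methylated regions from a sliding-window scan.

    Windows of ``window`` bp tile each chromosome from position 1 with
    ``step`` bp steps.  Per window, Fisher's exact test compares the
    pooled replicate (meth, unmeth) counts of the two groups; p-values
    are BH-adjusted over all tested windows.  A window qualifies when
    its adjusted p < ``adj_p``, its level changed at least ``fold``-fold
    and it contains >= ``min_dmps`` DMPs matching the window direction.
    Qualifying same-direction windows separated by <= ``merge_gap`` bp
    are combined.  With ``boundaries="trim"`` (default) the reported
    DMR is trimmed to the outermost contributing DMPs;
    ``boundaries="windows"`` reports the raw window union.
    """
    if boundaries not in ("trim", "windows"):
        raise ValueError(f"unknown boundaries mode {boundaries!r}")
    keys = [g1.rep1, g1.rep2, g2.rep1, g2.rep2]
    meth, unmeth = _aligned_counts(tables, keys, eligible)
    m1 = meth[:, :2].sum(axis=1)
    u1 = unmeth[:, :2].sum(axis=1)
    m2 = meth[:, 2:].sum(axis=1)
    u2 = unmeth[:, 2:].sum(axis=1)
    chroms = eligible["chrom"].to_numpy()
    pos = eligible["pos"].to_numpy()

    dmp_pos: dict[str, np.ndarray] = {}
    dmp_dir: dict[str, np.ndarray] = {}
    if len(dmps):
        for chrom, grp in dmps.groupby("chrom", sort=True):
            grp = grp.sort_values("pos")
            dmp_pos[chrom] = grp["pos"].to_numpy()
            dmp_dir[chrom] = grp["direction"].to_numpy()

    win_rows: list[dict] = []
    for chrom in pd.unique(chroms):
        cmask = chroms == chrom
        cpos = pos[cmask]
        cm1, cu1, cm2, cu2 = m1[cmask], u1[cmask], m2[cmask], u2[cmask]
        order = np.argsort(cpos, kind="mergesort")
        cpos = cpos[order]
        cm1, cu1, cm2, cu2 = cm1[order], cu1[order], cm2[order], cu2[order]
        if len(cpos) == 0:
            continue
        chrom_end = int(cpos[-1])
        dpos = dmp_pos.get(chrom, np.empty(0, dtype=int))
        ddir = dmp_dir.get(chrom, np.empty(0, dtype=object))
        for start in range(1, chrom_end + 1, step):
            end = start + window - 1
            partial = end > chrom_end
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, end, side="right")
            n_sites = hi - lo
            if n_sites == 0:
                continue
            if partial and n_sites < min_dmps:
                continue
            wm1, wu1 = int(cm1[lo:hi].sum()), int(cu1[lo:hi].sum())
            wm2, wu2 = int(cm2[lo:hi].sum()), int(cu2[lo:hi].sum())
            cov1, cov2 = wm1 + wu1, wm2 + wu2
            if cov1 == 0 or cov2 == 0:
                continue
            sl1 = cm1[lo:hi] / np.maximum(1, cm1[lo:hi] + cu1[lo:hi])
            sl2 = cm2[lo:hi] / np.maximum(1, cm2[lo:hi] + cu2[lo:hi])
            lvl1 = float(sl1.mean())
            lvl2 = float(sl2.mean())
            if lvl1 == 0.0 and lvl2 == 0.0:
                continue
            eps1 = lvl1 if lvl1 > 0 else 1.0 / (cov1 + 1)
            eps2 = lvl2 if lvl2 > 0 else 1.0 / (cov2 + 1)
            fold_change = max(eps1, eps2) / min(eps1, eps2)
            dlo = np.searchsorted(dpos, start, side="left")
            dhi = np.searchsorted(dpos, end, side="right")
            direction = "hyper" if lvl1 > lvl2 else "hypo"
            in_dir = ddir[dlo:dhi] == direction
            win_rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": min(end, chrom_end),
                    "table": (wm1, wu1, wm2, wu2),
                    "level_g1": lvl1,
                    "level_g2": lvl2,
                    "fold": fold_change,
                    "direction": direction,
                    "n_dmps": int(in_dir.sum()),
                    "dmp_positions": dpos[dlo:dhi][in_dir],
                }
            )

    if not win_rows:
        return pd.DataFrame(columns=DMR_COLUMNS)
    win = pd.DataFrame(win_rows)
    p = _fisher_batch(np.array([t for t in win["table"]]), alternative)
    _, win["adj_p"], _, _ = multipletests(p, method="fdr_bh")
    qual = win[
        (win["adj_p"] < adj_p)
        & (win["fold"] >= fold)
        & (win["n_dmps"] >= min_dmps)
    ]
    if qual.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)

    rows: list[dict] = []
    for chrom, direction, s, e, members in _merge_intervals(qual, merge_gap):
        member_rows = qual.loc[members]
        all_dmps = np.unique(np.concatenate(list(member_rows["dmp_positions"])))
        if boundaries == "trim" and len(all_dmps):
            s_out, e_out = int(all_dmps.min()), int(all_dmps.max())
        else:
            s_out, e_out = s, e
        cmask = (chroms == chrom) & (pos >= s) & (pos <= e)
        wm1, wu1 = int(m1[cmask].sum()), int(u1[cmask].sum())
        wm2, wu2 = int(m2[cmask].sum()), int(u2[cmask].sum())
        sl1 = m1[cmask] / np.maximum(1, m1[cmask] + u1[cmask])
        sl2 = m2[cmask] / np.maximum(1, m2[cmask] + u2[cmask])
        lvl1 = float(sl1.mean()) if cmask.any() else np.nan
        lvl2 = float(sl2.mean()) if cmask.any() else np.nan
        eps1 = lvl1 if lvl1 > 0 else 1.0 / (wm1 + wu1 + 1)
        eps2 = lvl2 if lvl2 > 0 else 1.0 / (wm2 + wu2 + 1)
        rows.append(
            {
                "chrom": chrom,
                "start": s_out,
                "end": e_out,
                "direction": direction,
                "n_dmps": int(len(all_dmps)),
                "level_g1": lvl1,
                "level_g2": lvl2,
                "fold": max(eps1, eps2) / min(eps1, eps2),
                "adj_p": float(member_rows["adj_p"].min()),
            }
        )
    out = pd.DataFrame(rows, columns=DMR_COLUMNS)
    return out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    """DMRs as BED6+3 (0-based half-open; direction in the name field)."""
    with open(path, "w") as fh:
        fh.write("# epimethyl DMRs: chrom start0 end name score strand n_dmps fold adj_p\n")
        for _, r in dmrs.iterrows():
            fh.write(
                "\t".join(
                    [
                        str(r["chrom"]),
                        str(int(r["start"]) - 1),
                        str(int(r["end"])),
                        str(r["direction"]),
                        "0",
                        ".",
                        str(int(r["n_dmps"])),
                        f"{r['fold']:.4g}",
                        f"{r['adj_p']:.4g}",
                    ]
                )
                + "\n"
            )
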
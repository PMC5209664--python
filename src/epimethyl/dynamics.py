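"""Recurrence ("hot spot"), maintenance, transgenerational-inheritance
and clustering analyses over called epimutation events.

Events from K independent comparisons are matched by locus identity:
exact (chrom, pos, strand) plus direction for DMPs and SMPs, and
reciprocal overlap >= 50% plus direction for DMRs.  A locus is
*recurring* when it appears in at least two comparisons with the same
direction.  The null expectation under uniform random placement of each
comparison's events over the eligible-site universe is computed either
analytically (from the per-site hit probabilities p_i = k_i / N) or by
seeded permutation.

Maintenance: a drought-induced event (D0 vs W0) is maintained when the
same locus and direction recur in the advanced drought-vs-control
comparisons (any or all of them, per mode).  Transgenerational: an
accumulated event (D10 vs D0) is transgenerational when it recurs in
both a drought-treated offspring comparison (G10 -> G11) and the
well-watered recovery comparison (G10 -> G10R1).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import DesignError

POINT_KINDS = ("DMP", "SMP")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of all printed
    percentages reproduced by this package)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(num: float, den: float, ndigits: int = 2) -> float:
    if den == 0:
        raise ZeroDivisionError("zero denominator in percentage")
    return round_half_up(100.0 * num / den, ndigits)


# ---------------------------------------------------------------------------
# locus matching
# ---------------------------------------------------------------------------

def _point_keys(df: pd.DataFrame) -> pd.Series:
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(int).astype(str)
        + ":"
        + df["strand"].astype(str)
        + ":"
        + df["direction"].astype(str)
    )


def _reciprocal_overlap(s1: int, e1: int, s2: int, e2: int) -> float:
    inter = min(e1, e2) - max(s1, s2) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (e1 - s1 + 1), inter / (e2 - s2 + 1))


class _IntervalClusters:
    """Greedy clustering of same-direction intervals across comparisons
    by reciprocal overlap with each cluster's founding interval."""

    def __init__(self, min_frac: float = 0.5) -> None:
        self.min_frac = min_frac
        self.reps: list[tuple[str, str, int, int]] = []

    def assign(self, chrom: str, direction: str, start: int, end: int) -> int:
        best_i, best_ov = -1, 0.0
        for i, (c, d, s, e) in enumerate(self.reps):
            if c != chrom or d != direction:
                continue
            ov = _reciprocal_overlap(start, end, s, e)
            if ov >= self.min_frac and ov > best_ov:
                best_i, best_ov = i, ov
        if best_i >= 0:
            return best_i
        self.reps.append((chrom, direction, start, end))
        return len(self.reps) - 1


def match_interval_events(
    event_sets: Mapping[str, pd.DataFrame], min_frac: float = 0.5
) -> pd.DataFrame:
    """Cluster interval events across comparisons; returns a frame with
    one row per cluster and one boolean column per comparison."""
    clusters = _IntervalClusters(min_frac)
    hits: dict[int, set[str]] = {}
    for label in sorted(event_sets):
        df = event_sets[label]
        for _, r in df.iterrows():
            ci = clusters.assign(
                str(r["chrom"]), str(r["direction"]), int(r["start"]), int(r["end"])
            )
            hits.setdefault(ci, set()).add(label)
    rows = []
    for ci, (chrom, direction, s, e) in enumerate(clusters.reps):
        row = {"chrom": chrom, "direction": direction, "start": s, "end": e}
        for label in event_sets:
            row[label] = label in hits.get(ci, set())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recurrence
# ---------------------------------------------------------------------------

def recurrence_analysis(
    event_sets: Mapping[str, pd.DataFrame],
    eligible_n: int,
    kind: str = "DMP",
    seed: int | None = None,
    expected_method: str = "analytic",
) -> pd.DataFrame:
    """Recurrence table over K comparisons' events of one kind.

    Returns one row per direction with distinct-locus counts by
    recurrence frequency 1..K, the observed recurring fraction
    (frequency >= 2) and the random expectation for the same
    per-comparison event counts over ``eligible_n`` sites.
    """
    labels = sorted(event_sets)
    K = len(labels)
    if K < 1:
        raise DesignError("recurrence analysis needs at least one comparison")

    if kind in POINT_KINDS:
        per_dir: dict[str, pd.DataFrame] = {}
        frames = []
        for label in labels:
            df = event_sets[label]
            frames.append(
                pd.DataFrame({"key": _point_keys(df), "direction": df["direction"]})
            )
        allev = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        rows = []
        directions = sorted(allev["direction"].unique()) if len(allev) else []
        for direction in directions:
            sub = allev[allev["direction"] == direction]
            freq = sub.groupby("key").size()
            counts = [
                int(event_sets[label]["direction"].eq(direction).sum())
                for label in labels
            ]
            rows.append(
                _recurrence_row(direction, freq, counts, eligible_n, K,
                                expected_method, seed)
            )
        return pd.DataFrame(rows)

    # interval events (DMRs)
    matched = match_interval_events(event_sets)
    rows = []
    for direction in sorted(matched["direction"].unique()) if len(matched) else []:
        sub = matched[matched["direction"] == direction]
        freq = sub[labels].sum(axis=1)
        counts = [
            int(event_sets[label]["direction"].eq(direction).sum()) for label in labels
        ]
        rows.append(
            _recurrence_row(direction, freq, counts, eligible_n, K,
                            expected_method, seed)
        )
    return pd.DataFrame(rows)


def _recurrence_row(
    direction: str,
    freq: pd.Series,
    counts: Sequence[int],
    eligible_n: int,
    K: int,
    expected_method: str,
    seed: int | None,
) -> dict:
    n_distinct = int(len(freq))
    if eligible_n < n_distinct:
        raise DesignError(
            f"eligible_n {eligible_n} smaller than distinct loci {n_distinct}"
        )
    recurring = int((freq >= 2).sum())
    row: dict = {"direction": direction, "n_distinct": n_distinct,
                 "n_recurring": recurring}
    for f in range(1, K + 1):
        row[f"freq_{f}"] = int((freq == f).sum())
    row["observed_recurring_fraction"] = recurring / n_distinct if n_distinct else 0.0
    row["expected_random_fraction"] = expected_random_recurrence(
        counts, eligible_n, method=expected_method, seed=seed
    )
    return row


def expected_random_recurrence(
    event_counts: Sequence[int],
    eligible_n: int,
    method: str = "analytic",
    seed: int | None = None,
    replicates: int = 100,
) -> float:
    """Expected recurring fraction under uniform random placement.

    Analytic: with per-comparison hit probabilities p_i = k_i / N
    independent across comparisons, returns E[#loci hit >= 2] /
    E[#loci hit >= 1].  Permutation: mean over ``replicates`` seeded
    uniform placements of the per-replicate recurring fraction.
    """
    counts = [int(k) for k in event_counts]
    N = int(eligible_n)
    for k in counts:
        if k > N:
            raise DesignError(f"event count {k} exceeds eligible universe {N}")
    if len(counts) <= 1 or sum(counts) == 0:
        return 0.0
    if method == "analytic":
        p = np.array(counts, dtype=float) / N
        none = np.prod(1.0 - p)
        exactly_one = sum(
            p[i] * np.prod(np.delete(1.0 - p, i)) for i in range(len(p))
        )
        p_ge1 = 1.0 - none
        p_ge2 = p_ge1 - exactly_one
        return float(p_ge2 / p_ge1) if p_ge1 > 0 else 0.0
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(replicates):
        draws = []
        for k in counts:
            # distinct loci per comparison: redraw collisions
            got = np.unique(rng.integers(0, N, size=k))
            while len(got) < k:
                extra = rng.integers(0, N, size=k - len(got))
                got = np.unique(np.concatenate([got, extra]))
            draws.append(got)
        allhits = np.concatenate(draws)
        _, hit_counts = np.unique(allhits, return_counts=True)
        n_distinct = len(hit_counts)
        fracs.append((hit_counts >= 2).sum() / n_distinct if n_distinct else 0.0)
    return float(np.mean(fracs))


# ---------------------------------------------------------------------------
# maintenance / transgenerational inheritance
# ---------------------------------------------------------------------------

def _match_events(
    reference: pd.DataFrame, others: Iterable[pd.DataFrame], kind: str,
    min_frac: float = 0.5,
) -> np.ndarray:
    """(n_ref, n_other) boolean presence matrix of reference events in
    each other event set (same locus and direction)."""
    others = list(others)
    out = np.zeros((len(reference), len(others)), dtype=bool)
    if len(reference) == 0:
        return out
    if kind in POINT_KINDS:
        ref_keys = _point_keys(reference)
        for j, df in enumerate(others):
            keys = set(_point_keys(df)) if len(df) else set()
            out[:, j] = ref_keys.isin(keys).to_numpy()
        return out
    for j, df in enumerate(others):
        if len(df) == 0:
            continue
        for i, (_, r) in enumerate(reference.iterrows()):
            sub = df[(df["chrom"] == r["chrom"]) & (df["direction"] == r["direction"])]
            for _, o in sub.iterrows():
                if (
                    _reciprocal_overlap(
                        int(r["start"]), int(r["end"]), int(o["start"]), int(o["end"])
                    )
                    >= min_frac
                ):
                    out[i, j] = True
                    break
    return out


def _inheritance_report(
    reference: pd.DataFrame, flag: np.ndarray, stat_name: str
) -> pd.DataFrame:
    rows = []
    directions = sorted(reference["direction"].unique()) if len(reference) else []
    for direction in directions:
        mask = (reference["direction"] == direction).to_numpy()
        n = int(mask.sum())
        n_pos = int(flag[mask].sum())
        rows.append(
            {
                "direction": direction,
                "n_events": n,
                stat_name: n_pos,
                "percentage": percent(n_pos, n) if n else 0.0,
            }
        )
    n_tot = int(len(reference))
    n_pos_tot = int(flag.sum())
    pooled = {
        "direction": "pooled",
        "n_events": n_tot,
        stat_name: n_pos_tot,
        "percentage": percent(n_pos_tot, n_tot) if n_tot else 0.0,
    }
    if n_pos_tot:
        for direction in directions:
            mask = (reference["direction"] == direction).to_numpy()
            share = percent(int(flag[mask].sum()), n_pos_tot)
            pooled[f"share_{direction}"] = share
    rows.append(pooled)
    return pd.DataFrame(rows)


def classify_maintenance(
    induced: pd.DataFrame,
    advanced: Mapping[str, pd.DataFrame],
    kind: str = "DMP",
    mode: str = "any",
) -> pd.DataFrame:
    """Which drought-induced events kept their changed status in the
    advanced-generation drought-vs-control comparisons.

    ``mode="any"`` (default): maintained when the locus+direction
    appears in at least one advanced comparison; ``mode="all"``:
    required in every one.
    """
    if mode not in ("any", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(induced) == 0:
        return _inheritance_report(induced, np.zeros(0, dtype=bool), "n_maintained")
    presence = _match_events(induced, [advanced[k] for k in sorted(advanced)], kind)
    flag = presence.any(axis=1) if mode == "any" else presence.all(axis=1)
    return _inheritance_report(induced, flag, "n_maintained")


def classify_transgenerational(
    accumulated: pd.DataFrame,
    drought_offspring: Mapping[str, pd.DataFrame],
    recovery: Mapping[str, pd.DataFrame],
    kind: str = "DMP",
) -> pd.DataFrame:
    """Which accumulated events were transmitted to offspring.

    Transgenerational = present (same locus and direction) in at least
    one drought-treated offspring comparison AND at least one
    well-watered recovery comparison.
    """
    if len(accumulated) == 0:
        return _inheritance_report(
            accumulated, np.zeros(0, dtype=bool), "n_transgenerational"
        )
    p1 = _match_events(
        accumulated, [drought_offspring[k] for k in sorted(drought_offspring)], kind
    )
    p2 = _match_events(accumulated, [recovery[k] for k in sorted(recovery)], kind)
    flag = p1.any(axis=1) & p2.any(axis=1)
    return _inheritance_report(accumulated, flag, "n_transgenerational")


def tally_report(counts: Mapping[str, tuple[float, float]]) -> pd.DataFrame:
    """Percentage table from labelled numerator/denominator pairs, with
    an aggregate row computed as sum(num) / sum(den)."""
    rows = []
    total_num = total_den = 0.0
    for label, (num, den) in counts.items():
        if den == 0:
            raise ZeroDivisionError(f"zero denominator for {label!r}")
        rows.append(
            {"label": label, "numerator": num, "denominator": den,
             "percentage": percent(num, den)}
        )
        total_num += num
        total_den += den
    rows.append(
        {
            "label": "total",
            "numerator": total_num,
            "denominator": total_den,
            "percentage": percent(total_num, total_den) if total_den else 0.0,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sample clustering
# ---------------------------------------------------------------------------

def cluster_samples(
    levels: pd.DataFrame,
    linkage: str = "average",
    metric: str = "euclidean",
) -> tuple[str, np.ndarray, list[str]]:
    """Agglomerative clustering of samples by methylation levels.

    ``levels`` is samples x loci; loci with an undefined level in any
    sample are dropped.  Samples are ordered lexicographically by label
    before linkage so that ties break deterministically.  Returns
    (newick string with branch lengths, linkage matrix, leaf labels).
    """
    if linkage != "average":
        raise ValueError("only average linkage is supported")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    if levels.shape[0] < 3:
        raise DesignError("clustering needs at least 3 samples")
    levels = levels.sort_index()
    clean = levels.dropna(axis=1)
    if clean.shape[1] == 0:
        raise DesignError("no loci with defined levels in all samples")
    dist = pdist(clean.to_numpy(dtype=float), metric=metric)
    Z = hierarchy.linkage(dist, method="average")
    labels = [str(x) for x in clean.index]
    tree = hierarchy.to_tree(Z)

    def newick(node, parent_height: float) -> str:
        length = max(0.0, parent_height - (node.dist if not node.is_leaf() else 0.0))
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    nwk = f"({newick(tree.left, tree.dist)},{newick(tree.right, tree.dist)});"
    return nwk, Z, labels


def dendrogram_clades(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    """All internal-node leaf sets of a linkage tree."""
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    clades = []
    for i, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        clades.append(merged)
    return clades


def sibling_adjacency_score(Z: np.ndarray, labels: list[str]) -> float:
    """Fraction of sibling replicate pairs that merge as immediate
    leaf pairs in the dendrogram.

    Sibling pairs are inferred from labels of the form ``..._r1`` /
    ``..._r2`` sharing their prefix.
    """
    prefixes = {}
    for lab in labels:
        stem, _, rep = lab.rpartition("_r")
        if rep in ("1", "2"):
            prefixes.setdefault(stem, set()).add(lab)
    pairs = [frozenset(v) for v in prefixes.values() if len(v) == 2]
    if not pairs:
        raise DesignError("no sibling pairs found in labels")
    n = len(labels)
    leaf_merges = set()
    for a, b, _, _ in Z:
        if a < n and b < n:
            leaf_merges.add(frozenset([labels[int(a)], labels[int(b)]]))
    return sum(1 for p in pairs if p in leaf_merges) / len(pairs)
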
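"""Conversion-rate calibration, binomial methylation calling, and
methylation level/density summaries.

A cytosine is called methylated when its methylated-read count is
significantly above the background expected from incomplete bisulfite
conversion and T-C sequencing error.  The per-read error probability is

    p_error = 1 - (1 - nonconversion_rate) * (1 - tc_error_rate)

with the non-conversion rate estimated from an unmethylated lambda
phage spike-in.  One-sided binomial tail p-values are corrected with
Benjamini-Hochberg across all callable sites and calls are made at
false-positive (FDR) level ``fpr`` (default 5%); a raw per-site
threshold mode is available for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SITE_KEY

STATUS_METHYLATED = "M"
STATUS_UNMETHYLATED = "U"
STATUS_UNCALLABLE = "NC"


class CalibrationError(ValueError):
    """Conversion-rate calibration is impossible (no spike-in coverage)."""


class UndefinedLevelError(ValueError):
    """A level or density is requested over zero covered cytosines."""


@dataclass(frozen=True)
class ConversionEstimate:
    """Combined bisulfite-conversion error model."""

    nonconversion_rate: float
    tc_error_rate: float = 0.001

    @property
    def p_error(self) -> float:
        """Per-read probability of an apparently methylated base at a
        truly unmethylated position."""
        return 1.0 - (1.0 - self.nonconversion_rate) * (1.0 - self.tc_error_rate)


def estimate_conversion(
    lambda_records: pd.DataFrame, tc_error_rate: float = 0.001
) -> ConversionEstimate:
    """Estimate the non-conversion rate from lambda spike-in counts.

    The spike-in genome is fully unmethylated, so every methylated read
    is a conversion failure: rate = sum(meth) / sum(meth + unmeth).
    """
    meth = int(lambda_records["meth"].sum())
    cov = meth + int(lambda_records["unmeth"].sum())
    if cov == 0:
        raise CalibrationError("lambda spike-in has zero coverage")
    if cov < 100:
        raise CalibrationError(
            f"lambda spike-in coverage {cov} too low for calibration (need >= 100)"
        )
    return ConversionEstimate(nonconversion_rate=meth / cov, tc_error_rate=tc_error_rate)


def call_methylation_status(
    table: pd.DataFrame,
    est: ConversionEstimate,
    fpr: float = 0.05,
    min_coverage: int = 3,
    method: str = "fdr",
) -> pd.DataFrame:
    """Call per-site methylation status for one sample.

    Returns a frame with the site key plus ``status`` (M/U/NC), ``p``
    and ``q`` columns.  ``p`` is the upper binomial tail
    P(X >= meth | n=coverage, p=p_error); ``q`` the Benjamini-Hochberg
    adjusted value over all callable sites.  Sites with coverage below
    ``min_coverage`` are uncallable.  With ``method="raw"`` the raw
    p-value is thresholded instead (q set equal to p).
    """
    if method not in ("fdr", "raw"):
        raise ValueError(f"unknown method {method!r}")
    out = table[SITE_KEY].copy()
    cov = table["meth"].to_numpy() + table["unmeth"].to_numpy()
    meth = table["meth"].to_numpy()
    callable_mask = cov >= min_coverage
    p = np.ones(len(table))
    # upper tail including the observed count
    p[callable_mask] = stats.binom.sf(
        meth[callable_mask] - 1, cov[callable_mask], est.p_error
    )
    q = np.ones(len(table))
    if method == "fdr":
        if callable_mask.any():
            _, q_adj, _, _ = multipletests(p[callable_mask], method="fdr_bh")
            q[callable_mask] = q_adj
    else:
        q = p.copy()
    status = np.where(q <= fpr, STATUS_METHYLATED, STATUS_UNMETHYLATED)
    status = np.where(callable_mask, status, STATUS_UNCALLABLE)
    out["status"] = status
    out["p"] = p
    out["q"] = q
    return out


def methylation_level(
    records: pd.DataFrame, mode: str = "mean"
) -> float:
    """Methylation level of a site or region.

    A single site's level is meth / (meth + unmeth).  A region's level
    is the unweighted mean of per-site levels over covered sites
    (``mode="mean"``, the definition used throughout); ``mode="pooled"``
    returns the read-pooled ratio instead.
    """
    cov = records["meth"] + records["unmeth"]
    covered = cov > 0
    if not covered.any():
        raise UndefinedLevelError("no covered cytosines in region")
    if mode == "pooled":
        return float(records.loc[covered, "meth"].sum() / cov[covered].sum())
    if mode != "mean":
        raise ValueError(f"unknown mode {mode!r}")
    site_levels = records.loc[covered, "meth"] / cov[covered]
    return float(site_levels.mean())


def methylation_density(
    statuses: pd.DataFrame, include_uncallable: bool = False
) -> float:
    """Proportion of methylated cytosines among cytosines of a region.

    The denominator defaults to callable cytosines; with
    ``include_uncallable`` the strict all-cytosines reading is used.
    """
    s = statuses["status"]
    denom = len(s) if include_uncallable else int((s != STATUS_UNCALLABLE).sum())
    if denom == 0:
        raise UndefinedLevelError("no cytosines in region")
    return float((s == STATUS_METHYLATED).sum() / denom)


def msre_qpcr_level(ct_digested: float, ct_undigested: float) -> float:
    """Methylation percentage from MSRE-qPCR Ct values.

    ddCt = Ct(digested) - Ct(undigested); level = 2**(-ddCt) * 100.
    Values above 100% are possible by extrapolation and flagged with a
    warning.
    """
    if not (np.isfinite(ct_digested) and np.isfinite(ct_undigested)):
        raise ValueError("Ct values must be finite")
    ddct = ct_digested - ct_undigested
    level = float(2.0 ** (-ddct) * 100.0)
    if level > 100.0:
        warnings.warn(
            f"MSRE-qPCR level {level:.2f}% exceeds 100% (negative ddCt)",
            stacklevel=2,
        )
    return level


def status_matrix(
    calls: dict, eligible: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Combine per-sample call frames into one status matrix.

    ``calls`` maps sample label (or SampleKey) to the output of
    :func:`call_methylation_status`.  Returns a frame indexed by
    (chrom, pos, strand) with one status column per sample, restricted
    to ``eligible`` sites when given.
    """
    cols = {}
    for key in sorted(calls, key=str):
        df = calls[key]
        s = df.set_index(SITE_KEY)["status"]
        cols[str(key)] = s
    mat = pd.DataFrame(cols)
    if eligible is not None:
        idx = pd.MultiIndex.from_frame(eligible[SITE_KEY])
        mat = mat.reindex(idx)
        mat = mat.fillna(STATUS_UNCALLABLE)
    return mat
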
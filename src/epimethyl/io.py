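"""Reading and writing of per-cytosine count tables and genomic features.

The universal substrate of the pipeline is a per-sample cytosine table in
the Bismark-style seven-column dialect (chrom, 1-based position, strand,
methylated read count, unmethylated read count, sequence context,
trinucleotide).  Cytosines are kept strand-specific throughout; symmetric
CpG collapsing is deliberately not performed.  Coordinates are 1-based
inclusive externally (cytosine reports, GFF3) and converted at the
boundary for BED input.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

GENERATIONS = ("G0", "G10", "G11", "G10R1")
TREATMENTS = ("D", "W")
REPLICATES = (1, 2)

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

#: canonical column order of a cytosine report
REPORT_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "trinucleotide"]

SITE_KEY = ["chrom", "pos", "strand"]


class CytosineReportError(ValueError):
    """Malformed cytosine report input."""


class DesignError(ValueError):
    """The sample design or configuration is inconsistent."""


@dataclass(frozen=True, order=True)
class SampleKey:
    """One individual of the study design.

    Per variety the full design enumerates 16 samples: four generations
    (G0, G10, G11 and the well-watered recovery generation G10R1), two
    treatments (drought D, well-watered W) and two sibling replicates.
    """

    generation: str
    treatment: str
    replicate: int
    variety: str = ""

    def __post_init__(self) -> None:
        if self.generation not in GENERATIONS:
            raise DesignError(f"unknown generation {self.generation!r}")
        if self.treatment not in TREATMENTS:
            raise DesignError(f"unknown treatment {self.treatment!r}")
        if self.replicate not in REPLICATES:
            raise DesignError(f"replicate must be 1 or 2, got {self.replicate!r}")

    @property
    def label(self) -> str:
        core = f"{self.treatment}{self.generation[1:]}_r{self.replicate}"
        return f"{self.variety}_{core}" if self.variety else core

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def design_keys(variety: str = "") -> list[SampleKey]:
    """All 16 sample keys of one variety, in deterministic order."""
    return [
        SampleKey(g, t, r, variety)
        for g, t, r in itertools.product(GENERATIONS, TREATMENTS, REPLICATES)
    ]


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def _validate_report(df: pd.DataFrame, n_comment_lines: int) -> None:
    def lineno(idx: int) -> int:
        return n_comment_lines + int(idx) + 1

    bad = ~df["strand"].isin(STRANDS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CytosineReportError(
            f"line {lineno(i)}: invalid strand {df['strand'].iloc[i]!r}"
        )
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CytosineReportError(
            f"line {lineno(i)}: invalid context {df['context'].iloc[i]!r}"
        )
    for col in ("meth", "unmeth"):
        bad = df[col] < 0
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise CytosineReportError(
                f"line {lineno(i)}: negative count in column {col!r}"
            )
    bad = df["pos"] < 1
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CytosineReportError(f"line {lineno(i)}: position must be >= 1")


def read_cytosine_report(path: str | Path, min_coverage: int = 3) -> pd.DataFrame:
    """Read a seven-column cytosine report into a table.

    Records below ``min_coverage`` are retained but flagged in the
    ``low_coverage`` column so that density denominators over all
    cytosines stay computable.  Raises :class:`CytosineReportError`
    naming the offending line on malformed input.
    """
    path = Path(path)
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=REPORT_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=REPORT_COLUMNS)
    if len(df) == 0:
        df = df.astype({"pos": int, "meth": int, "unmeth": int})
    else:
        for col in ("pos", "meth", "unmeth"):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() | (converted != converted.round())
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise CytosineReportError(
                    f"line {n_comment + i + 1}: non-integer value in column {col!r}"
                )
            df[col] = converted.astype(int)
        _validate_report(df, n_comment)
    df["coverage"] = df["meth"] + df["unmeth"]
    df["low_coverage"] = df["coverage"] < min_coverage
    return df


def write_cytosine_report(
    df: pd.DataFrame, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    """Write the canonical seven columns as TSV with a '#' provenance line."""
    path = Path(path)
    extra = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    with open(path, "w") as fh:
        fh.write(f"# epimethyl {__version__} cytosine report {extra}".rstrip() + "\n")
        df[REPORT_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def site_index(df: pd.DataFrame) -> pd.MultiIndex:
    """MultiIndex of (chrom, pos, strand) for a cytosine table."""
    return pd.MultiIndex.from_frame(df[SITE_KEY])


def build_eligible_set(
    tables: Mapping[SampleKey, pd.DataFrame] | Sequence[pd.DataFrame],
    min_coverage: int = 3,
) -> pd.DataFrame:
    """Sites covered at least ``min_coverage``-fold in *every* sample.

    This is the shared analysis universe: the downstream DMP/SMP callers
    only consider cytosines covered in all supplied individuals.  Returns
    a frame of (chrom, pos, strand) sorted deterministically.
    """
    if isinstance(tables, Mapping):
        frames = [tables[k] for k in sorted(tables)]
    else:
        frames = list(tables)
    if len(frames) == 0:
        raise DesignError("eligible set needs at least one sample table")
    common: pd.MultiIndex | None = None
    for df in frames:
        ok = df.loc[df["coverage"] >= min_coverage, SITE_KEY]
        idx = pd.MultiIndex.from_frame(ok)
        common = idx if common is None else common.intersection(idx)
    assert common is not None
    out = common.to_frame(index=False)
    out.columns = SITE_KEY
    return out.sort_values(SITE_KEY, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# genomic features
# ---------------------------------------------------------------------------

FEATURE_KINDS = ("gene", "CDS", "intron", "five_prime_UTR", "three_prime_UTR", "TE")

#: GFF3 feature types folded into the transposable-element kind
_TE_TYPES = {
    "TE",
    "transposable_element",
    "transposable_element_gene",
    "transposon_fragment",
    "repeat_region",
}

_GFF_KIND = {
    "gene": "gene",
    "CDS": "CDS",
    "intron": "intron",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
}

FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "kind", "id"]


@dataclass
class FeatureSet:
    """Genes, gene parts and transposable elements, 1-based inclusive."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.df) and (self.df["end"] < self.df["start"]).any():
            raise CytosineReportError("feature with end < start")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["kind"] == kind].reset_index(drop=True)

    @staticmethod
    def empty() -> "FeatureSet":
        return FeatureSet(pd.DataFrame(columns=FEATURE_COLUMNS))


def _gff_attr(attrs: str, key: str) -> str | None:
    for field in attrs.strip().split(";"):
        if not field:
            continue
        k, _, v = field.partition("=")
        if k.strip() == key:
            return v.strip()
    return None


def _derive_introns(genes: pd.DataFrame, exons: pd.DataFrame) -> list[dict]:
    """Introns as the gaps between a gene's exons (set arithmetic)."""
    introns: list[dict] = []
    by_parent: dict[str, list[tuple[int, int]]] = {}
    for _, ex in exons.iterrows():
        by_parent.setdefault(ex["parent"], []).append((ex["start"], ex["end"]))
    for _, g in genes.iterrows():
        spans = sorted(by_parent.get(g["id"], []))
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 > e1 + 1:
                introns.append(
                    {
                        "chrom": g["chrom"],
                        "start": e1 + 1,
                        "end": s2 - 1,
                        "strand": g["strand"],
                        "kind": "intron",
                        "id": f"{g['id']}.intron{len(introns) + 1}",
                    }
                )
    return introns


def read_features(path: str | Path, fmt: str | None = None) -> FeatureSet:
    """Read a GFF3 or BED6 file into a :class:`FeatureSet`.

    BED intervals (0-based half-open) are shifted to 1-based inclusive.
    For GFF3 input, introns absent from the file are derived from each
    gene's exons.
    """
    path = Path(path)
    if fmt is None:
        fmt = "BED" if path.suffix.lower() == ".bed" else "GFF3"
    fmt = fmt.upper()
    if fmt not in ("GFF3", "BED"):
        raise DesignError(f"unknown feature format {fmt!r}")

    rows: list[dict] = []
    if fmt == "BED":
        try:
            bed = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
        except pd.errors.EmptyDataError:
            return FeatureSet.empty()
        ncol = bed.shape[1]
        for i, rec in bed.iterrows():
            start0, end0 = int(rec[1]), int(rec[2])
            if end0 < start0:
                raise CytosineReportError(f"line {i + 1}: end < start in BED record")
            name = str(rec[3]) if ncol > 3 else f"feature{i + 1}"
            rows.append(
                {
                    "chrom": str(rec[0]),
                    "start": start0 + 1,
                    "end": end0,
                    "strand": str(rec[5]) if ncol > 5 else "+",
                    "kind": "gene",
                    "id": name,
                }
            )
        return FeatureSet(pd.DataFrame(rows, columns=FEATURE_COLUMNS))

    exon_rows: list[dict] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise CytosineReportError(f"line {i}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise CytosineReportError(f"line {i}: end < start in GFF3 record")
            fid = _gff_attr(attrs, "ID") or _gff_attr(attrs, "Name") or f"feature{i}"
            if ftype == "exon":
                exon_rows.append(
                    {
                        "chrom": chrom,
                        "start": start_i,
                        "end": end_i,
                        "parent": _gff_attr(attrs, "Parent") or "",
                    }
                )
                continue
            kind = "TE" if ftype in _TE_TYPES else _GFF_KIND.get(ftype)
            if kind is None:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": start_i,
                    "end": end_i,
                    "strand": strand,
                    "kind": kind,
                    "id": fid,
                }
            )
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if exon_rows and not df[df["kind"] == "intron"].shape[0]:
        introns = _derive_introns(df[df["kind"] == "gene"], pd.DataFrame(exon_rows))
        if introns:
            df = pd.concat([df, pd.DataFrame(introns)], ignore_index=True)
    return FeatureSet(df)


def write_features_gff3(features: FeatureSet, path: str | Path) -> None:
    kind_to_type = {"TE": "transposable_element"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"# epimethyl {__version__}\n")
        for _, f in features.df.iterrows():
            ftype = kind_to_type.get(f["kind"], f["kind"])
            fh.write(
                "\t".join(
                    [
                        str(f["chrom"]),
                        "epimethyl",
                        ftype,
                        str(int(f["start"])),
                        str(int(f["end"])),
                        ".",
                        f["strand"],
                        ".",
                        f"ID={f['id']}",
                    ]
                )
                + "\n"
            )


def to_zero_based(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open (for window arithmetic/BED)."""
    return start_1based - 1, end_1based


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0
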
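"""Data model and readers/writers for multi-strain methylomes.

The atomic observation is a cytosine with its sequence context (CG, CHG
or CHH), strand, and methylated / total read counts.  A methylome is a
table of such observations for one sample replicate; an accession is a
pool of replicates.  Internal coordinates are 1-based inclusive (the
allc convention); BED output is 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

CONTEXTS = ("CG", "CHG", "CHH")

#: Hierarchical order for feature assignment; first match wins.
FEATURE_HIERARCHY = ("CDS", "intron", "UTR5", "UTR3", "transposon")

#: Collapsing map used when reporting with a single UTR class.
COLLAPSED_FEATURE = {
    "CDS": "CDS",
    "intron": "intron",
    "UTR5": "UTR",
    "UTR3": "UTR",
    "transposon": "transposon",
    "intergenic": "intergenic",
}

_COLUMNS = ["chrom", "pos", "strand", "context", "meth_reads", "total_reads", "qual_ok"]


class MethylomeParseError(ValueError):
    """A file row could not be parsed or violated a record invariant."""


@dataclass(frozen=True)
class CytosineRecord:
    """A single cytosine observation."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    meth_reads: int
    total_reads: int
    qual_ok: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")
        if not (0 <= self.meth_reads <= self.total_reads):
            raise ValueError("need 0 <= meth_reads <= total_reads")


def collapse_context(raw: str) -> str:
    """Collapse a trinucleotide context (e.g. ``CGA``, ``CAG``) to CG/CHG/CHH."""
    raw = raw.upper()
    if raw in CONTEXTS:
        return raw
    if len(raw) < 2 or raw[0] != "C":
        raise MethylomeParseError(f"unknown context token {raw!r}")
    if raw[1] == "G":
        return "CG"
    if len(raw) >= 3 and raw[2] == "G":
        return "CHG"
    if all(b in "ACGT" for b in raw[1:]):
        return "CHH"
    raise MethylomeParseError(f"unknown context token {raw!r}")


class MethylomeTable:
    """Per-cytosine counts of one sample replicate.

    Wraps a DataFrame with columns chrom, pos, strand, context,
    meth_reads, total_reads, qual_ok, kept sorted by (chrom, pos,
    strand) with unique keys.
    """

    def __init__(self, df: pd.DataFrame, sample_id: str = "", replicate_id: str = ""):
        df = df.loc[:, _COLUMNS].copy()
        self._validate(df)
        df = df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) keys")
        self.df = df
        self.sample_id = sample_id
        self.replicate_id = replicate_id

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        bad = df.index[~df["context"].isin(CONTEXTS)]
        if len(bad):
            raise MethylomeParseError(f"unknown context in row {bad[0] + 1}")
        bad = df.index[df["meth_reads"] > df["total_reads"]]
        if len(bad):
            raise MethylomeParseError(
                f"meth_reads > total_reads in row {bad[0] + 1}"
            )
        bad = df.index[(df["meth_reads"] < 0) | (df["pos"] < 1)]
        if len(bad):
            raise MethylomeParseError(f"invalid value in row {bad[0] + 1}")
        bad = df.index[~df["strand"].isin(["+", "-"])]
        if len(bad):
            raise MethylomeParseError(f"invalid strand in row {bad[0] + 1}")

    def __len__(self) -> int:
        return len(self.df)

    def records(self):
        for row in self.df.itertuples(index=False):
            yield CytosineRecord(
                row.chrom, int(row.pos), row.strand, row.context,
                int(row.meth_reads), int(row.total_reads), bool(row.qual_ok),
            )

    @classmethod
    def from_records(cls, records, sample_id: str = "", replicate_id: str = ""):
        df = pd.DataFrame([r.__dict__ for r in records], columns=_COLUMNS)
        return cls(df, sample_id, replicate_id)


@dataclass
class SamplePool:
    """An accession: one or more replicate methylomes of pooled siblings."""

    accession_id: str
    replicates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("a pool needs at least one replicate")

    def accumulated(self) -> pd.DataFrame:
        """Sum read counts over replicates on the shared position universe.

        A position's quality flag holds only if every replicate's does.
        """
        dfs = [r.df for r in self.replicates]
        if len(dfs) == 1:
            return dfs[0].copy()
        keys = ["chrom", "pos", "strand", "context"]
        merged = dfs[0]
        for i, other in enumerate(dfs[1:], start=1):
            merged = merged.merge(
                other, on=keys, how="inner", suffixes=("", f"_{i}")
            )
        out = merged[keys].copy()
        meth_cols = [c for c in merged.columns if c.startswith("meth_reads")]
        tot_cols = [c for c in merged.columns if c.startswith("total_reads")]
        qual_cols = [c for c in merged.columns if c.startswith("qual_ok")]
        out["meth_reads"] = merged[meth_cols].sum(axis=1)
        out["total_reads"] = merged[tot_cols].sum(axis=1)
        out["qual_ok"] = merged[qual_cols].all(axis=1)
        return out[_COLUMNS].sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers

def read_methylome(path, format: str = "allc-tsv", sample_id: str = "",
                   replicate_id: str = "") -> MethylomeTable:
    """Read a methylome table from an allc-style TSV or a bedMethyl file."""
    if format == "allc-tsv":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "pos", "strand", "context", "meth_reads", "total_reads", "qual"],
            dtype={"chrom": str},
        )
        try:
            df["context"] = df["context"].map(collapse_context)
        except MethylomeParseError as e:
            raise MethylomeParseError(str(e)) from None
        df["qual_ok"] = df["qual"].astype(int).astype(bool)
    elif format == "bedmethyl":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        if df.shape[1] < 11:
            raise MethylomeParseError("bedMethyl needs at least 11 columns")
        cov = df[9].astype(int)
        pct = df[10].astype(float)
        out = pd.DataFrame(
            {
                "chrom": df[0],
                "pos": df[1].astype(int) + 1,
                "strand": df[5],
                "context": df[3].map(collapse_context),
                "meth_reads": np.rint(cov * pct / 100.0).astype(int),
                "total_reads": cov,
                "qual_ok": True,
            }
        )
        df = out
    else:
        raise ValueError(f"unknown format {format!r}")
    return MethylomeTable(df[_COLUMNS], sample_id=sample_id, replicate_id=replicate_id)


def write_methylome(table: MethylomeTable, path, format: str = "allc-tsv") -> None:
    df = table.df
    if format == "allc-tsv":
        out = df.copy()
        out["qual"] = out.pop("qual_ok").astype(int)
        out.to_csv(path, sep="\t", header=False, index=False)
    elif format == "bedmethyl":
        pct = np.where(df["total_reads"] > 0,
                       100.0 * df["meth_reads"] / df["total_reads"].replace(0, 1), 0.0)
        out = pd.DataFrame(
            {
                0: df["chrom"],
                1: df["pos"] - 1,
                2: df["pos"],
                3: df["context"],
                4: np.minimum(df["total_reads"], 1000),
                5: df["strand"],
                6: df["pos"] - 1,
                7: df["pos"],
                8: "0,0,0",
                9: df["total_reads"],
                10: pct,
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_bed6(regions: pd.DataFrame, path, score_col: str = "score") -> None:
    """Write regions (1-based inclusive chrom/start/end) as BED6."""
    out = pd.DataFrame(
        {
            0: regions["chrom"],
            1: regions["start"] - 1,
            2: regions["end"],
            3: [f"region_{i}" for i in range(len(regions))],
            4: regions[score_col] if score_col in regions else 0,
            5: ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# coverage / quality filtering

def filter_covered_sites(pools, min_cov: int = 3, min_frac_strains: float = 0.5):
    """Positions adequately covered in enough strains.

    A position is retained when at least ``ceil(min_frac_strains *
    n_strains)`` strains have replicate-accumulated coverage of at least
    ``min_cov`` reads with good base quality.  Returns a set of
    (chrom, pos, strand) keys.
    """
    if not pools:
        raise ValueError("need at least one pool")
    if min_cov < 1 or not (0 < min_frac_strains <= 1):
        raise ValueError("bad thresholds")
    need = math.ceil(min_frac_strains * len(pools))
    counts: dict = {}
    for pool in pools:
        acc = pool.accumulated()
        ok = acc[(acc["total_reads"] >= min_cov) & acc["qual_ok"]]
        for key in zip(ok["chrom"], ok["pos"], ok["strand"]):
            counts[key] = counts.get(key, 0) + 1
    return {k for k, c in counts.items() if c >= need}


# ---------------------------------------------------------------------------
# false-methylation rate (unconverted control, e.g. chloroplast)

def estimate_false_methylation_rate(table: MethylomeTable) -> float:
    """Pooled rate of apparent methylation in an unmethylated control.

    Reads mapped to the (unmethylated) chloroplast estimate the combined
    bisulfite non-conversion and sequencing error rate used as the null
    for methylated-site calling.
    """
    tot = int(table.df["total_reads"].sum())
    if tot == 0:
        raise ValueError("control table has zero total reads")
    return float(table.df["meth_reads"].sum()) / tot


# ---------------------------------------------------------------------------
# genomic-feature annotation

@dataclass(frozen=True)
class FeatureAnnotation:
    feature_class: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_HIERARCHY:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.start > self.end:
            raise ValueError("start must be <= end")


_GFF_TYPE_MAP = {
    "CDS": "CDS",
    "intron": "intron",
    "five_prime_UTR": "UTR5",
    "three_prime_UTR": "UTR3",
    "transposable_element": "transposon",
    "transposon": "transposon",
    "transposable_element_gene": "transposon",
}


def read_gff3_features(path) -> list:
    """Read feature annotations from GFF3, keeping only hierarchy classes."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["seqid", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
        dtype={"seqid": str},
    )
    feats = []
    for row in df.itertuples(index=False):
        cls = _GFF_TYPE_MAP.get(row.type)
        if cls is not None:
            feats.append(FeatureAnnotation(cls, row.seqid, int(row.start), int(row.end)))
    return feats


class Annotator:
    """Hierarchical assignment of intervals to genomic features.

    The first overlapping class in the order CDS > intron > 5'UTR >
    3'UTR > transposon wins; an interval overlapping nothing is
    intergenic.
    """

    def __init__(self, features):
        self._trees: dict = {cls: {} for cls in FEATURE_HIERARCHY}
        for f in features:
            tree = self._trees[f.feature_class].setdefault(f.chrom, IntervalTree())
            tree.addi(f.start, f.end + 1)  # half-open internally

    def annotate(self, chrom: str, start: int, end: int) -> str:
        for cls in FEATURE_HIERARCHY:
            tree = self._trees[cls].get(chrom)
            if tree is not None and tree.overlap(start, end + 1):
                return cls
        return "intergenic"


def annotate(interval, features) -> str:
    """One-shot hierarchical annotation of a (chrom, start, end) interval."""
    chrom, start, end = interval
    return Annotator(features).annotate(chrom, start, end)
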
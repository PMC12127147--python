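"""Readers and writers for the tabular and alignment formats the pipeline touches.

Formats handled here:

* beta-value matrices — TSV, probes in rows, samples in columns, values are
  methylation fractions in ``[0, 1]`` with a configurable missing-value token;
* region sets — BED3/BED4, 0-based half-open coordinates;
* bisulfite alignments — SAM text in the Bismark dialect, i.e. each aligned
  read carries an ``XM`` methylation-call string (``Z``/``z`` = methylated /
  unmethylated CpG; CHG/CHH/unknown calls are ignored);
* sample metadata tables — TSV with one row per sample (purity estimates,
  survival endpoints, free-form labels);
* marker/probe panels — one identifier per line.

Coordinate conventions: BED is 0-based half-open; SAM positions are converted
from 1-based; a CpG call projected to reference position ``p`` belongs to a
region iff ``start <= p < end``.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("methet")

NA_TOKEN = "NA"
FLOAT_FORMAT = "%.6g"

# CIGAR operation codes accepted when projecting XM calls to the reference:
# M, I, D, S, =, X.  N/H/P are rejected (spliced or hard-clipped bisulfite
# alignments are outside this dialect).
_ALLOWED_CIGAR_OPS = {0, 1, 2, 4, 7, 8}


class FormatError(ValueError):
    """A file violated the format contract (bad value, duplicate id, ...)."""


# ---------------------------------------------------------------------------
# Beta matrices
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions.

    ``data`` is a float DataFrame indexed by probe id with sample ids as
    columns; missing values are NaN.  ``probe_meta`` optionally carries
    per-probe annotations (CGI membership, panel tags, planted truth, ...)
    aligned on the probe index.
    """

    data: pd.DataFrame
    probe_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta value {vals[i, j]!r} outside [0, 1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def read_beta_matrix(path: str | Path, na_token: str = NA_TOKEN) -> BetaMatrix:
    """Read a TSV beta matrix (header row = sample ids, first column = probe ids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = next(s for s in header if header.count(s) > 1)
        raise FormatError(f"duplicate sample id {dup!r}")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        na_values=[na_token], keep_default_na=False,
    )
    data = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        unparsed = numeric.isna() & raw[col].notna()
        if unparsed.any():
            probe = raw.index[unparsed.to_numpy()][0]
            raise FormatError(
                f"unparseable beta value {raw.loc[probe, col]!r} "
                f"at probe {probe!r}, sample {col!r} in {path}"
            )
        data[col] = numeric
    data.index.name = raw.index.name or "probe_id"
    return BetaMatrix(data)


def write_beta_matrix(bm: BetaMatrix, path: str | Path, na_token: str = NA_TOKEN) -> None:
    df = bm.data.copy()
    df.index.name = df.index.name or "probe_id"
    df.to_csv(path, sep="\t", na_rep=na_token, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Region sets (BED)
# ---------------------------------------------------------------------------


class Region(NamedTuple):
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    region_id: str


@dataclass
class RegionSet:
    """Sorted set of half-open genomic intervals with unique ids."""

    regions: list[Region]
    _by_chrom: dict[str, tuple[list[int], list[Region]]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        for r in self.regions:
            if r.start >= r.end:
                raise FormatError(f"region {r.region_id!r}: start {r.start} >= end {r.end}")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate region id {dup!r}")
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end))
        for r in self.regions:
            starts, regs = self._by_chrom.setdefault(r.chrom, ([], []))
            starts.append(r.start)
            regs.append(r)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Region]:
        """Regions intersecting [start, end) on chrom."""
        if chrom not in self._by_chrom:
            return []
        starts, regs = self._by_chrom[chrom]
        hi = bisect_left(starts, end)
        # regions are only sorted by start, so scan the prefix for end > start
        return [r for r in regs[:hi] if r.end > start]


def read_bed_regions(path: str | Path) -> RegionSet:
    """Read BED3/BED4; the 4th column (when present) is the region id."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            rid = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            regions.append(Region(chrom, start, end, rid))
    return RegionSet(regions)


def write_bed_regions(rs: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


# ---------------------------------------------------------------------------
# Bismark-dialect SAM
# ---------------------------------------------------------------------------


class ReadMethRecord(NamedTuple):
    """Per-read CpG methylation summary within one region."""

    read_id: str
    region_id: str
    n_cpg: int
    n_meth: int
    m: float  # n_meth / n_cpg


def read_bismark_sam(
    path: str | Path,
    regions: RegionSet,
    min_cpg: int = 4,
) -> list[ReadMethRecord]:
    """Project Bismark XM CpG calls to the reference and summarise per region.

    Only ``Z``/``z`` symbols contribute; calls landing inside soft clips or
    insertions have no reference position and are never counted.  Reads with
    fewer than ``min_cpg`` in-region CpG calls are dropped; unmapped,
    secondary and supplementary alignments are skipped; reads without an XM
    tag are skipped and counted in a logged total.
    """
    records: list[ReadMethRecord] = []
    n_missing_xm = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            for op, _ in aln.cigartuples or []:
                if op not in _ALLOWED_CIGAR_OPS:
                    raise FormatError(
                        f"unsupported CIGAR operation code {op} in read {aln.query_name!r}"
                    )
            if not aln.has_tag("XM"):
                n_missing_xm += 1
                continue
            xm = str(aln.get_tag("XM"))
            hits = regions.overlapping(
                aln.reference_name, aln.reference_start, aln.reference_end
            )
            if not hits:
                continue
            # (query_pos, ref_pos) for aligned (M/=/X) bases only
            pairs = aln.get_aligned_pairs(matches_only=True)
            calls = [
                (rpos, xm[qpos])
                for qpos, rpos in pairs
                if qpos is not None and qpos < len(xm) and xm[qpos] in "Zz"
            ]
            for region in hits:
                n_cpg = n_meth = 0
                for rpos, symbol in calls:
                    if region.start <= rpos < region.end:
                        n_cpg += 1
                        n_meth += symbol == "Z"
                if n_cpg >= min_cpg:
                    records.append(
                        ReadMethRecord(
                            aln.query_name, region.region_id, n_cpg, n_meth, n_meth / n_cpg
                        )
                    )
    if n_missing_xm:
        logger.warning("skipped %d reads without an XM tag", n_missing_xm)
    return records


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

#: columns given a numeric type when present
_SAMPLE_NUMERIC = ("purity", "time", "tumor_fraction")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample table indexed by ``sample_id``.

    Recognised columns are typed (purity in [0,1] or missing, time >= 0,
    event in {0, 1}); unrecognised columns are preserved as labels.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id {dup!r}")
    df = df.set_index("sample_id")
    for col in df.columns:
        if col in _SAMPLE_NUMERIC or col.startswith("purity"):
            df[col] = pd.to_numeric(df[col], errors="raise")
    for col in df.columns:
        if col.startswith("purity"):
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                sid = vals[(vals < 0) | (vals > 1)].index[0]
                raise FormatError(f"purity outside [0, 1] for sample {sid!r}")
    if "time" in df.columns and (df["time"].dropna() < 0).any():
        raise FormatError("negative survival time")
    if "event" in df.columns:
        ev = pd.to_numeric(df["event"], errors="raise")
        ok = ev.isna() | ev.isin([0, 1])
        if not ok.all():
            sid = df.index[~ok][0]
            raise FormatError(f"event value outside {{0, 1}} for sample {sid!r}")
        df["event"] = ev
    return df


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------


def read_panel(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line panel file."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise FormatError(f"duplicate panel identifier {dup!r}")
    return ids


def write_panel(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")
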
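"""Input/output for haploid alignments, metadata and coverage-based site filtering.

Sequence data are aligned haploid sequences (mtDNA or the male-specific portion
of the Y chromosome, MSY) with an explicit 1-based reference coordinate for
every column.  mtDNA coordinates follow the rCRS convention (16,569 bp);
MSY variant tables use genome (GRCh38) coordinates.

Only the four nucleotides, ``N`` (missing) and ``-`` (gap) are legal states:
the markers are haploid, so IUPAC ambiguity codes that encode heterozygosity
are rejected at read time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DegenerateInputError, FormatError, MetadataError

#: rCRS mitochondrial reference length in bp.
RCRS_LENGTH = 16_569
#: 1-based inclusive bounds of the mitochondrial coding region.
MT_CODING_REGION = (577, 16_023)

VALID_STATES = frozenset("ACGTN-")
MISSING_STATES = frozenset("N-")


@dataclass
class HaploidAlignment:
    """Aligned haploid sequences for a single marker.

    Attributes
    ----------
    sample_ids:
        Ordered, unique sample identifiers (one per row of ``matrix``).
    positions:
        Strictly increasing 1-based reference coordinates, one per column.
    matrix:
        ``(n_samples, n_sites)`` array of single characters in ``ACGTN-``.
    marker:
        ``"mtDNA"`` or ``"MSY"``.
    """

    sample_ids: list[str]
    positions: np.ndarray
    matrix: np.ndarray
    marker: str = "mtDNA"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise FormatError("alignment matrix must be 2-dimensional")
        if self.matrix.shape != (len(self.sample_ids), len(self.positions)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.positions)} positions"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise MetadataError(f"duplicate sample ids: {dupes}")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise FormatError("positions must be strictly increasing")
        bad = set(np.unique(self.matrix)) - VALID_STATES
        if bad:
            raise FormatError(
                f"illegal haploid states {sorted(bad)}; only A/C/G/T/N/- allowed"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sequence(self, sample_id: str) -> str:
        return "".join(self.matrix[self.sample_ids.index(sample_id)])

    def select_sites(self, keep: np.ndarray) -> "HaploidAlignment":
        """Return a new alignment restricted to the column index array ``keep``."""
        keep = np.asarray(keep)
        return HaploidAlignment(
            sample_ids=list(self.sample_ids),
            positions=self.positions[keep],
            matrix=self.matrix[:, keep],
            marker=self.marker,
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "HaploidAlignment":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return HaploidAlignment(
            sample_ids=list(sample_ids),
            positions=self.positions.copy(),
            matrix=self.matrix[idx],
            marker=self.marker,
        )


def read_alignment(path: str | Path | io.TextIOBase, marker: str = "mtDNA",
                   positions: Iterable[int] | None = None) -> HaploidAlignment:
    """Read an aligned FASTA file into a :class:`HaploidAlignment`.

    All records must have equal length; characters other than ``ACGTN-``
    (after upper-casing) are rejected — in particular IUPAC ambiguity codes,
    which would break the haploid contract.  ``positions`` defaults to
    ``1..L``.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"unequal record lengths {sorted(lengths)} in {path}")
    matrix = np.array([list(str(r.seq).upper()) for r in records], dtype="U1")
    if positions is None:
        positions = np.arange(1, matrix.shape[1] + 1)
    return HaploidAlignment(ids, np.asarray(list(positions)), matrix, marker)


def write_alignment(aln: HaploidAlignment, path: str | Path | io.TextIOBase) -> None:
    """Write an alignment as single-line-wrapped FASTA (60 columns)."""
    records = [
        SeqRecord(Seq("".join(row)), id=sid, description="")
        for sid, row in zip(aln.sample_ids, aln.matrix)
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# sample metadata


@dataclass
class SampleTable:
    """Per-sample metadata: marker, population labels, optional individual link.

    ``group`` is the combined country-by-migrant-route label used for the
    finest population subdivision (e.g. ``"Romania:Vlax"``).
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "marker", "country", "route")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise MetadataError(f"metadata missing columns: {missing}")
        if "individual_id" not in self.df.columns:
            self.df = self.df.assign(individual_id=pd.NA)
        dup = self.df.duplicated(subset=["sample_id", "marker"])
        if dup.any():
            raise MetadataError(
                f"duplicate sample ids within a marker: "
                f"{sorted(self.df.loc[dup, 'sample_id'].unique())}"
            )
        self.df = self.df.assign(
            group=self.df["country"].astype(str) + ":" + self.df["route"].astype(str)
        )

    def for_marker(self, marker: str) -> "SampleTable":
        return SampleTable(self.df[self.df["marker"] == marker].drop(columns="group"))

    def labels(self, sample_ids: Sequence[str], level: str) -> np.ndarray:
        """Population labels (``country``, ``route`` or ``group``) aligned to
        ``sample_ids`` order."""
        if level not in ("country", "route", "group"):
            raise MetadataError(f"unknown grouping level {level!r}")
        lookup = self.df.set_index("sample_id")[level]
        missing = [s for s in sample_ids if s not in lookup.index]
        if missing:
            raise MetadataError(f"samples without metadata: {missing}")
        return lookup.loc[list(sample_ids)].to_numpy()

    def check_covers(self, aln: HaploidAlignment) -> None:
        have = set(self.df.loc[self.df["marker"] == aln.marker, "sample_id"])
        missing = [s for s in aln.sample_ids if s not in have]
        if missing:
            raise MetadataError(f"alignment samples without metadata: {missing}")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.df.drop(columns="group").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coverage filter


def read_coverage(path: str | Path) -> pd.DataFrame:
    """Read a two-column TSV (position, summed_depth)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"position", "summed_depth"} <= set(df.columns):
        raise FormatError("coverage table needs columns: position, summed_depth")
    if (df["summed_depth"] < 0).any():
        raise FormatError("negative coverage depth")
    return df


def coverage_filter(coverage: pd.DataFrame | dict[int, float]
                    ) -> tuple[np.ndarray, tuple[float, float]]:
    """Retain positions whose total (across-individuals) depth lies between
    half and double of the mean depth.

    Returns the sorted array of retained positions and the real-valued bounds
    ``(mean/2, 2*mean)``; round only for display.
    """
    if isinstance(coverage, dict):
        coverage = pd.DataFrame(
            {"position": list(coverage), "summed_depth": list(coverage.values())}
        )
    if coverage.empty:
        raise DegenerateInputError("empty coverage vector")
    depth = coverage["summed_depth"].to_numpy(dtype=float)
    mean = depth.mean()
    if mean == 0:
        raise DegenerateInputError("all-zero coverage")
    lo, hi = mean / 2.0, mean * 2.0
    keep = (depth >= lo) & (depth <= hi)
    retained = np.sort(coverage.loc[keep, "position"].to_numpy(dtype=np.int64))
    return retained, (lo, hi)


# ---------------------------------------------------------------------------
# site masks


@dataclass
class SiteMask:
    """Positions/intervals to exclude plus an optional inclusive region bound.

    ``positions`` are single excluded sites (mutation hotspots), ``intervals``
    inclusive 1-based excluded ranges (e.g. the 941-942 insertion region) and
    ``region`` an inclusive 1-based window outside which everything is
    dropped (e.g. the mitochondrial coding region 577-16,023).
    """

    positions: frozenset[int] = field(default_factory=frozenset)
    intervals: tuple[tuple[int, int], ...] = ()
    region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.positions = frozenset(int(p) for p in self.positions)
        self.intervals = tuple((int(a), int(b)) for a, b in self.intervals)
        for a, b in self.intervals:
            if a > b:
                raise FormatError(f"interval {a}-{b} reversed")

    def excluded(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask over ``positions`` that the mask removes."""
        positions = np.asarray(positions)
        out = np.isin(positions, list(self.positions))
        for a, b in self.intervals:
            out |= (positions >= a) & (positions <= b)
        if self.region is not None:
            lo, hi = self.region
            out |= (positions < lo) | (positions > hi)
        return out

    def union(self, other: "SiteMask") -> "SiteMask":
        if self.region is not None and other.region is not None:
            region = (max(self.region[0], other.region[0]),
                      min(self.region[1], other.region[1]))
        else:
            region = self.region or other.region
        return SiteMask(self.positions | other.positions,
                        self.intervals + other.intervals, region)


def default_hotspot_mask() -> SiteMask:
    """Packaged mtDNA mask: common hypervariable/hotspot sites plus the
    941-942 insertion region.

    The list is configurable; this default covers the classic length-
    heteroplasmy and hypermutable control-region sites.
    """
    path = Path(__file__).parent / "data" / "mtdna_hotspots.tsv"
    singles: set[int] = set()
    intervals: list[tuple[int, int]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "-" in line:
            a, b = line.split("-")
            intervals.append((int(a), int(b)))
        else:
            singles.add(int(line))
    return SiteMask(frozenset(singles), tuple(intervals))


def coding_region_mask() -> SiteMask:
    """Mask restricting mtDNA to the coding region (577-16,023 inclusive)."""
    return SiteMask(region=MT_CODING_REGION)


def apply_masks(aln: HaploidAlignment, mask: SiteMask) -> HaploidAlignment:
    """Drop masked columns; the coordinate map of the survivors is preserved."""
    drop = mask.excluded(aln.positions)
    if drop.all():
        raise DegenerateInputError("mask removes every site")
    return aln.select_sites(np.where(~drop)[0])


# ---------------------------------------------------------------------------
# optional VCF ingestion (haploid GT)


def read_vcf(path: str | Path, marker: str = "MSY") -> HaploidAlignment:
    """Read haploid genotypes from a VCF into an alignment of variant sites.

    Multi-allelic records are handled by indexing into REF+ALT; missing
    genotypes become ``N``.  Only single-base alleles are kept (indels are
    outside the classification and distance contracts).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    positions: list[int] = []
    columns: list[list[str]] = []
    for rec in vcf:
        alleles = [rec.REF] + list(rec.ALT)
        if any(len(a) != 1 for a in alleles if a is not None):
            continue
        col = []
        for g in rec.genotypes:
            idx = g[0]
            col.append("N" if idx is None or idx < 0 else alleles[idx].upper())
        positions.append(rec.POS)
        columns.append(col)
    if not positions:
        raise DegenerateInputError(f"no usable SNP records in {path}")
    order = np.argsort(positions)
    matrix = np.array(columns, dtype="U1").T[:, order]
    return HaploidAlignment(sample_ids, np.asarray(positions)[order], matrix, marker)
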
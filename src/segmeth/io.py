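"""Core data containers and file I/O for methylome analysis.

Containers
----------
``CpGRecord``
    A single CpG dyad call: position of the C on the plus strand,
    methylated / total read counts, and the derived methylation level.
``Methylome``
    Per-chromosome sorted arrays of CpG calls for one WGBS sample (or a
    pool of replicates). This is the substrate of every downstream stage.
``GenomicRegion``
    A classed interval (PMR/UMR/LMR/gUMR/FMR/CGI/raw) with CpG count and
    mean methylation.
``GeneModel``
    Strand-aware TSS/TES extents for one gene.

File formats
------------
CpG call tables are bedGraph-like TSV: either the 5-column counts dialect
``chrom start end meth unmeth`` or the 6-column MethylDackel bedGraph
``chrom start end percent meth unmeth`` (counts take precedence). Regions
travel as BED3+ with optional class / n_cpg / mean_meth columns; gene
models as 5-column TSV. All readers are gzip-transparent.

Coordinates are 0-based half-open throughout; a CpG position is the
0-based position of the C on the plus strand.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

REGION_CLASSES = {"PMR", "UMR", "LMR", "gUMR", "FMR", "CGI", "raw"}


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass(frozen=True)
class CpGRecord:
    chrom: str
    pos: int
    meth_count: int
    total_count: int

    def __post_init__(self):
        if self.total_count <= 0:
            raise ValueError(f"total_count must be positive, got {self.total_count}")
        if not 0 <= self.meth_count <= self.total_count:
            raise ValueError(
                f"meth_count {self.meth_count} outside [0, {self.total_count}]"
            )

    @property
    def level(self) -> float:
        return self.meth_count / self.total_count


@dataclass
class ChromCalls:
    """CpG calls on one chromosome as parallel sorted arrays."""

    pos: np.ndarray
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if not (len(self.pos) == len(self.meth) == len(self.total)):
            raise ValueError("pos/meth/total length mismatch")
        if len(self.pos) > 1 and not np.all(np.diff(self.pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.total <= 0):
            raise ValueError("zero-coverage CpGs are dropped at ingestion")
        if np.any(self.meth < 0) or np.any(self.meth > self.total):
            raise ValueError("meth counts outside [0, total]")

    @property
    def level(self) -> np.ndarray:
        return self.meth / self.total

    def __len__(self) -> int:
        return len(self.pos)


@dataclass
class Methylome:
    sample_id: str
    chrom_sizes: dict[str, int]
    data: dict[str, ChromCalls] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, calls in self.data.items():
            if chrom not in self.chrom_sizes:
                raise ValueError(f"chromosome {chrom!r} absent from chrom_sizes")
            if len(calls) and calls.pos[-1] >= self.chrom_sizes[chrom]:
                raise ValueError(
                    f"CpG at {chrom}:{calls.pos[-1]} beyond chromosome "
                    f"length {self.chrom_sizes[chrom]}"
                )

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    @property
    def n_cpgs(self) -> int:
        return sum(len(c) for c in self.data.values())

    def iter_records(self) -> Iterator[CpGRecord]:
        for chrom in self.chroms:
            c = self.data[chrom]
            for p, m, t in zip(c.pos, c.meth, c.total):
                yield CpGRecord(chrom, int(p), int(m), int(t))

    @classmethod
    def from_records(
        cls, sample_id: str, records: Iterable[CpGRecord], chrom_sizes: Mapping[str, int]
    ) -> "Methylome":
        by_chrom: dict[str, list[CpGRecord]] = {}
        for r in records:
            by_chrom.setdefault(r.chrom, []).append(r)
        data = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: r.pos)
            pos = np.array([r.pos for r in recs], dtype=np.int64)
            if len(pos) > 1 and np.any(np.diff(pos) == 0):
                dup = pos[np.where(np.diff(pos) == 0)[0][0]]
                raise ValueError(f"duplicate CpG at {chrom}:{dup}")
            data[chrom] = ChromCalls(
                pos=pos,
                meth=np.array([r.meth_count for r in recs], dtype=np.int64),
                total=np.array([r.total_count for r in recs], dtype=np.int64),
            )
        return cls(sample_id=sample_id, chrom_sizes=dict(chrom_sizes), data=data)


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start: int
    end: int
    region_class: str = "raw"
    n_cpg: int = 0
    mean_meth: float | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if self.n_cpg < 0:
            raise ValueError("n_cpg must be non-negative")
        if self.mean_meth is not None and not 0.0 <= self.mean_meth <= 1.0:
            raise ValueError(f"mean_meth {self.mean_meth} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError("tss and tes must differ")
        if self.strand == "-" and self.tss <= self.tes:
            raise ValueError("minus-strand gene must have tss > tes")
        if self.strand == "+" and self.tss >= self.tes:
            raise ValueError("plus-strand gene must have tss < tes")

    @property
    def extent(self) -> tuple[int, int]:
        """Genic extent [min, max) of TSS/TES, strand-independent."""
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    @property
    def length(self) -> int:
        lo, hi = self.extent
        return hi - lo


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_cpg_table(path, sample_id: str, chrom_sizes: Mapping[str, int]) -> Methylome:
    """Read a per-CpG methylation call table into a Methylome.

    Dialects (auto-detected by column count):

    * 5 columns ``chrom start end meth unmeth`` — counts dialect;
    * 6 columns ``chrom start end percent meth unmeth`` — MethylDackel
      bedGraph; the counts columns are authoritative, the percent column
      is ignored.

    Zero-coverage rows are dropped with a single summary warning;
    methylation level is always recomputed from counts. Rows may arrive
    unsorted; the output is sorted by (chrom, pos).
    """
    records: list[CpGRecord] = []
    n_zero = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) not in (5, 6):
                raise ParseError(
                    f"{path}:{lineno}: expected 5 (counts) or 6 (MethylDackel) "
                    f"columns, got {len(parts)}"
                )
            chrom = parts[0]
            if chrom not in chrom_sizes:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start = int(parts[1])
                int(parts[2])  # end; CpG identity is carried by start
                if len(parts) == 5:
                    meth, unmeth = int(parts[3]), int(parts[4])
                else:
                    meth, unmeth = int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            total = meth + unmeth
            if total == 0:
                n_zero += 1
                continue
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative read count")
            records.append(CpGRecord(chrom, start, meth, total))
    if n_zero:
        warnings.warn(f"{path}: dropped {n_zero} zero-coverage CpGs", stacklevel=2)
    return Methylome.from_records(sample_id, records, chrom_sizes)


def write_cpg_table(methylome: Methylome, path) -> None:
    """Write the counts dialect (chrom start end meth unmeth)."""
    with open(path, "wt") as fh:
        for chrom in methylome.chroms:
            c = methylome.data[chrom]
            for p, m, t in zip(c.pos, c.meth, c.total):
                fh.write(f"{chrom}\t{p}\t{p + 2}\t{m}\t{t - m}\n")


def merge_strand_calls(
    plus: Sequence[CpGRecord], minus: Sequence[CpGRecord]
) -> list[CpGRecord]:
    """Merge plus/minus strand calls of CpG dyads into one record per dyad.

    The C on the minus strand of a CpG dyad sits one base downstream of the
    plus-strand C, so a minus record at position p pairs with the plus
    record at p - 1. Counts are summed and the level recomputed. Unpaired
    minus records are kept as their own dyad at p - 1 with a warning.
    """
    plus_by_key = {(r.chrom, r.pos): r for r in plus}
    merged: dict[tuple[str, int], tuple[int, int]] = {
        k: (r.meth_count, r.total_count) for k, r in plus_by_key.items()
    }
    n_unpaired = 0
    for r in minus:
        key = (r.chrom, r.pos - 1)
        if key in merged:
            m, t = merged[key]
            merged[key] = (m + r.meth_count, t + r.total_count)
        else:
            n_unpaired += 1
            merged[key] = (r.meth_count, r.total_count)
    if n_unpaired:
        warnings.warn(
            f"{n_unpaired} unpaired minus-strand calls kept as single-strand dyads",
            stacklevel=2,
        )
    out = [
        CpGRecord(chrom, pos, m, t) for (chrom, pos), (m, t) in merged.items()
    ]
    out.sort(key=lambda r: (r.chrom, r.pos))
    return out


def read_regions_bed(path) -> list[GenomicRegion]:
    """Read BED3+ into GenomicRegions.

    Optional columns 4-6 are class, n_cpg, mean_meth ('.' for undefined
    mean). Unknown class strings raise; BED with start >= end or
    non-integer coordinates raise ParseError.
    """
    regions: list[GenomicRegion] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            cls = parts[3] if len(parts) > 3 and parts[3] != "." else "raw"
            n_cpg = int(parts[4]) if len(parts) > 4 and parts[4] != "." else 0
            mean = (
                float(parts[5]) if len(parts) > 5 and parts[5] != "." else None
            )
            try:
                regions.append(
                    GenomicRegion(parts[0], start, end, cls, n_cpg, mean)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return regions


def write_regions_bed(regions: Iterable[GenomicRegion], path) -> None:
    """Write regions as BED6-like TSV; read_regions_bed round-trips it."""
    with open(path, "wt") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
            mean = "." if r.mean_meth is None else f"{r.mean_meth:.6f}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_class}\t{r.n_cpg}\t{mean}\n"
            )


def read_gene_models(path) -> list[GeneModel]:
    """Read a 5-column TSV: gene_id, chrom, strand, tss, tes."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            gene_id = parts[0]
            if gene_id in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                genes.append(
                    GeneModel(gene_id, parts[1], parts[2], int(parts[3]), int(parts[4]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "wt") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tes}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chrom, length."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes[parts[0]] = int(parts[1])
    return sizes
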
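"""Genomic data model and annotation / read / track I/O.

Every coordinate inside the package is 0-based, half-open ``[start, end)``.
GFF3 (1-based, closed) is converted at the file boundary; BED is taken as-is.
Strand ``.`` is permitted for reads (the ChIP libraries are unstranded) but
forbidden for genes, because TSS windows require an orientation.

Sample metadata (antibody, condition, sequencing depth) travels either in
``#key=value`` comment lines at the top of a BED6 read file or in a YAML
sample sheet; the sheet wins on conflict.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

ANTIBODIES = ("Smad2/3", "H3K4me3", "H3K27me3", "input")
CONDITIONS = ("TGFb_plus", "TGFb_minus")


class GenomeIOError(ValueError):
    """Base class for annotation / read I-O failures."""


class ParseError(GenomeIOError):
    pass


class ValidationError(GenomeIOError):
    pass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval; ``strand`` is '+', '-' or '.'."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """One pre-collapsed transcript model per gene.

    ``exons`` are stored in transcription order (ascending coordinates on
    '+', descending on '-'); they are re-sorted on construction so callers
    may pass them in genomic order.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', "
                f"got {self.interval.strand!r}"
            )
        exons = tuple(self.exons)
        if not exons:
            raise ValidationError(f"gene {self.gene_id} has zero exons")
        exons = tuple(
            sorted(exons, key=lambda e: e.start,
                   reverse=self.interval.strand == "-")
        )
        object.__setattr__(self, "exons", exons)
        genomic = sorted(exons, key=lambda e: e.start)
        for prev, nxt in zip(genomic, genomic[1:]):
            if prev.end > nxt.start:
                raise ValidationError(
                    f"gene {self.gene_id}: overlapping exons "
                    f"{prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
                )
        for e in exons:
            if e.chrom != self.interval.chrom:
                raise ValidationError(
                    f"gene {self.gene_id}: exon on {e.chrom}, "
                    f"gene on {self.interval.chrom}"
                )
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon {e.start}-{e.end} outside "
                    f"gene body {self.interval.start}-{self.interval.end}"
                )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def first_intron(self) -> GenomicInterval | None:
        """Gap between exon 1 and exon 2 in transcription order, or None."""
        if len(self.exons) < 2:
            return None
        e1, e2 = self.exons[0], self.exons[1]
        if self.strand == "+":
            lo, hi = e1.end, e2.start
        else:
            lo, hi = e2.end, e1.start
        if lo >= hi:  # abutting exons: no intron
            return None
        return GenomicInterval(self.chrom, lo, hi, self.strand)


@dataclass
class ReadSet:
    """Aligned read intervals from one ChIP (or input) library."""

    sample_id: str
    antibody: str | None
    condition: str | None
    reads: tuple[GenomicInterval, ...]
    total_sequenced: int

    def __post_init__(self) -> None:
        self.reads = tuple(self.reads)
        if self.antibody is not None and self.antibody not in ANTIBODIES:
            raise ValidationError(f"unknown antibody {self.antibody!r}")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.total_sequenced < len(self.reads):
            raise ValidationError(
                f"sample {self.sample_id}: total_sequenced "
                f"({self.total_sequenced}) < mapped ({len(self.reads)})"
            )

    @property
    def mapped(self) -> int:
        return len(self.reads)


@dataclass
class Annotation:
    """Gene models keyed by gene_id plus chromosome lengths."""

    genes: dict[str, GeneModel]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            sizes: dict[str, int] = {}
            for g in self.genes.values():
                sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.interval.end)
            self.chrom_sizes = sizes
        for g in self.genes.values():
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValidationError(
                    f"gene {g.gene_id} on unknown chromosome {g.chrom}"
                )
            if g.interval.end > size:
                raise ValidationError(
                    f"gene {g.gene_id} extends past end of {g.chrom} "
                    f"({g.interval.end} > {size})"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[GeneModel]:
        return [self.genes[k] for k in sorted(self.genes)]


# ---------------------------------------------------------------------------
# annotation I/O


def read_annotation(path: str | os.PathLike, fmt: str | None = None,
                    chrom_sizes: Mapping[str, int] | None = None) -> Annotation:
    """Read a gene annotation from GFF3 or BED12.

    ``fmt`` is inferred from the file suffix when omitted. GFF3 coordinates
    are shifted to the internal 0-based half-open convention; chromosome
    sizes come from ``##sequence-region`` directives when present, else from
    the right-most feature end.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"gff3": "gff3", ".gff3": "gff3", ".gff": "gff3",
               ".bed": "bed12", ".bed12": "bed12"}.get(suffix)
        if fmt is None:
            raise ParseError(f"cannot infer annotation format from {path.name}")
    if fmt == "gff3":
        return _read_gff3(path, chrom_sizes)
    if fmt == "bed12":
        return _read_bed12(path, chrom_sizes)
    raise ParseError(f"unknown annotation format {fmt!r}")


def _read_gff3(path: Path, chrom_sizes: Mapping[str, int] | None) -> Annotation:
    import gffutils

    # Pre-scan so malformed lines are reported with their line number; the
    # gffutils parser's own errors are opaque about position.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path.name} line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name} line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise ParseError(
                    f"{path.name} line {lineno}: bad coordinates "
                    f"{start}-{end}"
                )

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    sizes: dict[str, int] = dict(chrom_sizes or {})
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            sizes[parts[1]] = int(parts[3])

    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        gid = g.id
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, g.strand)
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        if not exons:
            raise ValidationError(f"gene {gid} has zero exon features")
        if gid in genes:
            raise ValidationError(f"duplicate gene id {gid}")
        genes[gid] = GeneModel(
            gid, GenomicInterval(g.seqid, g.start - 1, g.end, g.strand),
            tuple(exons),
        )
    return Annotation(genes, sizes)


def _read_bed12(path: Path, chrom_sizes: Mapping[str, int] | None) -> Annotation:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path.name} line {lineno}: BED12 needs 12 fields, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
                sizes_ = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts_ = [int(x) for x in fields[11].rstrip(",").split(",")]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path.name} line {lineno}: {exc}") from exc
            if len(sizes_) != len(starts_) or len(sizes_) != int(fields[9]):
                raise ParseError(
                    f"{path.name} line {lineno}: inconsistent block columns"
                )
            exons = tuple(
                GenomicInterval(chrom, start + bs, start + bs + sz, strand)
                for bs, sz in zip(starts_, sizes_)
            )
            if name in genes:
                raise ValidationError(f"duplicate gene id {name}")
            genes[name] = GeneModel(
                name, GenomicInterval(chrom, start, end, strand), exons
            )
    return Annotation(genes, dict(chrom_sizes or {}))


def write_annotation(annotation: Annotation, path: str | os.PathLike,
                     fmt: str = "gff3") -> None:
    path = Path(path)
    if fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in sorted(annotation.chrom_sizes):
                fh.write(
                    f"##sequence-region {chrom} 1 "
                    f"{annotation.chrom_sizes[chrom]}\n"
                )
            for g in annotation.sorted_genes():
                iv = g.interval
                fh.write(
                    f"{iv.chrom}\tbivalent_smad\tgene\t{iv.start + 1}\t"
                    f"{iv.end}\t.\t{iv.strand}\t.\tID={g.gene_id}\n"
                )
                for i, e in enumerate(sorted(g.exons, key=lambda e: e.start), 1):
                    fh.write(
                        f"{e.chrom}\tbivalent_smad\texon\t{e.start + 1}\t"
                        f"{e.end}\t.\t{iv.strand}\t.\t"
                        f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                    )
    elif fmt == "bed12":
        with open(path, "w") as fh:
            for g in annotation.sorted_genes():
                iv = g.interval
                exons = sorted(g.exons, key=lambda e: e.start)
                sizes = ",".join(str(e.length) for e in exons)
                starts = ",".join(str(e.start - iv.start) for e in exons)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t"
                    f"{iv.strand}\t{iv.start}\t{iv.end}\t0\t{len(exons)}\t"
                    f"{sizes}\t{starts}\n"
                )
    else:
        raise ParseError(f"unknown annotation format {fmt!r}")


# ---------------------------------------------------------------------------
# read I/O


def read_reads_bed(path: str | os.PathLike, *, sample_id: str | None = None,
                   antibody: str | None = None, condition: str | None = None,
                   total_sequenced: int | None = None) -> ReadSet:
    """Read a BED6 read file; ``#key=value`` header lines carry metadata.

    Explicit keyword overrides (typically from a sample sheet) win over the
    file header.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    reads: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("#").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name} line {lineno}: BED needs >= 3 fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name} line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end or start < 0:
                raise ValidationError(
                    f"{path.name} line {lineno}: invalid interval "
                    f"{start}-{end}"
                )
            strand = fields[5] if len(fields) >= 6 else "."
            reads.append(GenomicInterval(fields[0], start, end, strand))

    if total_sequenced is None:
        total_sequenced = int(meta.get("total_sequenced", len(reads)))
    return ReadSet(
        sample_id=sample_id or meta.get("sample_id", path.stem),
        antibody=antibody or meta.get("antibody"),
        condition=condition or meta.get("condition"),
        reads=tuple(reads),
        total_sequenced=total_sequenced,
    )


def write_reads_bed(readset: ReadSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample_id={readset.sample_id}\n")
        if readset.antibody is not None:
            fh.write(f"#antibody={readset.antibody}\n")
        if readset.condition is not None:
            fh.write(f"#condition={readset.condition}\n")
        fh.write(f"#total_sequenced={readset.total_sequenced}\n")
        for i, r in enumerate(readset.reads):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tread_{i}\t0\t{r.strand}\n"
            )


def mapping_summary(readset: ReadSet | None = None, *,
                    mapped: int | None = None,
                    total_sequenced: int | None = None) -> float:
    """Percent of sequenced reads that mapped, to one decimal.

    Takes either a :class:`ReadSet` or explicit ``mapped`` /
    ``total_sequenced`` counts (e.g. from a sequencing summary).
    """
    if readset is not None:
        mapped, total_sequenced = readset.mapped, readset.total_sequenced
    if mapped is None or total_sequenced is None:
        raise TypeError("need a ReadSet or mapped and total_sequenced")
    if total_sequenced <= 0:
        raise ValidationError(
            "mapped fraction undefined for total_sequenced = 0")
    if mapped > total_sequenced or mapped < 0:
        raise ValidationError(
            f"mapped ({mapped}) must be in [0, total_sequenced "
            f"({total_sequenced})]")
    return round(100.0 * mapped / total_sequenced, 1)


# ---------------------------------------------------------------------------
# generic interval / peak / track writers


def write_bed(items: Sequence, path: str | os.PathLike) -> None:
    """Write intervals or peaks as BED.

    Plain intervals become BED6; objects with a ``region`` attribute (peaks)
    become BED6+1 with score = round(10 x max_ratio) and the summit in the
    extra column.
    """
    with open(path, "w") as fh:
        for i, item in enumerate(items):
            if hasattr(item, "region"):
                r = item.region
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\tpeak_{i + 1}\t"
                    f"{round(10 * item.max_ratio)}\t{r.strand}\t"
                    f"{item.summit}\n"
                )
            else:
                fh.write(
                    f"{item.chrom}\t{item.start}\t{item.end}\t"
                    f"iv_{i + 1}\t0\t{item.strand}\n"
                )


def read_bed_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    return list(read_reads_bed(path).reads)


def write_bedgraph(track, path: str | os.PathLike) -> None:
    """Write a binned SignalTrack (or ratio track) as bedGraph."""
    bin_size = track.bin_size
    values = getattr(track, "counts", None)
    if values is None:
        values = track.ratios
    with open(path, "w") as fh:
        for chrom in sorted(values):
            arr = values[chrom]
            for b, v in enumerate(arr):
                lo = b * bin_size
                v = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{chrom}\t{lo}\t{lo + bin_size}\t{v}\n")


def read_bedgraph(path: str | os.PathLike):
    """Read a bedGraph written by :func:`write_bedgraph` back into a track."""
    import numpy as np

    from .peak_calling import SignalTrack

    per_chrom: dict[str, dict[int, float]] = {}
    bin_size = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, lo, hi, val = line.split("\t")
            lo, hi = int(lo), int(hi)
            if bin_size is None:
                bin_size = hi - lo
            per_chrom.setdefault(chrom, {})[lo // bin_size] = float(val)
    if bin_size is None:
        raise ParseError(f"{path}: empty bedGraph")
    counts = {}
    for chrom, bins in per_chrom.items():
        arr = np.zeros(max(bins) + 1, dtype=float)
        for b, v in bins.items():
            arr[b] = v
        counts[chrom] = arr
    library = int(round(sum(a.sum() for a in counts.values())))
    return SignalTrack(bin_size=bin_size, counts=counts, library_size=library)


# ---------------------------------------------------------------------------
# sample sheets


def load_sample_sheet(path: str | os.PathLike) -> list[dict]:
    """Load a YAML sample sheet: a list of records with keys
    sample_id, path, antibody, condition and optional total_sequenced."""
    path = Path(path)
    with open(path) as fh:
        sheet = yaml.safe_load(fh)
    if not isinstance(sheet, list):
        raise ParseError(f"{path.name}: sample sheet must be a YAML list")
    for rec in sheet:
        if "path" not in rec:
            raise ParseError(f"{path.name}: sample record without a path")
    return sheet


def read_samples(sheet_path: str | os.PathLike) -> dict[tuple[str, str], ReadSet]:
    """Read every sample in a sheet, keyed by (antibody, condition).

    Sheet fields override BED header metadata on conflict.
    """
    sheet_path = Path(sheet_path)
    out: dict[tuple[str, str], ReadSet] = {}
    for rec in load_sample_sheet(sheet_path):
        bed = Path(rec["path"])
        if not bed.is_absolute():
            bed = sheet_path.parent / bed
        rs = read_reads_bed(
            bed,
            sample_id=rec.get("sample_id"),
            antibody=rec.get("antibody"),
            condition=rec.get("condition"),
            total_sequenced=rec.get("total_sequenced"),
        )
        key = (rs.antibody, rs.condition)
        if key in out:
            raise ValidationError(f"duplicate sample for {key}")
        out[key] = rs
    return out
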
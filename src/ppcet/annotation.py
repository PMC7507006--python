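"""Genome annotations, gene models and promoter windows.

All coordinates are 0-based, half-open (BED convention). A gene is reduced
to a single (TSS, TTS) anchor pair; on the minus strand the TSS is the
*larger* coordinate. Promoter windows are symmetric in genome space around
the TSS (strand only matters when orienting meta-profiles).
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

VALID_LABELS = frozenset({"pCR", "non-pCR", "unknown"})


def normalize_chrom_name(name: str, mode: str | None) -> str:
    """Optional "chr"-prefix harmonization ("add", "strip" or None)."""
    if mode is None:
        return name
    if mode == "add":
        return name if name.startswith("chr") else f"chr{name}"
    if mode == "strip":
        return name[3:] if name.startswith("chr") else name
    raise ValueError(f"unknown chromosome normalization mode {mode!r}")


@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome name/length table plus the mitochondrial contig name."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    mito_name: str | None = None

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.mito_name is not None and self.mito_name not in self.chrom_names:
            raise ValueError(f"mito_name {self.mito_name!r} not in assembly")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def nuclear_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.chrom_names if c != self.mito_name)

    @property
    def nuclear_bp(self) -> int:
        return sum(self.lengths[c] for c in self.nuclear_names)


@dataclass(frozen=True)
class GeneModel:
    """One gene collapsed to a TSS/TTS anchor pair.

    ``tss < tts`` on the plus strand and ``tss > tts`` on the minus strand;
    both are 0-based genome positions.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss == self.tts:
            raise ValueError(f"gene {self.gene_id}: tss == tts")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tts")


@dataclass(frozen=True)
class PromoterWindow:
    """Half-open promoter interval around a TSS, clipped to the chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    clipped: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    label: str
    collection_date: _dt.date
    fragment_path: str | None = None

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {sorted(VALID_LABELS)}, got {self.label!r}")


def _parse_bed12_line(fields: Sequence[str], lineno: int) -> GeneModel:
    if len(fields) < 6:
        raise ValueError(f"line {lineno}: BED gene annotation needs >= 6 columns")
    chrom, start, end, name, _, strand = fields[:6]
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed BED record ({exc})") from exc
    if end_i <= start_i:
        raise ValueError(f"line {lineno}: end <= start")
    if strand == "+":
        return GeneModel(name, chrom, "+", tss=start_i, tts=end_i)
    if strand == "-":
        return GeneModel(name, chrom, "-", tss=end_i, tts=start_i)
    raise ValueError(f"line {lineno}: bad strand {strand!r}")


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_annotation(
    path: str | Path,
    format: str | None = None,
    assembly: GenomeAssembly | None = None,
    collapse: str = "five_prime",
    normalize_chrom: str | None = None,
) -> list[GeneModel]:
    """Read gene models from BED12/BED6 or GTF.

    GTF transcripts sharing a ``gene_id`` are collapsed to one model whose
    TSS is the 5'-most transcript start (``collapse="five_prime"``, the
    default) or kept per transcript (``collapse="per_transcript"``, with
    ids ``gene:transcript_index``). Genes on chromosomes absent from
    *assembly* (when given) are skipped and counted.
    """
    path = Path(path)
    if format is None:
        format = "GTF" if path.suffix.lower() in (".gtf", ".gff") else "BED12"
    if format not in ("BED12", "GTF"):
        raise ValueError(f"unknown annotation format {format!r}")
    if collapse not in ("five_prime", "per_transcript"):
        raise ValueError(f"unknown collapse mode {collapse!r}")

    known = set(assembly.chrom_names) if assembly is not None else None
    skipped = 0
    genes: list[GeneModel] = []

    if format == "BED12":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                try:
                    gm = _parse_bed12_line(fields, lineno)
                except ValueError:
                    raise
                except Exception as exc:  # int() failures etc.
                    raise ValueError(f"line {lineno}: malformed BED record ({exc})") from exc
                if normalize_chrom:
                    gm = GeneModel(gm.gene_id, normalize_chrom_name(gm.chrom, normalize_chrom),
                                   gm.strand, gm.tss, gm.tts)
                if known is not None and gm.chrom not in known:
                    skipped += 1
                    continue
                genes.append(gm)
    else:
        # transcript spans per gene_id: (chrom, strand, [starts], [ends])
        tx: dict[str, list] = {}
        order: list[str] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9:
                    raise ValueError(f"line {lineno}: GTF needs 9 tab-separated columns")
                chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
                if feature != "transcript":
                    continue
                chrom = normalize_chrom_name(chrom, normalize_chrom)
                m = _GTF_GENE_ID.search(attrs)
                if m is None:
                    raise ValueError(f"line {lineno}: missing gene_id attribute")
                if strand not in ("+", "-"):
                    raise ValueError(f"line {lineno}: bad strand {strand!r}")
                if known is not None and chrom not in known:
                    skipped += 1
                    continue
                gid = m.group(1)
                s, e = int(start) - 1, int(end)  # GTF is 1-based closed
                if e <= s:
                    raise ValueError(f"line {lineno}: end <= start")
                if gid not in tx:
                    tx[gid] = [chrom, strand, []]
                    order.append(gid)
                elif tx[gid][0] != chrom or tx[gid][1] != strand:
                    raise ValueError(f"gene {gid}: transcripts on mixed chrom/strand")
                tx[gid][2].append((s, e))
        for gid in order:
            chrom, strand, spans = tx[gid]
            if collapse == "per_transcript":
                for i, (s, e) in enumerate(spans):
                    name = f"{gid}:{i}"
                    if strand == "+":
                        genes.append(GeneModel(name, chrom, "+", tss=s, tts=e))
                    else:
                        genes.append(GeneModel(name, chrom, "-", tss=e, tts=s))
            else:
                if strand == "+":
                    tss = min(s for s, _ in spans)
                    tts = max(e for _, e in spans)
                    genes.append(GeneModel(gid, chrom, "+", tss=tss, tts=tts))
                else:
                    tss = max(e for _, e in spans)
                    tts = min(s for s, _ in spans)
                    genes.append(GeneModel(gid, chrom, "-", tss=tss, tts=tts))

    if skipped:
        logger.warning("read_gene_annotation: skipped %d records on unknown chromosomes", skipped)
    return genes


def derive_promoter_windows(
    genes: Iterable[GeneModel],
    flank: int = 1000,
    assembly: GenomeAssembly | None = None,
) -> list[PromoterWindow]:
    """Promoter window ``[tss - flank, tss + flank)`` per gene, clipped.

    The window is symmetric in genome coordinates regardless of strand;
    clipping at chromosome edges is recorded on the window.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    windows: list[PromoterWindow] = []
    for g in genes:
        chrom_len = assembly.length(g.chrom) if assembly is not None else None
        if chrom_len is not None and not (0 <= g.tss <= chrom_len):
            raise ValueError(f"gene {g.gene_id}: tss {g.tss} outside chromosome {g.chrom}")
        start = g.tss - flank
        end = g.tss + flank
        clipped = False
        if start < 0:
            start, clipped = 0, True
        if chrom_len is not None and end > chrom_len:
            end, clipped = chrom_len, True
        windows.append(PromoterWindow(g.gene_id, g.chrom, start, end, g.strand, clipped))
    return windows


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Headered TSV: sample_id, label, collection_date, fragment_path."""
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "label", "collection_date"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"sample sheet must have columns {sorted(required)}")
        for row in reader:
            sid = row["sample_id"]
            if sid in seen:
                raise ValueError(f"duplicate sample_id {sid!r}")
            seen.add(sid)
            records.append(
                SampleRecord(
                    sample_id=sid,
                    label=row["label"],
                    collection_date=_dt.date.fromisoformat(row["collection_date"]),
                    fragment_path=row.get("fragment_path") or None,
                )
            )
    return records


def write_sample_sheet(records: Iterable[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "label", "collection_date", "fragment_path"])
        for r in records:
            writer.writerow([r.sample_id, r.label, r.collection_date.isoformat(), r.fragment_path or ""])
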
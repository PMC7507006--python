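"""Promoter coverage matrices and TSS/TTS composite meta-profiles.

The coverage readout per promoter is the mean per-base fragment-overlap
depth over the window, scaled per million fragments in the sample library
(depth normalization). Meta-profiles average per-base normalized depth
over genes within a sample (oriented so offsets increase in transcription
direction), then over samples, keeping samples the exchangeable unit for
group testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAssembly, PromoterWindow, SampleRecord
from .fragments import FragmentSet

logger = logging.getLogger(__name__)

PER_MILLION = 1e6


@dataclass
class PromoterCoverageMatrix:
    """Genes × samples normalized promoter coverage."""

    values: pd.DataFrame  # index = gene_ids, columns = sample_ids
    total_fragments: pd.Series  # per-sample library size (raw)
    normalization: str = "per-million-fragments"

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.total_fragments.index):
            raise ValueError("sample metadata does not match matrix columns")
        vals = self.values.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise ValueError("coverage values must be finite and non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class MetaProfile:
    offsets: np.ndarray  # -flank .. flank-1, transcription-oriented
    signal: np.ndarray  # mean normalized depth per offset
    anchor: str  # "TSS" or "TTS"
    group: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "signal": self.signal, "group": self.group})


def window_depth(fragments: FragmentSet, window: PromoterWindow) -> float:
    """Mean per-base overlap depth of a sample's fragments over one window."""
    if window.span <= 0:
        raise ValueError("window has zero span")
    total = fragments.overlap_sums(window.chrom, [window.start], [window.end])[0]
    return float(total) / window.span


def _window_depths(fragments: FragmentSet, windows: Sequence[PromoterWindow]) -> np.ndarray:
    out = np.zeros(len(windows), dtype=np.float64)
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        starts = np.array([windows[i].start for i in idxs])
        ends = np.array([windows[i].end for i in idxs])
        sums = fragments.overlap_sums(chrom, starts, ends)
        out[idxs] = sums / (ends - starts)
    return out


def _window_midpoint_rates(fragments: FragmentSet, windows: Sequence[PromoterWindow]) -> np.ndarray:
    out = np.zeros(len(windows), dtype=np.float64)
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        starts = np.array([windows[i].start for i in idxs])
        ends = np.array([windows[i].end for i in idxs])
        out[idxs] = fragments.midpoint_counts(chrom, starts, ends) / (ends - starts)
    return out


def promoter_matrix(
    samples: Sequence[tuple[SampleRecord, FragmentSet]],
    windows: Sequence[PromoterWindow],
    normalization: str = "per-million-fragments",
    statistic: str = "per-base",
) -> PromoterCoverageMatrix:
    """Normalized promoter coverage: depth × 1e6 / total fragments.

    ``statistic="per-base"`` (default) uses mean per-base overlap depth;
    ``statistic="midpoint"`` counts fragment midpoints per window bp, for
    sensitivity analyses.
    """
    if not samples or not windows:
        raise ValueError("need at least one sample and one window")
    if normalization != "per-million-fragments":
        raise ValueError(f"unknown normalization {normalization!r}")
    if statistic not in ("per-base", "midpoint"):
        raise ValueError(f"unknown statistic {statistic!r}")
    gene_ids = [w.gene_id for w in windows]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene_ids among promoter windows")
    measure = _window_depths if statistic == "per-base" else _window_midpoint_rates
    cols = {}
    totals = {}
    for rec, fs in samples:
        total = fs.n_fragments
        totals[rec.sample_id] = total
        if total == 0:
            logger.warning("sample %s has 0 fragments; coverage column is all zeros", rec.sample_id)
            cols[rec.sample_id] = np.zeros(len(windows))
        else:
            cols[rec.sample_id] = measure(fs, windows) * PER_MILLION / total
    values = pd.DataFrame(cols, index=gene_ids)
    return PromoterCoverageMatrix(values=values, total_fragments=pd.Series(totals, dtype=float)[values.columns])


def _sample_profile(
    fs: FragmentSet,
    genes: Sequence[GeneModel],
    anchor: str,
    flank: int,
    assembly: GenomeAssembly | None,
) -> np.ndarray:
    """Per-offset normalized depth for one sample, averaged over genes."""
    acc = np.zeros(2 * flank, dtype=np.float64)
    used = 0
    for g in genes:
        pos = g.tss if anchor == "TSS" else g.tts
        start, end = pos - flank, pos + flank
        if start < 0 or (assembly is not None and end > assembly.length(g.chrom)):
            continue  # clipped anchors are excluded from the composite
        cov = fs.window_coverage(g.chrom, start, end)
        if g.strand == "-":
            cov = cov[::-1]
        acc += cov
        used += 1
    if used == 0:
        return acc
    acc /= used
    total = fs.n_fragments
    return acc * PER_MILLION / total if total else acc


def meta_profiles_by_sample(
    samples: Sequence[tuple[SampleRecord, FragmentSet]],
    genes: Sequence[GeneModel],
    anchor: str = "TSS",
    flank: int = 1000,
    assembly: GenomeAssembly | None = None,
) -> pd.DataFrame:
    """Samples × offsets table of per-sample composite profiles."""
    if anchor not in ("TSS", "TTS"):
        raise ValueError("anchor must be 'TSS' or 'TTS'")
    if not genes:
        raise ValueError("gene list is empty")
    offsets = np.arange(-flank, flank)
    rows = {
        rec.sample_id: _sample_profile(fs, genes, anchor, flank, assembly)
        for rec, fs in samples
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=offsets)


def meta_profile(
    samples: Sequence[tuple[SampleRecord, FragmentSet]],
    genes: Sequence[GeneModel],
    anchor: str = "TSS",
    flank: int = 1000,
    assembly: GenomeAssembly | None = None,
    group: str = "all",
) -> MetaProfile:
    """Composite profile: gene-mean within sample, then mean over samples."""
    per_sample = meta_profiles_by_sample(samples, genes, anchor, flank, assembly)
    return MetaProfile(
        offsets=per_sample.columns.to_numpy(),
        signal=per_sample.to_numpy().mean(axis=0),
        anchor=anchor,
        group=group,
    )
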
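"""Comparator fragmentomic feature families.

Three genome-wide feature sets serve as baselines against promoter
profiling: (1) short/long fragment-length ratios in non-overlapping 5-Mb
bins (the DELFI-style fragmentation profile), (2) fragments-per-million
per bp in labeled genome subcompartment classes, and (3) a mitochondrial
DNA copy-number proxy. Fragments are assigned to bins/regions by their
midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAssembly
from .fragments import FragmentSet

logger = logging.getLogger(__name__)


@dataclass
class BinFeatureVector:
    sample_id: str
    ids: list[str]  # bin or region-class identifiers
    values: np.ndarray
    feature_kind: str  # "fragment_ratio_5mb" | "subcompartment_coverage"

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.ids, name=self.sample_id)


@dataclass
class MtDnaEstimate:
    sample_id: str
    mito_fragments: int
    nuclear_fragments: int
    copy_number_proxy: float


def fragment_profile_5mb(
    fragments: FragmentSet,
    assembly: GenomeAssembly,
    short_range: tuple[int, int] = (100, 150),
    long_range: tuple[int, int] = (151, 220),
    bin_size: int = 5_000_000,
    sample_id: str = "",
) -> BinFeatureVector:
    """Short/long fragment-count ratio per 5-Mb bin, z-standardized.

    Bins are full non-overlapping ``bin_size`` windows tiling each nuclear
    contig from its start. Bins with zero long fragments are imputed to
    the sample median ratio; a constant ratio vector standardizes to all
    zeros.
    """
    if short_range[1] >= long_range[0] or short_range[0] > short_range[1] or long_range[0] > long_range[1]:
        raise ValueError("length ranges must be ordered and disjoint")
    ids: list[str] = []
    ratios: list[float] = []
    for chrom in assembly.nuclear_names:
        n_bins = assembly.length(chrom) // bin_size
        if n_bins == 0:
            continue
        mids = fragments.midpoints(chrom)
        lens = fragments.lengths(chrom)
        in_bins = mids < n_bins * bin_size
        bin_idx = mids[in_bins] // bin_size
        lens = lens[in_bins]
        short = (lens >= short_range[0]) & (lens <= short_range[1])
        long = (lens >= long_range[0]) & (lens <= long_range[1])
        n_short = np.bincount(bin_idx[short], minlength=n_bins).astype(float)
        n_long = np.bincount(bin_idx[long], minlength=n_bins).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(n_long > 0, n_short / np.maximum(n_long, 1e-300), np.nan)
        ids.extend(f"{chrom}:{i * bin_size}-{(i + 1) * bin_size}" for i in range(n_bins))
        ratios.extend(r.tolist())
    if not ids:
        raise ValueError("assembly has no complete bins at this bin size")
    vals = np.asarray(ratios, dtype=np.float64)
    missing = np.isnan(vals)
    if missing.all():
        vals = np.zeros_like(vals)
    elif missing.any():
        vals[missing] = np.nanmedian(vals)
    sd = vals.std()
    vals = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    return BinFeatureVector(sample_id, ids, vals, "fragment_ratio_5mb")


def read_region_classes(path: str | Path) -> pd.DataFrame:
    """4-column BED (chrom, start, end, class) of subcompartment regions."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "label"], usecols=[0, 1, 2, 3],
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("region with end <= start")
    return df


def subcompartment_coverage(
    fragments: FragmentSet,
    regions: pd.DataFrame,
    assembly: GenomeAssembly | None = None,
    sample_id: str = "",
) -> BinFeatureVector:
    """Fragments-per-million per bp of each region class (by midpoint)."""
    regions = regions.copy()
    if assembly is not None:
        known = set(assembly.chrom_names)
        bad = ~regions["chrom"].isin(known)
        if bad.any():
            logger.warning("subcompartment_coverage: skipped %d regions on unknown chromosomes", int(bad.sum()))
            regions = regions[~bad]
    total = fragments.n_fragments
    labels = sorted(regions["label"].unique())
    values = []
    for label in labels:
        sub = regions[regions["label"] == label]
        bp = int((sub["end"] - sub["start"]).sum())
        if bp == 0:
            logger.warning("subcompartment class %r covers 0 bp", label)
            values.append(0.0)
            continue
        count = 0
        for chrom, grp in sub.groupby("chrom"):
            count += int(fragments.midpoint_counts(chrom, grp["start"].to_numpy(), grp["end"].to_numpy()).sum())
        fpm = count * 1e6 / total if total else 0.0
        values.append(fpm / bp)
    return BinFeatureVector(sample_id, [str(l) for l in labels], np.asarray(values), "subcompartment_coverage")


def mtdna_copy_number(
    fragments: FragmentSet,
    assembly: GenomeAssembly,
    sample_id: str = "",
) -> MtDnaEstimate:
    """Length-normalized mito/nuclear fragment-rate ratio, diploid-scaled.

    proxy = (mito_fragments / mito_bp) / (nuclear_fragments / nuclear_bp) × 2.
    """
    if assembly.mito_name is None:
        raise ValueError("assembly does not declare a mitochondrial contig")
    mito = fragments.count(assembly.mito_name)
    nuclear = fragments.n_fragments - mito
    if nuclear == 0:
        raise ValueError("no nuclear fragments; copy-number proxy undefined")
    mito_rate = mito / assembly.length(assembly.mito_name)
    nuc_rate = nuclear / assembly.nuclear_bp
    return MtDnaEstimate(sample_id, mito, nuclear, copy_number_proxy=2.0 * mito_rate / nuc_rate)


def comparator_feature_table(
    samples,
    assembly: GenomeAssembly,
    kind: str,
    regions: pd.DataFrame | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Samples × features table for one comparator family."""
    rows = {}
    for rec, fs in samples:
        if kind == "fragment_ratio_5mb":
            fv = fragment_profile_5mb(fs, assembly, sample_id=rec.sample_id, **kwargs)
            rows[rec.sample_id] = fv.to_series()
        elif kind == "subcompartment_coverage":
            if regions is None:
                raise ValueError("subcompartment_coverage requires a region table")
            fv = subcompartment_coverage(fs, regions, assembly, sample_id=rec.sample_id)
            rows[rec.sample_id] = fv.to_series()
        elif kind == "mtdna":
            est = mtdna_copy_number(fs, assembly, sample_id=rec.sample_id)
            rows[rec.sample_id] = pd.Series({"mtdna_copy_number": est.copy_number_proxy})
        else:
            raise ValueError(f"unknown comparator kind {kind!r}")
    return pd.DataFrame(rows).T
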
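"""Synthetic cfDNA cohorts with a nucleosome footprint at promoters.

The generative model mirrors the biology the package analyses: plasma
cfDNA is nucleosome-protected DNA, so fragment midpoints concentrate on a
genome-wide grid of nucleosome centers; promoters of *expressed* genes are
nucleosome-depleted, so fragment sampling density inside their ±1 kb TSS
window is multiplied by ``(1 − d)`` where ``d`` is the depletion strength.
A therapy-response effect is encoded by flipping the expression class of a
chosen differential gene set in the non-pCR group, so the two groups differ
in promoter coverage at exactly those genes — the ground truth every
downstream stage is checked against.

The genome is a small synthetic assembly (two autosome-like contigs plus a
16.6 kb mitochondrial contig); coordinates do not correspond to any real
genome. Sequence-level effects (GC bias, mappability, copy number) are out
of scope.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    GeneModel,
    GenomeAssembly,
    PromoterWindow,
    SampleRecord,
    derive_promoter_windows,
    write_sample_sheet,
)
from .fragments import FragmentSet, write_fragments

MITO_LENGTH = 16_569  # human mtDNA length, reused for the synthetic contig


def default_assembly(
    autosome_lengths: Sequence[int] = (20_000_000, 20_000_000),
    mito_length: int = MITO_LENGTH,
) -> GenomeAssembly:
    names = tuple(f"chr{i + 1}" for i in range(len(autosome_lengths))) + ("chrM",)
    lengths = tuple(autosome_lengths) + (mito_length,)
    return GenomeAssembly(names, lengths, mito_name="chrM")


def make_gene_universe(
    n_genes: int,
    assembly: GenomeAssembly,
    gene_length: int = 10_000,
    margin: int = 20_000,
    seed: int = 0,
) -> list[GeneModel]:
    """Evenly spread synthetic genes over the nuclear contigs.

    TSS positions get a random sub-spacing jitter so promoter windows are
    not phase-locked to the nucleosome grid; strands alternate. Gene
    bodies never overlap a neighbour's promoter window.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    nuclear = assembly.nuclear_names
    total = assembly.nuclear_bp
    per_chrom = [max(1, round(n_genes * assembly.length(c) / total)) for c in nuclear]
    # adjust rounding drift on the largest contig
    per_chrom[-1] += n_genes - sum(per_chrom)
    genes: list[GeneModel] = []
    gi = 0
    for chrom, k in zip(nuclear, per_chrom):
        usable = assembly.length(chrom) - 2 * margin
        if usable <= k * gene_length:
            raise ValueError(f"{chrom} too short for {k} genes")
        pitch = usable // k
        jitter = rng.integers(0, max(1, pitch - gene_length - 2000), size=k)
        for j in range(k):
            anchor = margin + j * pitch + int(jitter[j])
            strand = "+" if gi % 2 == 0 else "-"
            if strand == "+":
                genes.append(GeneModel(f"g{gi:05d}", chrom, "+", tss=anchor, tts=anchor + gene_length))
            else:
                genes.append(GeneModel(f"g{gi:05d}", chrom, "-", tss=anchor + gene_length, tts=anchor))
            gi += 1
    return genes


@dataclass(frozen=True)
class ExpressionProgram:
    """Per-gene expression classes and the group-differential overrides.

    ``classes`` is the base program shared by both groups; genes listed in
    ``differential`` have their class flipped in the non-pCR group.
    ``ndr_depletion`` (d) multiplies fragment density inside the promoter
    window of every "high" gene by (1 − d); d = 1 is the idealized fully
    nucleosome-depleted promoter.
    """

    classes: dict[str, str]  # gene_id -> {"high", "low"}
    differential: tuple[str, ...]
    ndr_depletion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ndr_depletion <= 1.0:
            raise ValueError("ndr_depletion must be in [0, 1]")
        bad = set(self.differential) - set(self.classes)
        if bad:
            raise ValueError(f"differential genes outside universe: {sorted(bad)[:3]}")
        if any(v not in ("high", "low") for v in self.classes.values()):
            raise ValueError("expression classes must be 'high' or 'low'")

    def class_for(self, gene_id: str, group: str) -> str:
        base = self.classes[gene_id]
        if group == "non-pCR" and gene_id in set(self.differential):
            return "low" if base == "high" else "high"
        return base


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_pcr: int = 10
    n_nonpcr: int = 10
    n_genes: int = 2000
    n_differential: int = 50
    mean_fragments_per_sample: int = 200_000
    fragment_length_mean: float = 167.0
    fragment_length_sd: float = 10.0
    nucleosome_spacing: int = 190
    jitter_sd: float = 20.0
    background_fraction: float = 0.10
    mito_fraction: float = 0.01
    ndr_depletion: float = 0.9
    high_fraction: float = 0.5
    promoter_flank: int = 1000
    ndr_mode: Literal["window", "core"] = "window"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pcr, self.n_nonpcr, self.n_genes, self.n_differential, 0) < 0:
            raise ValueError("counts must be >= 0")
        for name in ("background_fraction", "mito_fraction", "ndr_depletion", "high_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.background_fraction + self.mito_fraction > 1.0:
            raise ValueError("background_fraction + mito_fraction must be <= 1")
        if self.n_differential > self.n_genes:
            raise ValueError("n_differential exceeds the gene universe")


@dataclass
class CohortResult:
    config: SyntheticCohortConfig
    assembly: GenomeAssembly
    genes: list[GeneModel]
    windows: list[PromoterWindow]
    program: ExpressionProgram
    samples: list[SampleRecord]
    fragments: dict[str, FragmentSet]
    truth_samples: pd.DataFrame
    truth_genes: pd.DataFrame

    @property
    def labels(self) -> pd.Series:
        return pd.Series({s.sample_id: s.label for s in self.samples})


def build_program(
    genes: Sequence[GeneModel],
    n_differential: int,
    ndr_depletion: float,
    high_fraction: float = 0.5,
    seed: int = 0,
) -> ExpressionProgram:
    """Assign base expression classes and pick the differential gene set."""
    if not genes:
        raise ValueError("gene universe is empty")
    if n_differential > len(genes):
        raise ValueError("n_differential exceeds the gene universe")
    rng = np.random.default_rng(seed)
    ids = [g.gene_id for g in genes]
    high = rng.random(len(ids)) < high_fraction
    classes = {gid: ("high" if h else "low") for gid, h in zip(ids, high)}
    diff = tuple(sorted(rng.choice(ids, size=n_differential, replace=False).tolist()))
    return ExpressionProgram(classes=classes, differential=diff, ndr_depletion=ndr_depletion)


def _depleted_intervals(
    windows: Sequence[PromoterWindow],
    program: ExpressionProgram,
    group: str,
    mode: str,
) -> dict[str, np.ndarray]:
    """Flattened sorted [s0,e0,s1,e1,...] arrays of depleted bp per chromosome."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        if program.class_for(w.gene_id, group) != "high":
            continue
        if mode == "core":
            # NDR is typically confined just upstream of the TSS
            tss = w.start + (w.end - w.start) // 2
            s, e = (tss - 200, tss + 50) if w.strand == "+" else (tss - 50, tss + 200)
            s, e = max(s, w.start), min(e, w.end)
        else:
            s, e = w.start, w.end
        per_chrom.setdefault(w.chrom, []).append((s, e))
    out: dict[str, np.ndarray] = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64).ravel()
    return out


def _truncated_normal(rng: np.random.Generator, n: int, mean: float, sd: float,
                      lo: float, hi: float) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_sample(
    config: SyntheticCohortConfig,
    program: ExpressionProgram,
    group: str,
    seed: int | np.random.SeedSequence,
    assembly: GenomeAssembly | None = None,
    windows: Sequence[PromoterWindow] | None = None,
) -> tuple[FragmentSet, dict]:
    """Draw one sample's fragments; deterministic given the seed.

    Fragment midpoints come from nucleosome centers tiled every
    ``nucleosome_spacing`` bp with Gaussian positional jitter, thinned by
    (1 − d) inside depleted promoter windows; a ``background_fraction``
    of midpoints is uniform over the nuclear genome (not thinned) and a
    ``mito_fraction`` lands uniformly on the mitochondrial contig.
    """
    if group not in ("pCR", "non-pCR"):
        raise ValueError(f"group must be 'pCR' or 'non-pCR', got {group!r}")
    if assembly is None:
        assembly = default_assembly()
    if windows is None:
        raise ValueError("promoter windows are required (gene universe empty?)")
    if not windows:
        raise ValueError("gene universe is empty")
    rng = np.random.default_rng(seed)
    n_total = int(rng.poisson(config.mean_fragments_per_sample))
    if n_total == 0:
        return FragmentSet({}), {"group": group, "n_fragments": 0, "n_mito": 0}

    n_mito, n_bg, n_nuc = rng.multinomial(
        n_total,
        [
            config.mito_fraction,
            config.background_fraction,
            1.0 - config.mito_fraction - config.background_fraction,
        ],
    )

    depleted = _depleted_intervals(windows, program, group, config.ndr_mode)
    d = program.ndr_depletion
    nuclear = assembly.nuclear_names
    nuc_lengths = np.array([assembly.length(c) for c in nuclear], dtype=np.float64)
    chrom_p = nuc_lengths / nuc_lengths.sum()
    n_centers = (nuc_lengths // config.nucleosome_spacing).astype(np.int64)

    chrom_out: list[np.ndarray] = []
    mid_out: list[np.ndarray] = []

    # nucleosome-grid midpoints with rejection thinning in depleted windows
    need = int(n_nuc)
    while need > 0:
        ci = rng.choice(len(nuclear), size=need, p=chrom_p)
        idx = rng.integers(0, n_centers[ci])
        pos = idx * config.nucleosome_spacing + config.nucleosome_spacing // 2
        pos = pos + np.rint(rng.normal(0.0, config.jitter_sd, size=need)).astype(np.int64)
        pos = np.clip(pos, 0, (nuc_lengths[ci] - 1).astype(np.int64))
        accept = np.ones(need, dtype=bool)
        if d > 0:
            u = rng.random(need)
            for k, chrom in enumerate(nuclear):
                flat = depleted.get(chrom)
                if flat is None:
                    continue
                m = ci == k
                if not m.any():
                    continue
                inside = np.searchsorted(flat, pos[m], side="right") % 2 == 1
                rej = inside & (u[m] < d)
                sub = accept[m]
                sub[rej] = False
                accept[m] = sub
        chrom_out.append(ci[accept])
        mid_out.append(pos[accept])
        need -= int(accept.sum())

    # uniform nuclear background (no thinning: models non-nucleosomal noise)
    if n_bg:
        ci = rng.choice(len(nuclear), size=int(n_bg), p=chrom_p)
        pos = (rng.random(int(n_bg)) * nuc_lengths[ci]).astype(np.int64)
        chrom_out.append(ci)
        mid_out.append(pos)

    ci_all = np.concatenate(chrom_out) if chrom_out else np.empty(0, dtype=np.int64)
    mid_all = np.concatenate(mid_out) if mid_out else np.empty(0, dtype=np.int64)

    # mitochondrial fragments
    mito_name = assembly.mito_name
    if n_mito and mito_name is None:
        raise ValueError("mito_fraction > 0 but assembly has no mitochondrial contig")
    mito_mid = (rng.random(int(n_mito)) * assembly.length(mito_name)).astype(np.int64) if n_mito else None

    lengths = _truncated_normal(
        rng, len(mid_all) + int(n_mito), config.fragment_length_mean, config.fragment_length_sd, 100, 400
    ).astype(np.int64)

    intervals: dict[str, np.ndarray] = {}
    for k, chrom in enumerate(nuclear):
        m = ci_all == k
        if not m.any():
            continue
        L = lengths[: len(mid_all)][m]
        starts = np.maximum(mid_all[m] - L // 2, 0)
        ends = np.minimum(starts + L, assembly.length(chrom))
        intervals[chrom] = np.column_stack((starts, ends))
    if mito_mid is not None and n_mito:
        L = lengths[len(mid_all):]
        starts = np.maximum(mito_mid - L // 2, 0)
        ends = np.minimum(starts + L, assembly.length(mito_name))
        intervals[mito_name] = np.column_stack((starts, ends))

    fs = FragmentSet(intervals)
    truth = {
        "group": group,
        "n_fragments": fs.n_fragments,
        "n_mito": int(n_mito),
        "mito_fraction_realized": (int(n_mito) / n_total) if n_total else 0.0,
    }
    return fs, truth


def _interleaved_order(n_pcr: int, n_nonpcr: int) -> list[str]:
    """Group labels in collection order, interleaved by fractional rank."""
    keyed = [((i + 0.5) / n_pcr, 0, "pCR") for i in range(n_pcr)]
    keyed += [((i + 0.5) / n_nonpcr, 1, "non-pCR") for i in range(n_nonpcr)]
    keyed.sort()
    return [g for _, _, g in keyed]


def simulate_cohort(
    config: SyntheticCohortConfig,
    assembly: GenomeAssembly | None = None,
    genes: Sequence[GeneModel] | None = None,
    start_date: _dt.date = _dt.date(2020, 1, 1),
) -> CohortResult:
    """Simulate a full two-group cohort with truth tables.

    Collection dates advance one day per sample with the two groups
    interleaved, so a chronological train/validation split at any fraction
    contains both labels.
    """
    if assembly is None:
        assembly = default_assembly()
    if genes is None:
        genes = make_gene_universe(config.n_genes, assembly, seed=config.seed)
    if not genes:
        raise ValueError("gene universe is empty")
    windows = derive_promoter_windows(genes, flank=config.promoter_flank, assembly=assembly)
    ss = np.random.SeedSequence(config.seed)
    prog_seed, *sample_seeds = ss.spawn(1 + config.n_pcr + config.n_nonpcr)
    program = build_program(
        genes,
        n_differential=config.n_differential,
        ndr_depletion=config.ndr_depletion,
        high_fraction=config.high_fraction,
        seed=prog_seed,
    )

    groups = _interleaved_order(config.n_pcr, config.n_nonpcr) if config.n_pcr and config.n_nonpcr else (
        ["pCR"] * config.n_pcr + ["non-pCR"] * config.n_nonpcr
    )
    samples: list[SampleRecord] = []
    fragments: dict[str, FragmentSet] = {}
    truth_rows = []
    for i, group in enumerate(groups):
        sid = f"S{i:03d}"
        fs, truth = simulate_sample(config, program, group, sample_seeds[i], assembly, windows)
        date = start_date + _dt.timedelta(days=i)
        samples.append(SampleRecord(sid, group, date, fragment_path=f"{sid}.bed"))
        fragments[sid] = fs
        truth_rows.append({"sample_id": sid, "collection_date": date.isoformat(), **truth})

    truth_samples = pd.DataFrame(truth_rows)
    diff_set = set(program.differential)
    truth_genes = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "base_class": [program.classes[g.gene_id] for g in genes],
            "pcr_class": [program.class_for(g.gene_id, "pCR") for g in genes],
            "nonpcr_class": [program.class_for(g.gene_id, "non-pCR") for g in genes],
            "differential": [g.gene_id in diff_set for g in genes],
        }
    )
    return CohortResult(
        config=config,
        assembly=assembly,
        genes=list(genes),
        windows=windows,
        program=program,
        samples=samples,
        fragments=fragments,
        truth_samples=truth_samples,
        truth_genes=truth_genes,
    )


def write_cohort(result: CohortResult, outdir: str | Path) -> Path:
    """Write fragment BEDs, sample sheet, truth tables and the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample in result.samples:
        write_fragments(result.fragments[sample.sample_id], outdir / sample.fragment_path)
    write_sample_sheet(result.samples, outdir / "samples.tsv")
    result.truth_samples.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
    result.truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    with open(outdir / "genes.bed", "w") as fh:
        for g in result.genes:
            lo, hi = min(g.tss, g.tts), max(g.tss, g.tts)
            fh.write(f"{g.chrom}\t{lo}\t{hi}\t{g.gene_id}\t0\t{g.strand}\n")
    cfg = {k: (v if not isinstance(v, float) else float(v)) for k, v in vars(result.config).items()}
    cfg["assembly"] = {
        "chrom_names": list(result.assembly.chrom_names),
        "chrom_lengths": list(result.assembly.chrom_lengths),
        "mito_name": result.assembly.mito_name,
    }
    with open(outdir / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return outdir
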
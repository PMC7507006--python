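import datetime as dt

import numpy as np
import pytest

from ppcet.annotation import GenomeAssembly, SampleRecord
from ppcet.fragments import FragmentSet
from ppcet.simulate import (
    SyntheticCohortConfig,
    default_assembly,
    make_gene_universe,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def tiny_assembly():
    return GenomeAssembly(("chr1", "chr2", "chrM"), (100_000, 50_000, 16_569), mito_name="chrM")


@pytest.fixture
def make_sample():
    def _make(sample_id="S0", label="pCR", day=0, path=None):
        return SampleRecord(sample_id, label, dt.date(2020, 1, 1) + dt.timedelta(days=day), path)

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """Shared moderate-effect synthetic cohort (5+5, 300 genes)."""
    cfg = SyntheticCohortConfig(
        n_pcr=5, n_nonpcr=5, n_genes=300, n_differential=20,
        mean_fragments_per_sample=40_000, ndr_depletion=0.9, seed=11,
    )
    assembly = default_assembly((2_000_000, 2_000_000))
    genes = make_gene_universe(cfg.n_genes, assembly, seed=cfg.seed)
    return simulate_cohort(cfg, assembly=assembly, genes=genes)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def fragset(*triples) -> FragmentSet:
    """Build a FragmentSet from (chrom, start, end) triples."""
    chroms = np.array([t[0] for t in triples], dtype=object)
    starts = [t[1] for t in triples]
    ends = [t[2] for t in triples]
    return FragmentSet.from_arrays(chroms, starts, ends)
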
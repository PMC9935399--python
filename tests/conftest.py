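import numpy as np
import pandas as pd
import pytest

from enhancerkit.core import ChromSizes, TssRecord
from enhancerkit.simulate import SyntheticConfig, plant_enhancers, simulate_bundle
from enhancerkit.tags import build_tag_directory


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_directory(records, sizes, cap=2, assay="chip", condition="treated",
                   replicate="rep1", **kwargs):
    """Build a TagDirectory from an iterable of (chrom, pos, strand)."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(
        list(records), columns=["chrom", "position", "strand"]
    )
    return build_tag_directory(df, assay, condition, replicate, cap, sizes, **kwargs)


def random_tags(rng, sizes, n, chroms=None):
    """Uniform random tag records over the genome."""
    chroms = chroms or sorted(sizes)
    lengths = np.array([sizes[c] for c in chroms], dtype=float)
    idx = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[idx]).astype(np.int64)
    return pd.DataFrame(
        {
            "chrom": [chroms[i] for i in idx],
            "position": pos,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
        }
    )


@pytest.fixture
def tss_set():
    return [
        TssRecord("g1", "chr1", 100_000, "+", 120_000),
        TssRecord("g2", "chr1", 400_000, "-", 380_000),
        TssRecord("g3", "chr2", 50_000, "+", 80_000),
    ]


# Scaled-down synthetic configuration for fast integration-style tests.
# Small libraries make the printed thresholds unreliable, so tests using this
# fixture exercise mechanics (determinism, file round-trips, pipeline wiring),
# not recovery rates.
SMALL_SYNTH = dict(
    genome={"chrS": 2_000_000},
    n_genes=8,
    n_megatrans=6,
    n_eralpha_other=6,
    n_other_active=5,
    n_decoy_tss=1,
    n_decoy_k27ac=1,
    n_decoy_nascent=1,
    k27ac_mass=1500.0,
    band_base_mass=600.0,
    gene_nascent_mass=4000.0,
    gene_polii_mass=2000.0,
    n_genes_up=1,
    n_genes_down=1,
)


@pytest.fixture
def small_config():
    return SyntheticConfig(**SMALL_SYNTH, seed=7)


@pytest.fixture(scope="session")
def default_truth_bundle():
    """One full-scale synthetic dataset shared across the session."""
    cfg = SyntheticConfig(seed=11)
    truth = plant_enhancers(cfg)
    bundle, _records = simulate_bundle(truth, cfg)
    return cfg, truth, bundle
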
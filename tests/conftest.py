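import numpy as np
import pandas as pd
import pytest

from tssmap.genome_io import Genome, GeneModel
from tssmap.synthetic_data import SynthConfig, plant_features, simulate_read_starts


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A compact synthetic genome: one replicon, all six classes planted."""
    return SynthConfig(
        n_replicons=1,
        n_genes=40,
        n_mtss=8,
        n_lmtss=4,
        n_pmtss=4,
        n_setss=6,
        n_astss=6,
        n_stss=4,
        jitter_rate=0.0,
        background_noise_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    genome, truth = plant_features(small_config)
    reads = simulate_read_starts(genome, truth, small_config)
    return genome, truth, reads


@pytest.fixture
def toy_genome() -> Genome:
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return Genome({"chr": seq})


def mirror_genome(genome: Genome) -> Genome:
    """Reverse-complement every replicon (coordinates mirror to L - pos + 1)."""
    from tssmap.genome_io import revcomp

    return Genome({r: revcomp(s) for r, s in genome.replicons.items()},
                  dict(genome.circular))


def mirror_pos(pos: int, length: int) -> int:
    return length - pos + 1


def mirror_reads(reads: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    out = reads.copy()
    lengths = out["replicon"].map({r: len(s) for r, s in genome.replicons.items()})
    out["five_prime_pos"] = lengths - out["five_prime_pos"] + 1
    out["strand"] = out["strand"].map({"+": "-", "-": "+"})
    return out


def mirror_genes(genes, genome: Genome):
    out = []
    for g in genes:
        L = genome.length(g.replicon)
        out.append(
            GeneModel(
                id=g.id,
                replicon=g.replicon,
                strand="-" if g.strand == "+" else "+",
                start_codon_pos=mirror_pos(g.start_codon_pos, L),
                stop_codon_pos=mirror_pos(g.stop_codon_pos, L),
            )
        )
    return out
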
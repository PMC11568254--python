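import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rbmrecomb import Genome, GeneRecord, SimConfig, generate_population

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_genome(genome_id: str, gene_seqs, spacer: str = "TTTTTTTTTT") -> Genome:
    """Assemble a toy single-contig genome from explicit gene sequences."""
    parts, genes, pos = [], [], 0
    for i, seq in enumerate(gene_seqs):
        parts.append(seq)
        genes.append(GeneRecord(f"g{i + 1:03d}", "c1", pos, pos + len(seq), "+", seq))
        pos += len(seq)
        if i < len(gene_seqs) - 1:
            parts.append(spacer)
            pos += len(spacer)
    return Genome(genome_id, [("c1", "".join(parts))], genes)


def random_gene(rng: np.random.Generator, length: int = 300) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_population():
    """A compact no-recombination population: ancestor + 4 daughters at each
    of two target ANI values (98.0 and 99.5), 150 genes of ~300 bp."""
    cfg = SimConfig(
        n_genes=150, gene_len_mu=300, gene_len_sd=60, min_gene_len=100,
        daughters_per_ani=4, ani_low=97.99, ani_high=98.0, ani_step=0.01,
        seed=42,
    )
    # two grid points is awkward with one (low, high] range at different ANIs;
    # build the second target by a separate config sharing the ancestor seed
    pop_98 = generate_population(cfg)
    cfg2 = SimConfig(
        n_genes=150, gene_len_mu=300, gene_len_sd=60, min_gene_len=100,
        daughters_per_ani=4, ani_low=99.49, ani_high=99.5, ani_step=0.01,
        seed=42,
    )
    pop_995 = generate_population(cfg2)
    genomes = pop_98.genomes + [g for g in pop_995.genomes if g.genome_id != "ancestor"]
    # ancestors of both runs are identical (same seed/layout); daughters of the
    # second run are renamed to keep ids unique
    assert pop_98.genomes[0].contigs == pop_995.genomes[0].contigs
    return {"genomes": genomes, "truth_98": pop_98.truth, "truth_995": pop_995.truth,
            "config": cfg}
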
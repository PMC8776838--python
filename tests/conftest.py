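import os

import pytest

from sidescan import io
from sidescan.simulate import SimConfig, SimGenome, gen_genome


def write_annotations(genome: SimGenome, directory: str) -> tuple[str, str]:
    """Write a simulated genome's GFF3 + domtblout; return the paths."""
    gff = os.path.join(directory, f"{genome.genome_id}.gff3")
    dom = os.path.join(directory, f"{genome.genome_id}.domtblout")
    io.write_gff3(gff, genome.genes)
    io.write_domtblout(dom, genome.domain_hits)
    return gff, dom


@pytest.fixture
def sim_genome() -> SimGenome:
    """A genome with the default planted petrobactin-like cluster."""
    return gen_genome(SimConfig(seed=11), genome_id="G11")


@pytest.fixture
def annotated_genome(sim_genome, tmp_path):
    gff, dom = write_annotations(sim_genome, str(tmp_path))
    return sim_genome, gff, dom
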
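import numpy as np
import pytest

from pairmotif.config import RunConfig
from pairmotif.motifs import Background, Motif
from pairmotif.scan import Hit


@pytest.fixture
def uniform_bg() -> Background:
    return Background.uniform()


@pytest.fixture
def default_config() -> RunConfig:
    return RunConfig()


def make_hit(start: int, pvalue: float, width: int = 5, strand: str = "+",
             motif_id: str = "m", gene_id: str = "g") -> Hit:
    return Hit(
        motif_id=motif_id,
        gene_id=gene_id,
        start=start,
        end=start + width,
        strand=strand,
        score=0.0,
        pvalue=pvalue,
    )


def random_probability_motif(motif_id: str, width: int,
                             rng: np.random.Generator) -> Motif:
    """A motif with Dirichlet(1,1,1,1) columns (no structure imposed)."""
    return Motif(motif_id, rng.dirichlet(np.ones(4), size=width))
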
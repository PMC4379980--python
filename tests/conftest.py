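import numpy as np
import pytest

from ltrkit.io import SequenceRecord, bundled_domain_proteins, bundled_trna_oligos
from ltrkit.simulate import (
    ElementTemplateSpec,
    build_template,
    plant_elements,
    random_dna,
)


@pytest.fixture(scope="session")
def trna_oligos():
    return bundled_trna_oligos()


@pytest.fixture(scope="session")
def domain_library():
    return bundled_domain_proteins()


@pytest.fixture(scope="session")
def single_element_world():
    """A 50-kb contig with one planted identical-LTR element and its truth."""
    rng = np.random.default_rng(42)
    spec = ElementTemplateSpec(family_id="famA", superfamily="Copia", ltr_len=400)
    template = build_template(spec, rng)
    background = random_dna(rng, 50_000)
    genome, manifest = plant_elements(
        background, [template], 1, 0, {"famA": 0.0}, 3.6e-9, rng, min_spacing=20_000
    )
    return SequenceRecord("contig1", genome), manifest, template
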
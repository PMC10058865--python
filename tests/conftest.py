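import numpy as np
import pytest

from repeatome import annotate as ann
from repeatome import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def library():
    return ann.default_domain_library()


@pytest.fixture(scope="session")
def planted():
    """One small genome with two planted families, reused across modules.

    Intact TSDs and termini (ages are low and the preserve switches are on)
    so detector and annotator tests can assert exact recovery.
    """
    rng = np.random.default_rng(7)
    fams = []
    for sf, lin, peak in (("Copia", "SIRE", 0.5), ("Gypsy", "Tekay", 1.5)):
        spec = syn.ElementSpec(sf, lin, ltr_len=500, internal_len=2600)
        fams.append(syn.RepeatFamily(f"{sf}_{lin}", spec, 5,
                                     syn.AgeDistribution.gaussian(peak, 0.1)))
    recipe = syn.SimRecipe(genome_length=300_000, families=fams,
                           mutate_tsd=False, preserve_motif=True)
    genome, truth = syn.plant_elements(recipe, rng)
    return genome, truth, recipe
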
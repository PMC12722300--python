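import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from tcellkit.repertoire import CellReceptor

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cell(cell_id, beta="TGTGCA", alphas=("TGCATT",), donor="D1",
              timepoint="single", subset="conventional"):
    """Receptor with nt junctions; aa strings derived as placeholders."""
    return CellReceptor(
        cell_id=cell_id, donor_id=donor, timepoint=timepoint,
        tra_nt=tuple(alphas), tra_aa=tuple("A" * (len(a) // 3)
                                           for a in alphas),
        trb_nt=(beta,) if beta else (),
        trb_aa=("C" * (len(beta) // 3),) if beta else (),
        subset=subset)


@pytest.fixture
def small_cohort():
    from tcellkit.simulate import CohortSpec, gen_cohort
    return gen_cohort(CohortSpec(n_healthy=4, n_t1d=5, seed=7))
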
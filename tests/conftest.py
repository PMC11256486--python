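import logging

import pytest

from tmtserum import RunConfig, StudyDesign, generate_study, run_pipeline
from tmtserum.synthetic import generate_annotations

logging.getLogger("tmtserum").setLevel(logging.ERROR)

#: Desk-scale study: same layout as the full cohort (30 patients, 3 plexes)
#: with fewer proteins so a pipeline run stays well under a second.
SMALL_KW = dict(n_proteins=120, peptides_per_protein=(1, 6),
                psms_per_peptide=(1, 2))


@pytest.fixture(scope="session")
def small_study():
    design = StudyDesign(rng_seed=11, **SMALL_KW)
    psm, meta, truth = generate_study(design)
    return design, psm, meta, truth


@pytest.fixture(scope="session")
def small_result(small_study):
    _, psm, meta, truth = small_study
    terms = generate_annotations(truth, rng_seed=11)
    return run_pipeline(RunConfig(), psm, meta, annotations=terms)
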
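import pytest

from vdjwell.annotate import TableBackend
from vdjwell.pipeline import process_run, score_run
from vdjwell.sim import generate_clone, generate_run


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One plate, 4 parents x 3 biological replicates, aberrant light chain
    spiked into 60% of samples, low substitution error rate."""
    outdir = tmp_path_factory.mktemp("small_run")
    aberrant = generate_clone(seed=999)
    design = {f"P/{i + 1}": 3 for i in range(4)}
    truth = generate_run(
        outdir,
        design,
        n_plates=1,
        aberrant_chain=aberrant,
        aberrant_prevalence=0.6,
        seed=11,
        reads_per_well=200,
        error_rate=0.002,
    )
    return truth


@pytest.fixture(scope="session")
def small_result(small_run):
    backend = TableBackend.from_clones(small_run.clones.values())
    return score_run(process_run(small_run.outdir, backend))


@pytest.fixture()
def clone_pair():
    return generate_clone(seed=1)
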
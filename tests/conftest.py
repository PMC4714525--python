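import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from m6akit import SimulationParams
from m6akit.pipeline import run_simulation
from m6akit.simulate import RRACH_5MERS

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_exp():
    """The default desk-scale preset: 500 transcripts, 3 organs x 2
    replicates, 2e5 fragments per library."""
    return run_simulation(SimulationParams(seed=7))


@pytest.fixture(scope="session")
def null_two_organ_exp():
    """No planted organ effects at all: the differential null."""
    params = SimulationParams(
        n_transcripts=300, depth=100_000, organs=("leaves", "roots"),
        replicates=1, dm_fraction=0.0, de_fraction=0.0, te_fraction=0.0,
        seed=11,
    )
    return run_simulation(params)


@pytest.fixture(scope="session")
def dm_recovery_exp():
    """Planted 4-fold NFPKM differences in 10% of transcripts.

    Background capture is off so the covered length equals the site footprint
    in both organs and the planted methylation fold passes through to NFPKM
    unchanged (with background on, signal-dependent covered-length growth
    compresses the realized fold well below the planted one).
    """
    params = SimulationParams(
        n_transcripts=400, depth=150_000, organs=("leaves", "flowers"),
        replicates=1, dm_fraction=0.10, dm_fold=4.0, de_fraction=0.0,
        te_fraction=0.0, p_nonspecific=0.0, seed=31,
    )
    return run_simulation(params)


@pytest.fixture(scope="session")
def stop_anchored_exp():
    """All sites at the stop codon / proximal 3'UTR."""
    params = SimulationParams(
        n_transcripts=200, depth=50_000, organs=("leaves",), replicates=1,
        placement_mass={"stop": 1.0, "cds": 0.0, "five_prime": 0.0},
        te_fraction=0.0, seed=3,
    )
    return run_simulation(params, assays=("m6A",))


@pytest.fixture(scope="session")
def uniform_coverage_exp():
    """Uniform-coverage control: padded fragmentation, mRNA assay only."""
    params = SimulationParams(
        n_transcripts=200, depth=100_000, organs=("leaves",), replicates=1,
        te_fraction=0.0, edge_model="padded", seed=13,
    )
    return run_simulation(params, assays=("mRNA",))


@pytest.fixture(scope="session")
def motif_exp():
    """Motif-recovery design: one site per transcript (one planted instance
    per peak), AAACT planted at 40%, remaining consensus 5-mers uniform,
    background capture off."""
    freqs = {m: 0.6 / 11 for m in RRACH_5MERS if m != "AAACT"}
    freqs["AAACT"] = 0.4
    params = SimulationParams(
        n_transcripts=600, depth=120_000, organs=("leaves",), replicates=1,
        te_fraction=0.0, p_nonspecific=0.0, motif_freqs=freqs,
        sites_probs={1: 1.0}, seed=5,
    )
    return run_simulation(params, assays=("m6A",))
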
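import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from binmeth.dmr import call_dmr_pipeline
from binmeth.simulate import (
    SimConfig,
    simulate_genome,
    simulate_methylome,
    simulate_srna_library,
)
from binmeth.srna import call_dsrs

ACCEPTANCE_SEED = 20240901


@pytest.fixture(scope="session")
def small_truth():
    """A quick 300 kb truth set for unit tests."""
    return simulate_genome(
        SimConfig(genome_size=300_000, n_rddm_loci=30, n_het_loci=10, n_genes=20, seed=7)
    )


@pytest.fixture(scope="session")
def default_truth():
    """The full desk-scale config used for acceptance: 2 Mb, 200 RdDM loci."""
    return simulate_genome(SimConfig(seed=ACCEPTANCE_SEED))


@pytest.fixture(scope="session")
def default_run(default_truth):
    """One full-scale simulation and all caller outputs shared by the
    acceptance tests: WT vs pkl / nrpd1 / nrpe1 plus a WT-vs-WT replicate
    null, for both methylation and 24-nt siRNA data."""
    truth = default_truth
    meth = {
        "WT": simulate_methylome(truth, "WT", seed=0),
        "WT2": simulate_methylome(truth, "WT", seed=99),
        "pkl": simulate_methylome(truth, "pkl", seed=1),
        "nrpd1": simulate_methylome(truth, "nrpd1", seed=2),
        "nrpe1": simulate_methylome(truth, "nrpe1", seed=3),
    }
    dmr_runs = {}
    for name in ("pkl", "nrpd1", "nrpe1", "WT2"):
        tested, dmrs = call_dmr_pipeline(meth["WT"], meth[name], truth.genome)
        dmr_runs[name] = {"bins": tested, "dmrs": dmrs}
    srna = {}
    for i, name in enumerate(("WT", "pkl", "nrpd1")):
        bins, total = simulate_srna_library(truth, name, seed=i)
        srna[name] = (bins, total)
    srna["WT2"] = simulate_srna_library(truth, "WT", seed=98)
    dsr_runs = {}
    for name in ("pkl", "nrpd1", "WT2"):
        tested, dsrs = call_dsrs(
            srna["WT"][0], srna[name][0], srna["WT"][1], srna[name][1]
        )
        dsr_runs[name] = {"bins": tested, "dsrs": dsrs}
    return {
        "truth": truth,
        "meth": meth,
        "dmr": dmr_runs,
        "srna": srna,
        "dsr": dsr_runs,
    }
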
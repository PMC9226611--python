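import time

import pytest

from tnscreen.pipeline import RunConfig, run
from tnscreen.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A compact but complete simulated study: 2 replicons, 120 genes,
    2 replicates of 60k reads.  Reused by mapping/tabulation/pipeline tests."""
    cfg = SimConfig(seed=11, replicon_lengths=(120_000, 15_000), n_genes=120,
                    reads_per_replicate=60_000, n_replicates=2)
    return simulate_all(cfg, tmp_path_factory.mktemp("smallsim"))


@pytest.fixture(scope="session")
def small_run(small_sim, tmp_path_factory):
    """Full pipeline run over the small simulated study (one condition)."""
    out = tmp_path_factory.mktemp("smallrun")
    rc = RunConfig(
        genome_path=str(small_sim.paths["fasta"]),
        annotation_path=str(small_sim.paths["gff"]),
        conditions={"parent": [str(p) for p in small_sim.paths["fastqs"]]},
        outdir=str(out), log_level="WARNING")
    return run(rc)


@pytest.fixture(scope="session")
def default_scale_run(tmp_path_factory):
    """End-to-end run at the generator's default study conditions:
    ~4.4 Mb genome, 4,000 genes, 3 replicates of 2x10^6 reads.

    Returns (simulation result, pipeline result, elapsed seconds).  The bulky
    FASTQ files are deleted once the pipeline has consumed them.
    """
    base = tmp_path_factory.mktemp("fullscale")
    t0 = time.time()
    cfg = SimConfig(seed=1)
    res = simulate_all(cfg, base / "sim")
    rc = RunConfig(
        genome_path=str(res.paths["fasta"]),
        annotation_path=str(res.paths["gff"]),
        conditions={"parent": [str(p) for p in res.paths["fastqs"]]},
        outdir=str(base / "out"), log_level="WARNING")
    rr = run(rc)
    elapsed = time.time() - t0
    for p in res.paths["fastqs"]:
        p.unlink()
    return res, rr, elapsed
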
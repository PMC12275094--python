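import numpy as np
import pytest

from chiapet_loops import (
    AlignedTag,
    PipelineParams,
    RunConfig,
    SimulationConfig,
    run_all,
    simulate_genome,
    simulate_library,
    write_library,
)
from chiapet_loops.align import RawPET
from chiapet_loops.classify import classify


def make_pet(chrom, p1, p2, s1="+", s2="-", span=50, read_id="r",
             params=PipelineParams()):
    """Classified PET from bare coordinates (tags canonically ordered)."""
    t1 = AlignedTag(read_id, chrom, p1, s1, span)
    t2 = AlignedTag(read_id, chrom, p2, s2, span)
    if (t1.chrom, t1.pos5) > (t2.chrom, t2.pos5):
        t1, t2 = t2, t1
    return classify(RawPET(t1, t2), params)


def make_raw_pet(c1, p1, s1, c2, p2, s2, read_id="r", span=50):
    t1 = AlignedTag(read_id, c1, p1, s1, span)
    t2 = AlignedTag(read_id, c2, p2, s2, span)
    if (t1.chrom, t1.pos5) > (t2.chrom, t2.pos5):
        t1, t2 = t2, t1
    return RawPET(t1, t2)


NOISELESS = dict(
    n_loops=10,
    pets_per_loop_mean=6.0,
    pets_per_loop_dispersion=0.0,
    self_ligation_fraction=0.0,
    trans_noise_fraction=0.0,
    random_intra_noise_fraction=0.0,
    duplicate_rate=0.0,
    error_rate=0.0,
    one_sided_fraction=0.0,
    peak_fraction=1.0,
)


def simulate_to_dir(out_dir, seed=1, **overrides):
    config = SimulationConfig(seed=seed, **overrides)
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    reads1, reads2, truth = simulate_library(config, genome, rng)
    paths = write_library(str(out_dir), genome, reads1, reads2, truth)
    return config, genome, truth, paths


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """10 loops x 6 PETs on a 2x1-Mb genome, no noise, pushed through run_all."""
    base = tmp_path_factory.mktemp("noiseless")
    config, genome, truth, paths = simulate_to_dir(base, seed=1, **NOISELESS)
    result = run_all(
        RunConfig(
            fq1=paths["fq1"],
            fq2=paths["fq2"],
            out_dir=str(base / "out"),
            genome_fasta=paths["genome"],
            peaks_bed=paths["truth_peaks"],
        )
    )
    return {"config": config, "truth": truth, "paths": paths, "result": result}


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory):
    """Default study conditions: noise, duplicates, one-sided linker reads."""
    base = tmp_path_factory.mktemp("noisy")
    config, genome, truth, paths = simulate_to_dir(base, seed=11)
    result = run_all(
        RunConfig(
            fq1=paths["fq1"],
            fq2=paths["fq2"],
            out_dir=str(base / "out"),
            genome_fasta=paths["genome"],
            peaks_bed=paths["truth_peaks"],
        )
    )
    return {"config": config, "truth": truth, "paths": paths, "result": result}
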
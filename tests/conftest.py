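"""Shared fixtures: one small simulated dataset plus a full pipeline run.

All fixtures are generated programmatically at test time; nothing is read
from checked-in data files.
"""

from __future__ import annotations

import pytest

from ervscan.consensus import default_library
from ervscan.pipeline import PipelineConfig, run_pipeline
from ervscan.simulate import SimulationConfig, simulate

SMALL_CONFIG = dict(
    seed=3, ancestor_length_bp=1_000_000, n_chromosomes=1,
    n_full_length=4, n_solo_ltr=4, n_truncated=2, n_ncpi=2,
    n_decoy_shared=1, n_outgroups=2, outgroup_divergence=0.01,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def small_dataset():
    return simulate(SimulationConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_run(small_dataset, tmp_path_factory):
    """The small dataset written to disk and pushed through the pipeline."""
    root = tmp_path_factory.mktemp("small_run")
    paths = small_dataset.write(root / "sim")
    config = PipelineConfig(
        genome=str(paths["ingroup"]),
        outgroups=[str(paths["outgroup_1"]), str(paths["outgroup_2"])],
        repeats_out=str(paths["out"]),
        library_dir=str(paths["library"]),
        outdir=str(root / "run"),
    )
    result = run_pipeline(config)
    return small_dataset, result, config


@pytest.fixture()
def locus_by_truth_span(small_run):
    """Map (chrom, start, end) -> detected locus for truth comparisons."""
    _, result, _ = small_run
    return {(l.chrom, l.start, l.end): l for l in result.loci}
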
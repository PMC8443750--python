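"""Shared fixtures: the simulated mock virome used across test modules."""
from __future__ import annotations

from pathlib import Path

import pytest

from termivore import RunConfig, run_pipeline
from termivore.virome_simulator import build_mock_virome, default_mock_specs

MOCK_SEED = 1
MOCK_READ_PAIRS = 20_000
MOCK_GENOME_LEN = 40_000


@pytest.fixture(scope="session")
def mock_virome(tmp_path_factory) -> dict:
    """Five-phage mock virome at full study scale, simulated once per session.

    2e4 read pairs per phage on 40 kb genomes (~75x mean coverage), no
    sequencing error: the reference panel of packaging mechanisms.
    """
    out = tmp_path_factory.mktemp("mock_virome")
    specs = default_mock_specs(n_read_pairs=MOCK_READ_PAIRS,
                               genome_len=MOCK_GENOME_LEN, seed=MOCK_SEED)
    paths = build_mock_virome(specs, out / "mock", seed=MOCK_SEED)
    truth = {s.name: s for s in specs}
    return {"paths": paths, "specs": truth, "out": out}


@pytest.fixture(scope="session")
def mock_virome_run(mock_virome) -> dict:
    """Pipeline results on the session mock virome."""
    paths = mock_virome["paths"]
    cfg = RunConfig(fasta=paths["fasta"], fastq_r1=paths["r1"],
                    fastq_r2=paths["r2"],
                    out_dir=mock_virome["out"] / "run",
                    run_seed=MOCK_SEED)
    summary = run_pipeline(cfg)
    return {**mock_virome, "summary": summary, "config": cfg}


@pytest.fixture()
def tiny_fasta(tmp_path) -> Path:
    path = tmp_path / "tiny.fasta"
    path.write_text(">c1 first contig\nACGTACGTAC\nGTACGT\n>c2\nNNNNACGT\n")
    return path
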
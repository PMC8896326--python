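"""Shared fixtures: one synthetic dataset and one pipeline run per session."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pytest

from lnclact.pipeline import PipelineConfig, run_all
from lnclact.simulate import SimulationConfig, simulate, write_dataset


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic dataset (seed 7) used across test modules."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def dataset_dir(dataset, tmp_path_factory) -> dict[str, Path]:
    """The same dataset written to disk; returns the path map."""
    outdir = tmp_path_factory.mktemp("dataset")
    return write_dataset(dataset, outdir)


def make_pipeline_config(paths: dict[str, Path], outdir: Path, **overrides) -> PipelineConfig:
    cfg = PipelineConfig(
        reference_gtf=str(paths["reference_gtf"]),
        assembled_gtf=str(paths["assembled_gtf"]),
        transcripts_fasta=str(paths["transcripts_fasta"]),
        training_coding_fasta=str(paths["training_coding_fasta"]),
        training_noncoding_fasta=str(paths["training_noncoding_fasta"]),
        expression_tsv=str(paths["expression_tsv"]),
        design_tsv=str(paths["design_tsv"]),
        ct_tsv=str(paths["ct_tsv"]),
        panel_txt=str(paths["panel_txt"]),
        gene_sets_gmt=str(paths["gene_sets_gmt"]),
        outdir=str(outdir),
    )
    return dataclasses.replace(cfg, **overrides)


@pytest.fixture(scope="session")
def pipeline_run(dataset_dir, tmp_path_factory):
    """One full pipeline run on the session dataset: (config, manifest)."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    cfg = make_pipeline_config(dataset_dir, outdir)
    manifest = run_all(cfg)
    return cfg, manifest
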
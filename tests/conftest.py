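"""Shared fixtures: one synthetic genome/annotation/catalog bundle per session."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from sorfkit.annotation import load_annotation
from sorfkit.fixtures import (
    FixtureConfig,
    FixtureManifest,
    make_catalogs,
    make_genome_and_annotation,
)
from sorfkit.pipeline import PipelineConfig, SourceConfig, run_pipeline


@dataclass
class Bundle:
    seed: int
    dir: Path
    fasta: Path
    gtf: Path
    manifest: FixtureManifest
    source_paths: dict


def build_bundle(seed: int, root: Path, n_sources: int = 3, redundancy: int = 2,
                 config: FixtureConfig | None = None, **catalog_kwargs) -> Bundle:
    out = root / f"fx_seed{seed}"
    fasta, gtf, manifest = make_genome_and_annotation(seed, config or FixtureConfig(), out)
    paths = make_catalogs(seed, manifest, out, n_sources=n_sources,
                          redundancy=redundancy, **catalog_kwargs)
    return Bundle(seed=seed, dir=out, fasta=fasta, gtf=gtf,
                  manifest=manifest, source_paths=paths)


def pipeline_config(bundle: Bundle, out_name: str = "run") -> PipelineConfig:
    n = len([k for k in bundle.source_paths if k.endswith(".csv") or
             (k.startswith("source") and not k.endswith("_chain") and k != "cell_type_map")])
    sources = [
        SourceConfig(f"source{i}", bundle.dir / f"source{i}.csv",
                     bundle.dir / f"source{i}.chain")
        for i in range(1, n + 1)
    ]
    return PipelineConfig(
        sources=sources, annotation=bundle.gtf, genome=bundle.fasta,
        out_dir=bundle.dir / out_name, cell_type_map=bundle.source_paths["cell_type_map"],
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> Bundle:
    """Seed-1 uncorrupted fixture bundle, shared read-only across tests."""
    return build_bundle(1, tmp_path_factory.mktemp("fixtures"))


@pytest.fixture(scope="session")
def transcript_models(bundle):
    return load_annotation(bundle.gtf, bundle.fasta)


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    return run_pipeline(pipeline_config(bundle))
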
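"""Shared fixtures: one default synthetic genome per session, plus a
completed pipeline run over it."""

from __future__ import annotations

import pytest

from rgenescape.pipeline import RunConfig, run_all
from rgenescape.synthetic import SyntheticConfig, make_genome


SMALL_CONFIG_KWARGS = dict(
    n_chroms=1,
    chrom_len=1_800_000,
    n_genes=30,
    n_rgenes_per_category=1,
    n_het_svs=10,
    n_hom_svs=4,
    ase_effect_genes=5,
    seed=7,
)


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The default-condition synthetic diploid genome with planted truth."""
    out = tmp_path_factory.mktemp("default_fixture")
    return make_genome(SyntheticConfig(seed=0), out)


@pytest.fixture(scope="session")
def pipeline_run(default_fixture, tmp_path_factory):
    """A full pipeline run over the default fixture."""
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = RunConfig(
        input_dir=str(default_fixture.out_dir),
        out_dir=str(out),
        seed=0,
        genes_b_gff="assemblyB_genes.gff3",
        proteins_b_fasta="assemblyB_proteins.faa",
        domains_b_tsv="assemblyB_domains.tsv",
        ortholog_map_tsv="ortholog_map.tsv",
    )
    report = run_all(cfg)
    return cfg, report
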
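"""Shared fixtures: a seeded synthetic mini-genome and loaded gene models."""

from __future__ import annotations

import pytest

from crisprdesign.fixtures import FixtureSpec, make_mini_genome
from crisprdesign.genome_io import parse_fasta, parse_gff3


@pytest.fixture(scope="session")
def mini(tmp_path_factory):
    """Default mini-genome: 1 contig, 60 kb, 5 genes, one planted duplicate."""
    out = tmp_path_factory.mktemp("fix")
    return make_mini_genome(FixtureSpec(seed=42, planted_duplicates=1), out)


@pytest.fixture(scope="session")
def assembly(mini):
    return parse_fasta(mini.fasta)


@pytest.fixture(scope="session")
def genes(mini, assembly):
    return {g.gene_id: g for g in parse_gff3(mini.gff3, assembly)}
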
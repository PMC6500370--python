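"""Shared fixtures: tiny on-disk matrices and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from methylpred.simulate import GeneratorConfig, generate_dataset

EXPR_TSV = """\
gene_id\tS1\tS2\tS3\tS4
GENE1\t1.0\t2.0\t3.0\t4.0
GENE2\t2.5\t2.5\t2.0\t1.0
GENE3\t0.0\t-1.0\t1.0\t0.5
"""

METH_TSV = """\
probe_id\tS1\tS2\tS3\tS4
cg0001\t0.10\t0.20\t0.30\t0.40
cg0002\t0.90\tNA\t0.70\t0.60
cg0003\t0.50\t0.55\tNA\t0.45
"""

SERIES_MATRIX = """\
!Series_title\t"toy"
!Series_geo_accession\t"GSE00000"
!Sample_title\t"a"\t"b"\t"c"\t"d"
!Series_platform_id\t"GPL570"
!series_matrix_table_begin
"ID_REF"\t"S1"\t"S2"\t"S3"\t"S4"
"GENE1"\t1.0\t2.0\t3.0\t4.0
"GENE2"\t2.5\t2.5\t2.0\t1.0
"GENE3"\t0.0\t-1.0\t1.0\t0.5
!series_matrix_table_end
"""

ANNOTATION_TSV = """\
probe_id\tUCSC_RefGene_Name\tUCSC_RefGene_Group
cg0001\tGENE1;GENE1\tTSS200;Body
cg0002\tGENE1\tBody
cg0003\tGENE2;GENE3\t5'UTR;3'UTR
cg0004\t\t
"""


@pytest.fixture
def expr_path(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(EXPR_TSV)
    return path


@pytest.fixture
def meth_path(tmp_path):
    path = tmp_path / "meth.tsv"
    path.write_text(METH_TSV)
    return path


@pytest.fixture
def series_matrix_path(tmp_path):
    path = tmp_path / "series.txt"
    path.write_text(SERIES_MATRIX)
    return path


@pytest.fixture
def annotation_path(tmp_path):
    path = tmp_path / "annotation.tsv"
    path.write_text(ANNOTATION_TSV)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample, 25-gene M-value cohort with mixed planted effects."""
    cfg = GeneratorConfig(
        n_samples=60,
        n_genes=25,
        probes_per_gene=(3, 12),
        scale="m",
        target_r2=((0.4, 0.0), (0.6, ("uniform", 0.2, 0.7))),
        missing_rate=0.0,
        seed=101,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
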
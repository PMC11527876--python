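import pytest

from neosexscan import simdata

#: gene used by the exon-loss fixture
EXON_GENE = "gene_00000"

#: trimmed alignment of 147 codons (441 nt); the inland W gametolog lost a
#: 91-codon (273 nt) terminal exon and both lineages' Z gametologs share a
#: 16-codon internal gap, mirroring a documented neo-sex gene structure
EXON_LOSS_DELETIONS = [
    (EXON_GENE, "W-inland", 56, 91),
    (EXON_GENE, "Z-coastal", 30, 16),
    (EXON_GENE, "Z-inland", 30, 16),
]


@pytest.fixture(scope="session")
def exon_loss_alignment():
    cfg = simdata.SimConfig(seed=42, n_genes=1, n_codons=147, nmt_fraction=1.0,
                            deletion_spec=EXON_LOSS_DELETIONS)
    alignments, og_table, fn_table, truth = simdata.simulate_gametolog_alignments(cfg)
    return alignments["og_00000"], truth


@pytest.fixture(scope="session")
def default_gene_cohort():
    """One default-parameter gene cohort (300 genes) shared across tests."""
    cfg = simdata.SimConfig(seed=5)
    return simdata.simulate_gametolog_alignments(cfg)


@pytest.fixture(scope="session")
def default_scaffold_cohort():
    cfg = simdata.SimConfig(seed=5)
    return simdata.simulate_scaffold_tables(cfg)
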
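import pytest
from hypothesis import HealthCheck, settings

from nlrkit.io import AnnotationTable, DomainHit, ProteinRecord
from nlrkit.roles import DomainRoleConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def roles() -> DomainRoleConfig:
    return DomainRoleConfig.default()


def build_table(hits_by_protein, species="Testus exampleus", sequences=None, genes=None):
    """Assemble an AnnotationTable from {protein_id: [accessions]}.

    ``hits_by_protein`` may map to a list of InterPro accessions (empty
    string for unintegrated signature-level hits); per-protein sequences
    and gene ids are optional.
    """
    table = AnnotationTable()
    for pid, accs in hits_by_protein.items():
        seq = (sequences or {}).get(pid)
        gene = (genes or {}).get(pid, "")
        table.add_protein(ProteinRecord(pid, species, gene_id=gene, sequence=seq))
        for i, acc in enumerate(accs):
            table.add_hit(
                DomainHit(pid, acc, f"SIG:{acc or 'none'}:{i}", 10 * i + 1, 10 * i + 50)
            )
    return table
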
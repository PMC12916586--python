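import pytest

from hlacc import table_fixtures
from hlacc.io import CohortTable, GenotypeRecord
from hlacc.nomenclature import parse_allele


@pytest.fixture(scope="session")
def fixtures():
    """Reconstructed reference count tables for all seven loci."""
    return table_fixtures()


def make_cohort(rows, loci, group="case"):
    """Build a CohortTable from [(sample_id, {locus: (a1, a2) | None}), ...]
    with allele strings."""
    records = []
    for sample_id, genotype in rows:
        parsed = {
            locus: None if pair is None else (parse_allele(pair[0]), parse_allele(pair[1]))
            for locus, pair in genotype.items()
        }
        records.append(GenotypeRecord(sample_id, group, parsed))
    return CohortTable(records, tuple(loci), group)
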
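import pytest
from hypothesis import settings

import preyspectra as ps

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from preyspectra.events import PREDATOR_SPECIES

#: representative taxon per prey group, used to build small tables by hand
GROUP_TAXON = {
    "gastropod": "Olivella semistriata",
    "bivalve": "Donax sp.",
    "crustacean": "Emerita sp.",
    "conspecific": PREDATOR_SPECIES,
}


def make_table(rows, provenance="test"):
    """Build an EventTable from (group, predator_mm, prey_mm) triples."""
    return ps.EventTable.from_events(
        [
            ps.PredationEvent(
                prey_group=g,
                prey_taxon=GROUP_TAXON[g],
                predator_length_mm=pred,
                prey_length_mm=prey,
                location="Playa Grande",
            )
            for g, pred, prey in rows
        ],
        provenance=provenance,
    )


def table_with_group_counts(n_by_group, predator_mm=30.0, prey_mm=10.0):
    """Table with the requested number of events per prey group."""
    rows = []
    for group, n in n_by_group.items():
        rows.extend([(group, predator_mm, prey_mm)] * n)
    return make_table(rows)


@pytest.fixture(scope="session")
def default_table():
    """One default synthetic table shared by read-only tests."""
    table, _ = ps.generate_events(ps.GeneratorConfig(seed=1))
    return table


@pytest.fixture(scope="session")
def default_report():
    _, report = ps.generate_events(ps.GeneratorConfig(seed=1))
    return report
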
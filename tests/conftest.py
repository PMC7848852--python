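import networkx as nx
import pytest

from lipidpath.reaction_db import default_database
from lipidpath.stats import ConditionDesign


@pytest.fixture(scope="session")
def db():
    return default_database()


@pytest.fixture()
def design_4v4():
    """Unpaired 4-vs-4 design with treated1..4 / control1..4 samples."""
    assignment = {f"treated{i}": "treated" for i in range(1, 5)}
    assignment.update({f"control{i}": "control" for i in range(1, 5)})
    return ConditionDesign(
        condition_of_interest="treated", control="control",
        sample_assignment=assignment,
    )


def scored_graph(edges, level="subclass", network_type="lipid", alpha=0.05):
    """Build a scored network directly from (u, v, reaction_id, z) tuples."""
    from lipidpath.stats import status_of
    from scipy.stats import norm

    G = nx.DiGraph(level=level, type=network_type, alpha=alpha)
    for u, v, rid, z in edges:
        G.add_edge(
            u, v, reaction=rid, kind="headgroup_transfer", genes=[],
            species_pairs=[(u, v)], fa_species=[],
            z=z, p=float(norm.sf(z)), status=status_of(z, alpha),
        )
    return G


@pytest.fixture()
def cortex_branch_graph(db):
    """The published branching example: PC→DG (3.083), DG→MG (2.054),
    DG→PA (−0.408)."""
    return scored_graph(
        [
            ("PC", "DG", "PC->DG", 3.083),
            ("DG", "MG", "DG->MG", 2.054),
            ("DG", "PA", "DG->PA", -0.408),
        ]
    )
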
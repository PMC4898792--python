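"""Canned small objects used in documentation, tests and the CLI.

``five_taxon_example_network`` is the package's worked example: five taxa
A-E on the backbone (((A,B),D),E), one introgression from E into D replacing
10% of D's genome, and one later hybrid speciation founding C from the B and
D lineages with a 60:40 contribution split.  Exhaustively resolving its four
reticulation routings gives the lineage-tree distribution

    (((A,(B,C)),D),E)   0.54      hybrid -> B side,  no introgression
    (((A,B),(C,D)),E)   0.36      hybrid -> D side,  no introgression
    ((A,(B,C)),(D,E))   0.06      hybrid -> B side,  introgressed locus
    ((A,B),((C,D),E))   0.04      hybrid -> D side,  introgressed locus

Note the ordering of events matters: because the hybrid speciation happens
after the introgression, a locus routed through the D-side parent can also
be captured by the introgression, producing the ((C,D),E) grouping.
"""

from __future__ import annotations

from .network import NetworkEvent, SpeciesNetwork

__all__ = ["five_taxon_example_network", "FIVE_TAXON_EXPECTED_DISTRIBUTION", "FIXTURES"]

#: Expected exact lineage-tree distribution of the five-taxon example.
FIVE_TAXON_EXPECTED_DISTRIBUTION = {
    "(((A,(B,C)),D),E);": 0.54,
    "(((A,B),(C,D)),E);": 0.36,
    "((A,(B,C)),(D,E));": 0.06,
    "((A,B),((C,D),E));": 0.04,
}


def five_taxon_example_network() -> SpeciesNetwork:
    """Five-taxon network with one hybrid speciation and one introgression."""
    # species ids: 0=A, 1=E, 2=D, 3=B, 4=C
    events = [
        NetworkEvent("speciation", 0.0, a=0, child=1),              # root: A-lineage | E
        NetworkEvent("speciation", 0.2, a=0, child=2),              # D splits from A-lineage
        NetworkEvent("speciation", 0.4, a=0, child=3),              # B splits from A
        NetworkEvent("introgression", 0.5, a=1, b=2, gamma=0.1),    # E -> D, 10% replaced
        NetworkEvent("hybrid", 0.6, a=3, b=2, child=4, gamma=0.6),  # C = 0.6*B + 0.4*D
    ]
    return SpeciesNetwork(events, n_species=5, end_time=1.0, names=["A", "E", "D", "B", "C"])


FIXTURES = {"five_taxon_example": five_taxon_example_network}
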
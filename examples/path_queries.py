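"""Mine the connectome with regex path queries.

Queries alternate node regexes (full-matched against class labels) and edge
kinds. Chemical hops are directional; gap-junction hops are symmetric. The
coupled-feedforward motif GC1 :: AC > GC2 (ganglion cell coupled to an
amacrine cell that inhibits a *different-class* ganglion cell) is a two-hop
query plus a disjointness filter.
"""

from retcouple import (
    count_matches,
    disjoint_filter,
    find_paths,
    input_spectrum,
    parse_query,
    rc1_summary_fixture,
)

graph = rc1_summary_fixture()

# every cone-bipolar ribbon synapse onto the tON DS analog
pattern = parse_query("CB.*, ribbon, GC tON DS")
matches = find_paths(graph, pattern)
print(f"cone bipolar ribbon inputs onto tON DS cells: {len(matches)}")
print(count_matches(matches, graph, group_by="first_class"))

# its input spectrum: one bipolar class dominates, another is excluded
spectrum = input_spectrum(graph, "GC606", "ribbon")
print(f"\ndominant class {spectrum.dominant_class} "
      f"({spectrum.fractions.max():.0%} of input); "
      f"CBb5 exclusion {spectrum.exclusion_fraction('CBb5'):.1%}")

# coupled-feedforward chains onto disjoint ganglion classes
chains = find_paths(graph, parse_query("GC.*, gap junction, .*AC.*, conventional, GC.*"))
disjoint = disjoint_filter(chains, graph, 0, 2)
targets = {graph.neurons[m.neuron_ids[-1]].class_label for m in disjoint}
print(f"\ncoupled feedforward chains: {len(disjoint)} onto classes {sorted(targets)}")
# Reading: excitation of the coupled ganglion cell can inhibit neighboring
# ganglion cells of other classes through its coupled amacrine partners.
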
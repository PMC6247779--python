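"""Tabulate a ganglion cell's synaptic and coupling drive, then extrapolate
to the whole cell.

The packaged summary fixture encodes the published tallies for a transient
ON directionally selective ganglion cell whose in-volume arbor is 18% of the
complete cell. Dividing observed counts by that arbor fraction estimates
whole-cell drive.
"""

from retcouple import drive_table, rc1_summary_fixture

graph = rc1_summary_fixture()
table = drive_table(graph, "GC606", arbor_fraction=0.18)

frame = table.to_frame()[["n", "mean_area_um2", "total_area_um2", "extrapolated_n"]]
print(frame.round({"mean_area_um2": 3, "total_area_um2": 1}))
print()
print(f"inhibitory : excitatory synapse ratio  {table.inhibitory_excitatory_count_ratio:.2f}")
print(f"inhibitory PSD area per ribbon area    {table.inhibitory_excitatory_area_ratio:.1f}")

# Reading: the cell receives ~3 inhibitory synapses per excitatory ribbon
# input and 5.5 um^2 of inhibitory PSD per um^2 of ribbon PSD; a complete
# cell of this class should carry ~1440 ribbon synapses, ~4350 conventional
# synapses and ~1270 gap junctions.
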
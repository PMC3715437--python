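# Example exclusion-id list for the manual-curation filtering step.
# Small GTPases of the ARF/SAR/RAB families are promiscuous hubs present
# in all three trafficking routes and are excluded from the off-pathway
# partner statistics.  Extend or replace this list for a real analysis.
P84077  # ARF1
P61204  # ARF3
P18085  # ARF4
P84085  # ARF5
P62330  # ARF6
Q9NR31  # SAR1A
Q9Y6B6  # SAR1B
P20339  # RAB5A
P61026  # RAB10
P62820  # RAB1A
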
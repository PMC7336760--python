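# Transmembrane topology registry for GABA-A receptor subunit alpha-2.
#
# Helix spans are a versioned snapshot in UniProt canonical coordinates
# (P47869), placed from the subunit's published structural landmarks:
# Pro280 sits at the N-terminal end of the pore-lining M2 helix (the -2'
# desensitization-gate ring), Leu291 is the conserved 9' activation-gate
# leucine, Met263 lies mid-M1, Phe325 mid-M3 and Asn335 at the M3 C-terminus.
# TRANSMEM-style boundary annotations are release-dependent and may differ
# from this snapshot by a residue or two at either end; prime numbering is
# anchored at the 9' leucine precisely so that such drift cannot move it.

[P47869]
gene = "GABRA2"
M1 = [253, 274]
M2 = [280, 301]
M3 = [315, 336]
M4 = [420, 441]
flank = 5
anchor = [291, 9]   # Leu291 = 9' (activation-gate leucine)
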
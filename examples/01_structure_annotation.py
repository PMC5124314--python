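"""Parse a hairpin's dot-bracket structure and annotate its loops/bulges.

Builds the pair map, measures every unpaired run's length l (the quantity
the loop-length encoding feeds on), and locates the terminal apex loop
that splits the precursor into its 5p and 3p arms.
"""

from lbsizecleav import annotate_loops, find_apex, max_loop_length, parse_dotbracket

structure = "((((((..((((((....))))))..))))))"
pm = parse_dotbracket(structure)
ann = annotate_loops(pm)
arms = find_apex(pm)

print("structure :", structure)
print("runs      :", "".join(str(l) if l else "-" for l in ann.run_length))
print("apex      :", arms.apex, "(half-open; the terminal loop)")
print("M         :", max_loop_length([ann]), "(max run length; fixes the encoding size)")

# Each digit above is the length of the unpaired run containing that
# position ('-' = base-paired); the apex run and the two 2-nt internal
# loop strands are what the L_l tokens will encode.
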
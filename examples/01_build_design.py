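"""Build the rotatable central composite design for the HILIC screening study.

Three mobile-phase factors (acetonitrile %, aqueous-phase pH, ammonium
formate concentration) give 2^3 factorial + 6 axial + 6 centre = 20 runs.
The axial runs sit at coded distance alpha = (2^3)^(1/4) = 1.68 from the
centre, which is what makes the design rotatable (uniform prediction
variance on spheres).
"""

import chromdoe as cd

design = cd.build_ccd(cd.HILIC_FACTORS, n_center=6)
print(f"alpha = {design.alpha:.6f}  (rotatable, 3 factors)")
print(f"runs  = {len(design)}  "
      f"({(design.blocks == 'factorial').sum()} factorial, "
      f"{(design.blocks == 'axial').sum()} axial, "
      f"{(design.blocks == 'center').sum()} centre)")
print()
print(design.to_frame(display=True).to_string(index=False))
print()
print("Each row is one experiment: coded levels are what the model sees,")
print("actual levels (e.g. 66.59 % ACN at the low ACN star point) are what")
print("the analyst would set on the instrument.")
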
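"""Transwell endothelial transcytosis: saturation and subclass competition.

Reproduces the two in vitro-style experiments: sweep apical IgG4 to find
the concentration where FcRn-mediated transcytosis saturates, then hold
IgG4 just below that point and add IgG1 to see competition emerge only
once total IgG exceeds the receptor's capacity.
"""

from placigg import HuvecParameters, competition_curve, find_saturation_point

p = HuvecParameters()

sat = find_saturation_point(p)
print(f"Transcytosis saturation point: {sat['saturation_mg_ml']:.3f} mg/ml")
print("  (the apical IgG4 dose that stoichiometrically exhausts the "
      f"{p.FcRn0:.0f} nM FcRn pool)")

comp = competition_curve(p, igg4_fixed_mg_ml=0.2)
print(f"IgG1 level where IgG4 transcytosis first drops >5%: "
      f"{comp['onset_igg1_mg_ml']:.2f} mg/ml")
print(f"  -> total IgG at onset: {comp['onset_total_mg_ml']:.2f} mg/ml, "
      "matching the saturation point: competition appears only when the "
      "receptor is limiting.")
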
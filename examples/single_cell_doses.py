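"""Absorbed dose to the nucleus of a single labelled tumour cell.

Runs the 14-µm cell / 10-µm nucleus phantom for both radionuclides and all
four subcellular source distributions, with the release normalised to
1 MeV per µm³ of cell volume (1437 MeV per cell).  The printed doses show
the two hallmarks of the comparison: doses rise as the source moves inward
(surface → cytoplasm → whole cell → nucleus), and ¹⁶¹Tb delivers 2–4× the
¹⁷⁷Lu dose everywhere thanks to its conversion- and Auger-electron load.
"""

import microdosim as md

N_DECAYS = 200_000  # sampled decays; statistics only, not the release

print(f"{'':14s}{'177Lu':>12s}{'161Tb':>12s}{'Tb/Lu':>8s}")
for dist in ("cell_surface", "cytoplasm", "whole_cell", "nucleus"):
    doses = {}
    for nuc in ("lu177", "tb161"):
        rep = md.run_single_cell(
            md.RunConfig(
                radionuclide=nuc,
                distribution=dist,
                n_decays=N_DECAYS,
                rng_seed=1,
            )
        )
        doses[nuc] = rep.dose_gy
    ef = md.enhancement_factor(doses["tb161"], doses["lu177"])
    print(
        f"{dist:14s}{doses['lu177']:10.2f} Gy{doses['tb161']:10.2f} Gy{ef:8.1f}"
    )
print(
    "\nEach row: dose to the 10-µm nucleus when 1436 MeV of electron energy\n"
    "is released in that source region; Tb/Lu is the enhancement factor."
)
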
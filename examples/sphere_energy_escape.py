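"""Energy escape from small uniformly labelled water spheres.

For ¹⁷⁷Lu releasing 1 MeV per µm³, the mean absorbed dose in a water
sphere falls far below the 160.2 Gy infinite-medium equilibrium value as
the sphere shrinks below the β range: this is why medium-energy β emitters
under-dose micrometastases.  The absorbed fraction printed is
dose / 160.2 Gy.
"""

import microdosim as md
from microdosim.dosimetry import MEV_PER_UM3_TO_GY

print(f"{'diameter':>10s}{'dose':>10s}{'absorbed fraction':>20s}")
for radius_um in (1000.0, 100.0, 10.0):
    rep = md.run_sphere(
        radius_um, "lu177", md.RunConfig(n_decays=50_000, rng_seed=3)
    )
    af = rep.dose_gy / MEV_PER_UM3_TO_GY
    print(f"{2 * radius_um / 1000:8.2f}mm{rep.dose_gy:8.1f} Gy{af:16.2f}")
print(
    "\nA 2-mm sphere keeps ~80% of the released energy; a 20-µm sphere\n"
    "(a single cell) keeps only ~4%: the rest escapes with the β particles."
)
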
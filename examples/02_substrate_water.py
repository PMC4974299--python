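"""Substrate hydrology: retention curve, plant-available water, targets.

Evaluates the van Genuchten retention curve of the default potting
substrate, derives plant-available water (field capacity at -0.01 MPa
minus permanent wilting point at -1.5 MPa) and the pot target weights
that hold the two watering regimes at 75% and 25% of it.
"""

from phenowater import (DEFAULT_RETENTION, SubstrateSpec, paw,
                        target_weight, theta_at)
from phenowater.environment import suction_head_cm

substrate = SubstrateSpec(retention=DEFAULT_RETENTION, volume=5.0)

for mpa in (-0.001, -0.01, -0.1, -1.5):
    theta = theta_at(suction_head_cm(mpa), DEFAULT_RETENTION)
    print(f"theta({mpa:>7} MPa) = {theta:.3f} cm3/cm3")

frac, ml = paw(substrate)
print(f"plant-available water: {frac:.3f} cm3/cm3 = {ml:.0f} ml "
      "per 5 L pot  <- the water a root system can actually extract")

control = target_weight(substrate, 0.75)
stress = target_weight(substrate, 0.25)
print(f"irrigation targets: control {control:.0f} g, drought {stress:.0f} g"
      f" (difference {control - stress:.0f} g = half the PAW)")
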
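"""Physical constants and unit conventions.

Units used throughout the package:

* contents        mmol/Loc   (millimoles per liter of *original* cells)
* concentrations  mmol/Lcw   (per liter of cell water); medium in mmol/L
* fluxes          mmol/Loch  (per liter of original cells per hour),
                  influx positive / efflux negative
* permeabilities  1/h, referenced to the standard cell area/volume ratio;
                  1/h is equivalent to ~2e-8 cm/s
* potential       mV; time in hours (h) externally, seconds in the stepper
"""

#: RT/F at 37 degC, in mV.
RTF_MV = 26.73

#: Conversion between the model's 1/h permeability unit and cm/s.
PERMEABILITY_CM_PER_S_PER_H = 2.0e-8

SECONDS_PER_HOUR = 3600.0


def permeability_h_to_cm_s(p_per_h: float) -> float:
    """Convert a permeability from 1/h (standard-cell units) to cm/s."""
    return p_per_h * PERMEABILITY_CM_PER_S_PER_H


def permeability_cm_s_to_h(p_cm_s: float) -> float:
    """Convert a permeability from cm/s to 1/h (standard-cell units)."""
    return p_cm_s / PERMEABILITY_CM_PER_S_PER_H
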
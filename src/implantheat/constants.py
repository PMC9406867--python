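"""Physical constants and fixed reference values.

The reference excitation used to normalise SAR maps is a hard (rectangular)
RF pulse of length 1 ms producing a 90-degree flip angle.  Both values are
fixed by convention and are deliberately constants, not configuration.
"""

import math

#: Proton gyromagnetic ratio, rad/s/T.
GAMMA_PROTON: float = 2.0 * math.pi * 42.577e6

#: Reference flip angle (rad) of the normalising hard pulse.
REF_FLIP_ANGLE: float = math.pi / 2.0

#: Reference hard-pulse length (s).
REF_PULSE_LENGTH: float = 1.0e-3

#: IEC SAR averaging window (s).
T_IEC: float = 360.0

#: Default gradient hardware limits for fixture waveforms (config-overridable).
DEFAULT_MAX_GRADIENT: float = 0.040  # T/m
DEFAULT_MAX_SLEW: float = 200.0  # T/m/s

#: Electrical conductivity presets for implant alloys, S/m.
CONDUCTIVITY_COCRMO: float = 1.16e6
CONDUCTIVITY_TI6AL4V: float = 5.8e5
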
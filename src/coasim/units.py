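"""Unit conversion constants.

Internal convention: lengths are stored in mm at the measurement level and
converted to cm for any dyne-based quantity; the lumped solver works in a
uniform (mmHg, s, ml) system.
"""

MMHG_TO_DYN_CM2 = 1333.22
"""1 mmHg in dyn/cm^2 (fixed conversion used throughout)."""

MMHG_TO_KPA = 0.133322
"""1 mmHg in kPa."""

MM_TO_CM = 0.1

CP_TO_POISE = 0.01
"""1 centipoise in poise (g/(cm s))."""
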
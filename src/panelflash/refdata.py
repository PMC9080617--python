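"""Reference measurement values for the baffled flat-panel reactor.

These are the published operating-point measurements the synthetic flow
emulator is calibrated against, together with the reported comparison values
used by the validation suite and the acceptance report.  Velocities are
sampling-line averages in cm/s; periods and mixing times in s; mass-transfer
coefficients in 1/h; light calibration in (g/L, cm).
"""

from __future__ import annotations

from .flow import AerationCalibration

# Line-averaged (vertical, horizontal) velocity targets per aeration rate.
# rows: (rate_vvm, baffled, vz_cm_s, vx_cm_s).  With baffles the vertical
# velocity saturates above 0.06 vvm; the 0.06/0.1 vvm baffled entries hold
# the last reported values flat.
AERATION_TABLE = AerationCalibration(
    rows=(
        (0.02, False, 10.2, 0.52),
        (0.04, False, 13.9, 0.62),
        (0.06, False, 16.5, 0.70),
        (0.10, False, 20.1, 0.90),
        (0.02, True, 9.6, 1.0),
        (0.04, True, 10.4, 1.3),
        (0.06, True, 10.4, 1.3),
        (0.10, True, 10.4, 1.3),
    )
)

#: Incident photon flux at the illuminated face, umol m^-2 s^-1.
I0_DEFAULT = 530.0
#: Critical photon flux separating light from dark zone, umol m^-2 s^-1.
I_CRIT_DEFAULT = 96.84

#: Measured (concentration g/L, critical depth cm) calibration points.
LIGHT_CALIBRATION = {0.28: 5.0, 0.85: 2.0, 1.7: 1.0}

#: Population L/D cycle period (s) at 0.02 vvm, 0.85 g/L.
LD_PERIOD_S = {"unbaffled": 17.1, "baffled": 14.1}

#: Probability (%) of a per-cell average period in the [5, 10) s bin.
LD_BIN_5_10_PERCENT = {"unbaffled": 27.9, "baffled": 43.6}

#: Population L/D period (s) with baffles at 0.28 and 1.7 g/L, 0.02 vvm.
LD_PERIOD_BY_CONC_BAFFLED_S = {0.28: 15.6, 1.7: 11.4}

#: Doppler-velocimeter measured average velocity magnitude (cm/s) at 0.02 vvm.
MEASURED_VELOCITY_CM_S = {"unbaffled": 0.48, "baffled": 0.95}

#: Simulated horizontal velocity (cm/s) the measurement is compared against.
SIMULATED_VELOCITY_CM_S = {"unbaffled": 0.52, "baffled": 1.0}

#: Volumetric mass-transfer coefficient k_L a_L (1/h) at 0.02 and 0.1 vvm.
KLA_PER_H = {
    "unbaffled": {0.02: 0.053, 0.10: 0.142},
    "baffled": {0.02: 0.081, 0.10: 0.208},
}

#: Tracer-pulse mixing time (s) at 0.02 and 0.1 vvm.
MIXING_TIME_S = {
    "unbaffled": {0.02: 48.1, 0.10: 27.6},
    "baffled": {0.02: 39.6, 0.10: 22.5},
}
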
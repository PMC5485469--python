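"""Reference values for the Lake Kinneret intraguild-predation study.

``REFERENCE_ANNUAL_PREDATION`` holds the reported average annual predation
of each of the six IGP channels (thousand ton wet weight per year) for the
calibrated Kinneret run at base (x1), doubled (x2) and eight-fold (x8)
fish abundance.  They serve as worked-example inputs for the scenario
table diagnostics — the derived cells (group totals, ratios,
percent-of-base) recompute from these channel values.

``SENSITIVITY_SIGNS`` records the reported direction of the change in
mean herbivorous-zooplankton concentration for each one-at-a-time +-50%
perturbation of the four IGP parameters (+1 denotes an increase, -1 a
decrease; entries with magnitude ~1% are direction-fragile and flagged).
"""

REFERENCE_ANNUAL_PREDATION = {
    "x1": {"z1_z1": 12.62, "f_z1": 2.37, "z1_z2": 31.81, "f_z2": 12.83,
           "z1_z3": 0.59, "f_z3": 0.08},
    "x2": {"z1_z1": 6.89, "f_z1": 3.48, "z1_z2": 25.32, "f_z2": 18.57,
           "z1_z3": 0.45, "f_z3": 0.13},
    "x8": {"z1_z1": 1.17, "f_z1": 5.01, "z1_z2": 12.11, "f_z2": 33.10,
           "z1_z3": 0.16, "f_z3": 0.35},
}

# (parameter, factor) -> (sign of reported mean-Z2 change, strict?)
SENSITIVITY_SIGNS = {
    ("g_max", 0.5): (+1, True),    # reported +27%
    ("g_max", 1.5): (-1, True),    # reported -10%
    ("P_zk1", 0.5): (-1, True),    # reported -7%
    ("P_zk1", 1.5): (+1, False),   # reported +1%
    ("V_11", 0.5): (-1, True),     # reported -8%
    ("V_11", 1.5): (+1, False),    # reported +1%
    ("V_12", 0.5): (+1, True),     # reported +10%
    ("V_12", 1.5): (-1, True),     # reported -7%
}

# reported initial values of the perturbed parameters
SENSITIVITY_INITIAL = {"g_max": 3.03, "P_zk1": 0.15, "V_11": 0.4, "V_12": 0.5}
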
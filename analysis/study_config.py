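"""Shared study conditions for the numbered analysis drivers.

One synthetic cohort stands in for the study sample throughout: 120
elderly subjects (ages 66-75, half female), APOE4 prevalence 0.22, and a
contiguous gray-matter pattern whose expression falls with the Framingham
risk score in females only (male slope zero).  Every driver regenerates
the same cohort deterministically from this config, so the scripts can be
run independently and in any order.
"""

from riskmvpa.synthetic import SyntheticConfig

STUDY_SEED = 42
STUDY_CONFIG = SyntheticConfig(seed=STUDY_SEED)

#: permutations per test in the drivers; enough for p-resolution 0.005
B_PERMUTATIONS = 199
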
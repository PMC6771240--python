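"""Named study scenarios used by the validation suite.

Each factory returns a :class:`SyntheticConfig` describing one simulated
study condition:

* ``recovery`` — marker-recovery power: a mid-sized cohort with 20 planted
  markers at a moderate per-marker effect (log-hazard coefficient ln 3)
  among a majority of null probes.
* ``null`` — an effect-free cohort with a large probe panel, for type-I
  calibration of the fixed median split and the best-fit scan.
* ``robustness`` — few, very strong markers (coefficient ln 8) in a large
  cohort, the regime where the split-half simulation should always call
  them robust.
* ``end_to_end`` — two strong complementary marker blocks tied to one
  latent risk factor (anti-correlated, near-deterministic traits), the
  regime in which a discovered type-1/type-2 signature pair should
  classify held-out patients with abstentions but no false calls.
"""

from __future__ import annotations

import math

from .synthetic_cohort import SyntheticConfig

__all__ = [
    "recovery_scenario",
    "null_scenario",
    "robustness_scenario",
    "end_to_end_scenario",
]


def recovery_scenario(seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(
        n_patients=300,
        n_proteins=200,
        n_adverse=10,
        n_favorable=10,
        effect_log_hr=math.log(3.0),
        censoring_rate=0.3,
        n_oc_plasma=0,
        n_n_plasma=0,
        seed=seed,
    )


def null_scenario(seed: int = 0, n_proteins: int = 2000) -> SyntheticConfig:
    return SyntheticConfig(
        n_patients=100,
        n_proteins=n_proteins,
        n_adverse=0,
        n_favorable=0,
        censoring_rate=0.3,
        n_oc_plasma=0,
        n_n_plasma=0,
        seed=seed,
    )


def robustness_scenario(seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(
        n_patients=300,
        n_proteins=50,
        n_adverse=2,
        n_favorable=2,
        effect_log_hr=math.log(8.0),
        censoring_rate=0.3,
        n_oc_plasma=0,
        n_n_plasma=0,
        seed=seed,
    )


def end_to_end_scenario(seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(
        n_patients=80,
        n_proteins=60,
        n_adverse=3,
        n_favorable=3,
        effect_log_hr=math.log(4.0),
        planted_trait_mode="shared",
        trait_flip_rate=0.01,
        censoring_rate=0.3,
        n_oc_plasma=0,
        n_n_plasma=0,
        seed=seed,
    )
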
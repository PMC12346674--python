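"""Synthetic e-nose dataset generator.

The measured chili-pepper headspace data behind the original study are not
available in machine-readable form, so this module generates datasets with
the same statistical structure: a class x bottle x repetition design, a
low-signal initial contact phase (the sample gas does not fully reach the
array in the first ~20 s), first-order exponential rise toward a
class-specific plateau, and multiplicative bottle-level / repetition-level
variability on top of additive per-sample noise.

Signal model for class ``c``, sensor ``s``, bottle ``b``, repetition ``r``::

    R(t) = 1 + A[c,s] * (1 + B[b]) * (1 + P[r]) * ramp(t) + eps(t)
    ramp(t) = max(0, 1 - exp(-(t - d[c]) / tau[c,s]))   for t > d[c], else 0

with B ~ N(0, sigma_bottle) fixed per bottle, P ~ N(0, sigma_rep) fixed per
repetition, eps ~ N(0, sigma_eps) i.i.d. per time point, and the result
clamped to a small positive floor so the G/G0 > 0 invariant survives the
additive noise.  First-order rise is the standard response kinetic of
metal-oxide sensors; amplitudes may be negative (sensors whose conductivity
ratio falls below 1 under the sample gas).

Difficulty presets scale the between-class amplitude separation relative to
the bottle/repetition spread; they stand in for the unknowable real effect
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import (
    N_SENSORS,
    CollectionDesign,
    Dataset,
    SensorRecord,
)

#: Positive floor applied after additive noise (keeps G/G0 > 0).
VALUE_FLOOR = 1e-3

#: Typical steady-state response of each sensor in array order: the three
#: reducing-response sensors sit below baseline (negative amplitude), the
#: broad-band sensors respond strongly.  Dimensionless G/G0 offsets.
BASE_AMPLITUDE = np.array(
    [-0.4, 6.0, -0.3, 0.8, -0.35, 2.5, 4.0, 3.0, 2.0, 0.6]
)

#: Difficulty presets: ``separation`` scales the relative between-class
#: amplitude differences; sigma_* are the noise scales of the signal model.
DIFFICULTY_PRESETS: dict[str, dict[str, float]] = {
    "easy": dict(separation=1.0, sigma_bottle=0.02, sigma_rep=0.01, sigma_eps=0.01),
    "medium": dict(separation=0.25, sigma_bottle=0.06, sigma_rep=0.03, sigma_eps=0.02),
    "hard": dict(separation=0.06, sigma_bottle=0.12, sigma_rep=0.06, sigma_eps=0.04),
}

# Contact delay and rise-time ranges (seconds).  Delays in [5, 20] reproduce
# the unstable first ~20 s; rise times put the plateau around 30-60 s.
DELAY_RANGE = (5.0, 20.0)
TAU_RANGE = (8.0, 25.0)


@dataclass(frozen=True)
class ClassProfileBank:
    """Per-class response profiles plus noise scales; fully seed-determined."""

    amplitudes: np.ndarray   # (n_classes, N_SENSORS) steady-state A[c,s]
    tau: np.ndarray          # (n_classes, N_SENSORS) rise time constants [s]
    delay: np.ndarray        # (n_classes,) contact delay d[c] [s]
    sigma_bottle: float
    sigma_rep: float
    sigma_eps: float
    seed: int
    difficulty: str

    def __post_init__(self) -> None:
        if np.any(self.tau <= 0):
            raise ValueError("rise time constants must be positive")
        if min(self.sigma_bottle, self.sigma_rep, self.sigma_eps) < 0:
            raise ValueError("noise scales must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.amplitudes.shape[0]

    def min_class_separation(self) -> float:
        """Minimum pairwise Euclidean distance between class amplitude vectors."""
        a = self.amplitudes
        dists = np.linalg.norm(a[:, None, :] - a[None, :, :], axis=-1)
        iu = np.triu_indices(self.n_classes, k=1)
        return float(dists[iu].min())


def make_profile_bank(
    design: CollectionDesign, difficulty: str = "medium", seed: int = 0
) -> ClassProfileBank:
    """Draw a deterministic profile bank for a collection design.

    Class amplitude vectors are ``BASE * (1 + separation * delta[c,s])``
    with ``delta ~ N(0, 1)``: the same seed yields the same deltas at every
    difficulty, so harder banks are exact shrunk versions of easier ones and
    separation comparisons across difficulties are deterministic.
    """
    if difficulty not in DIFFICULTY_PRESETS:
        raise ValueError(
            f"difficulty must be one of {sorted(DIFFICULTY_PRESETS)}, "
            f"got {difficulty!r}"
        )
    preset = DIFFICULTY_PRESETS[difficulty]
    rng = np.random.default_rng(seed)
    delta = rng.standard_normal((design.n_classes, N_SENSORS))
    amplitudes = BASE_AMPLITUDE * (1.0 + preset["separation"] * delta)
    tau = rng.uniform(*TAU_RANGE, size=(design.n_classes, N_SENSORS))
    delay = rng.uniform(*DELAY_RANGE, size=design.n_classes)
    return ClassProfileBank(
        amplitudes=amplitudes,
        tau=tau,
        delay=delay,
        sigma_bottle=preset["sigma_bottle"],
        sigma_rep=preset["sigma_rep"],
        sigma_eps=preset["sigma_eps"],
        seed=seed,
        difficulty=difficulty,
    )


def _ramp(t: np.ndarray, delay: float, tau: np.ndarray) -> np.ndarray:
    """First-order rise, zero before the contact delay.

    ``t``: (n_seconds,), ``tau``: (N_SENSORS,) -> (N_SENSORS, n_seconds).
    """
    dt = t[None, :] - delay
    r = 1.0 - np.exp(-dt / tau[:, None])
    return np.where(dt > 0, np.maximum(r, 0.0), 0.0)


def generate_dataset(bank: ClassProfileBank, design: CollectionDesign) -> Dataset:
    """Emit exactly n_classes x n_bottles x n_repetitions records.

    Deterministic given (bank, design): the record-noise stream is seeded
    from the bank's master seed, independently of the profile draws.
    """
    if bank.n_classes != design.n_classes:
        raise ValueError(
            f"bank has {bank.n_classes} classes, design expects {design.n_classes}"
        )
    rng = np.random.default_rng([bank.seed, 0xE05E])
    n_seconds = design.n_seconds
    t = np.arange(1, n_seconds + 1, dtype=float)

    bottle_eff = rng.normal(
        0.0, bank.sigma_bottle, size=(design.n_classes, design.n_bottles)
    )
    rep_eff = rng.normal(
        0.0,
        bank.sigma_rep,
        size=(design.n_classes, design.n_bottles, design.n_repetitions),
    )

    records: list[SensorRecord] = []
    for c in range(design.n_classes):
        ramp = _ramp(t, float(bank.delay[c]), bank.tau[c])  # (sensors, seconds)
        for b in range(design.n_bottles):
            for r in range(design.n_repetitions):
                gain = (1.0 + bottle_eff[c, b]) * (1.0 + rep_eff[c, b, r])
                signal = 1.0 + bank.amplitudes[c][:, None] * gain * ramp
                eps = rng.normal(0.0, bank.sigma_eps, size=(N_SENSORS, n_seconds))
                values = np.maximum(signal + eps, VALUE_FLOOR)
                records.append(
                    SensorRecord(
                        record_id=f"c{c:02d}_b{b:02d}_r{r:02d}",
                        class_label=c,
                        bottle_id=b,
                        repetition_id=r,
                        values=values,
                    )
                )
    ds = Dataset(records=records, design=design)
    ds.validate(require_complete=True)
    return ds
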
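"""First-order schedule model of hardware loop unrolling.

Unrolling a loop by a factor U replicates the loop body U times on the
device so U iterations execute concurrently: n iterations then take
ceil(n / U) sequential stages instead of n, at U times the loop-body
resource cost.  The model is purely combinational — constant stage time,
no pipeline fill/drain, no memory-port contention beyond the chosen
factor — which is exactly the trade the unrolling argument is about.

For the 5-tap convolution loop unrolled by 2: ceil(5/2) = 3 stages, a
(5 - 3)/5 = 2/5 execution-time saving, at twice the resources.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction


def _check(n: int, unroll: int) -> None:
    if n < 1:
        raise ValueError("iteration count must be >= 1")
    if unroll < 1:
        raise ValueError("unroll factor must be >= 1")


def unrolled_stages(n: int, unroll: int) -> int:
    """Sequential stages after unrolling: ceil(n / U)."""
    _check(n, unroll)
    return -(-n // unroll)


def time_saving(n: int, unroll: int) -> Fraction:
    """Fraction of execution time saved: (n - ceil(n/U)) / n."""
    _check(n, unroll)
    return Fraction(n - unrolled_stages(n, unroll), n)


def resource_cost(n: int, unroll: int) -> int:
    """Loop-body replication factor (relative area cost): U."""
    _check(n, unroll)
    return unroll


@dataclass(frozen=True)
class LoopSchedule:
    """Summary of one unrolled loop at a given stage time."""

    n_iterations: int
    unroll_factor: int
    stage_time: float = 1.0

    def __post_init__(self) -> None:
        _check(self.n_iterations, self.unroll_factor)
        if self.stage_time <= 0:
            raise ValueError("stage time must be positive")

    @property
    def stages(self) -> int:
        return unrolled_stages(self.n_iterations, self.unroll_factor)

    @property
    def latency(self) -> float:
        return self.stages * self.stage_time

    @property
    def saving(self) -> Fraction:
        return time_saving(self.n_iterations, self.unroll_factor)

    @property
    def resource_multiplier(self) -> int:
        return resource_cost(self.n_iterations, self.unroll_factor)
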
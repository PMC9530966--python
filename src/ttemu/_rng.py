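"""Counter-based uniform streams for the cohort simulator.

Every random draw is addressed by ``(seed, patient, day, channel)`` and
produced by a 64-bit mixing function, so the simulator is embarrassingly
vectorisable across patients while keeping a crucial reproducibility
property: enlarging ``n_patients`` appends new patients without changing
the trajectories of existing ones, and forcing a treatment regime leaves
the draws of the untouched channels (severity noise, death, discharge)
identical to the observational run under the same seed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri

__all__ = ["uniforms", "normals", "CH"]

# draw channels
class CH:
    AGE = 101
    SEX = 102
    COMORBID = 103
    SEV0 = 104
    SEV_NOISE = 1
    MEASURE = 2
    TREAT = 3
    DEATH = 4
    DISCHARGE = 5


_M1 = np.uint64(0xFF51AFD7ED558CCD)
_M2 = np.uint64(0xC4CEB9FE1A85EC53)
_P1 = np.uint64(0x9E3779B97F4A7C15)
_P2 = np.uint64(0xD1B54A32D192ED03)
_P3 = np.uint64(0x8CB92BA72F3D8DD7)
_SHIFT33 = np.uint64(33)
_SHIFT11 = np.uint64(11)
_INV53 = float(2.0 ** -53)


def _mix(z: np.ndarray) -> np.ndarray:
    """64-bit finaliser (murmur3 variant): full avalanche on uint64 arrays."""
    z = z ^ (z >> _SHIFT33)
    z = z * _M1
    z = z ^ (z >> _SHIFT33)
    z = z * _M2
    z = z ^ (z >> _SHIFT33)
    return z


def uniforms(seed: int, patients: np.ndarray, day: int, channel: int) -> np.ndarray:
    """U(0,1) draws, one per patient id, for a given day and channel.

    Deterministic in all four arguments; draws for distinct tuples are
    statistically independent for simulation purposes.
    """
    pid = np.asarray(patients, dtype=np.uint64)
    mask = (1 << 64) - 1
    key = np.uint64((int(seed) * 0x9E3779B97F4A7C15) & mask)
    ctr = np.uint64(((int(day) * 0xD1B54A32D192ED03)
                     ^ (int(channel) * 0x8CB92BA72F3D8DD7)) & mask)
    h = _mix(_mix(pid * _P3 ^ key) ^ ctr)
    # top 53 bits -> open interval (0, 1): never exactly 0 or 1
    return ((h >> _SHIFT11).astype(np.float64) + 0.5) * _INV53


def normals(seed: int, patients: np.ndarray, day: int, channel: int) -> np.ndarray:
    """Standard normal draws via the inverse CDF of :func:`uniforms`."""
    return ndtri(uniforms(seed, patients, day, channel))
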
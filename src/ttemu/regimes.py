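"""Treatment regimes of the emulated trial.

Two strategies are compared:

* ``dynamic_steroids`` — start corticosteroids on the first day severe-hypoxia
  criteria are met and continue for ``duration_days`` (default 6) consecutive
  days, truncated at the end of follow-up;
* ``never_treat`` — no corticosteroids on any day.

A regime is a deterministic decision rule: given the hypoxia history observed
through day ``t`` it returns the treatment the rule assigns on day ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Regime", "DYNAMIC", "NEVER"]


@dataclass(frozen=True)
class Regime:
    kind: str  # "dynamic_steroids" | "never_treat"
    duration_days: int = 6

    def __post_init__(self) -> None:
        if self.kind not in ("dynamic_steroids", "never_treat"):
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")

    def assign(self, hypoxia_history: np.ndarray, day: int) -> int:
        """Treatment assigned on ``day`` given hypoxia through that day.

        ``hypoxia_history`` must cover days ``0..day`` (extra entries ignored).
        """
        h = np.asarray(hypoxia_history)[: day + 1]
        if len(h) < day + 1:
            raise ValueError("hypoxia history shorter than requested day")
        if self.kind == "never_treat":
            return 0
        hits = np.flatnonzero(h > 0)
        if hits.size == 0:
            return 0
        t_star = int(hits[0])
        return int(t_star <= day <= t_star + self.duration_days - 1)

    def assign_path(self, hypoxia: np.ndarray) -> np.ndarray:
        """Vectorised assignment over a full per-day hypoxia matrix.

        ``hypoxia`` is (n, tau) (or (tau,)); returns an int array of the same
        shape with the rule's assignment for every day.
        """
        h = np.atleast_2d(np.asarray(hypoxia))
        n, tau = h.shape
        if self.kind == "never_treat":
            out = np.zeros((n, tau), dtype=np.int8)
        else:
            seen = h.cumsum(axis=1) > 0
            first = np.where(seen.any(axis=1), seen.argmax(axis=1), tau)
            days = np.arange(tau)[None, :]
            out = ((days >= first[:, None])
                   & (days < first[:, None] + self.duration_days)).astype(np.int8)
        return out if np.asarray(hypoxia).ndim == 2 else out[0]


DYNAMIC = Regime("dynamic_steroids", 6)
NEVER = Regime("never_treat")
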
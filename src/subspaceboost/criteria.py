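"""Generalized information criteria of the l0 family.

The criteria share the form ``n * log(RSS/n) + lambda * |S|`` and differ only
in the penalty weight: AIC uses ``lambda = 2``, BIC ``log n`` and the
extended BIC ``log n + 2 * gamma * log p`` with ``gamma`` in [0, 1].  A raw
positive ``lambda`` can be supplied directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CriterionSpec"]

_NAMES = ("AIC", "BIC", "EBIC", "RAW")


@dataclass(frozen=True)
class CriterionSpec:
    """Member of the GIC family used in the double-checking step.

    Parameters
    ----------
    name : {"AIC", "BIC", "EBIC", "RAW"} (case-insensitive)
    gamma : EBIC weight in [0, 1]; ignored otherwise.
    lambda_raw : positive penalty, required for ``RAW``.
    """

    name: str = "BIC"
    gamma: float = 1.0
    lambda_raw: float = None

    def __post_init__(self):
        object.__setattr__(self, "name", str(self.name).upper())
        if self.name not in _NAMES:
            raise ValueError(f"unknown criterion {self.name!r}; choose from {_NAMES}")
        if self.name == "EBIC" and not (0.0 <= self.gamma <= 1.0):
            raise ValueError("EBIC gamma must lie in [0, 1]")
        if self.name == "RAW":
            if self.lambda_raw is None or self.lambda_raw <= 0:
                raise ValueError("RAW criterion requires a positive lambda_raw")

    def penalty(self, n: int, p: int) -> float:
        """Resolved penalty weight lambda(n, p)."""
        if self.name == "AIC":
            return 2.0
        if self.name == "BIC":
            return math.log(n)
        if self.name == "EBIC":
            return math.log(n) + 2.0 * self.gamma * math.log(p)
        return float(self.lambda_raw)
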
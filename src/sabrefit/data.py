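"""Concentration-effect dataset container.

One :class:`ECDataset` holds a single agonist x pretreatment curve: molar
concentrations, mean effects in percent of the system maximum, and optional
SEMs / replicate counts carried through as metadata. Effects are stored in
percent at the I/O boundary; fitting code converts to fractional effect
(percent / 100) internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

__all__ = ["ECDataset", "PRETREATMENTS"]

#: Valid pretreatment labels: N = naive, X = irreversibly inactivated
#: (FSCPX-pretreated in the emulated study design).
PRETREATMENTS = ("N", "X")


@dataclass
class ECDataset:
    agonist: str
    pretreatment: str
    concentrations: np.ndarray  # molar, strictly increasing; first may be 0
    effects: np.ndarray  # percent of system maximum
    sems: np.ndarray | None = None
    n_reps: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.pretreatment not in PRETREATMENTS:
            raise ValidationError(
                f"pretreatment must be one of {PRETREATMENTS}, got {self.pretreatment!r}"
            )
        if self.concentrations.ndim != 1 or self.effects.ndim != 1:
            raise ValidationError("concentrations and effects must be 1-D")
        if len(self.concentrations) != len(self.effects):
            raise ValidationError("concentrations and effects must have equal length")
        if len(self.concentrations) == 0:
            raise ValidationError("dataset must contain at least one point")
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be >= 0")
        if np.any(self.concentrations[1:] <= 0):
            raise ValidationError("only the first concentration may be 0 (baseline)")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValidationError("concentrations must be strictly increasing")
        if np.any(self.effects < 0):
            raise ValidationError("effects must be >= 0")
        for name in ("sems", "n_reps"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float if name == "sems" else int)
                if arr.shape != self.concentrations.shape:
                    raise ValidationError(f"{name} must align with concentrations")
                setattr(self, name, arr)

    @property
    def name(self) -> str:
        return f"{self.agonist} {self.pretreatment}"

    @property
    def fractions(self) -> np.ndarray:
        """Effects on the fractional (0-1) scale."""
        return self.effects / 100.0

    def rescaled(self, factor: float) -> "ECDataset":
        """Return a copy with effects (and SEMs) multiplied by ``factor``."""
        return replace(
            self,
            effects=self.effects * factor,
            sems=None if self.sems is None else self.sems * factor,
        )
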
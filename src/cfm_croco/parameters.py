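"""Aggregate parameter set for a simulation run.

Bundles the environmental response constants, envelope diffusivity, C/N
metabolism constants, Fe translocation schedule and cell-size acclimation
anchors.  ``Parameters.default()`` returns the calibrated configuration
used for the canonical culture conditions (12L:12D, 28 degC, 150 umol
photons m-2 s-1, 20% or 5% O2 aeration).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields, is_dataclass

from .environment import TempLightParams
from .iron import IronSchedule
from .metabolism import CellSizeParams, MetabolicParams
from .oxygen import DiffusivityParams

__all__ = ["Parameters"]


@dataclass
class Parameters:
    """Full parameter set of the cell flux model."""

    temp_light: TempLightParams = field(default_factory=TempLightParams)
    diffusivity: DiffusivityParams = field(default_factory=DiffusivityParams)
    metabolism: MetabolicParams = field(default_factory=MetabolicParams)
    iron: IronSchedule = field(default_factory=IronSchedule)
    cell_size: CellSizeParams = field(default_factory=CellSizeParams)
    fe_total: float = 2.0e-18  # mol Fe cell-1, conserved within the cell

    @classmethod
    def default(cls) -> "Parameters":
        return cls()

    def copy(self) -> "Parameters":
        return copy.deepcopy(self)

    def with_overrides(self, **overrides: float) -> "Parameters":
        """Return a copy with dotted or bare field overrides applied.

        Bare names are searched across the sub-parameter blocks; dotted names
        (``"metabolism.K_CS"``) address a block directly.
        """
        out = self.copy()
        for key, value in overrides.items():
            _set_param(out, key, value)
        return out

    def get(self, key: str) -> float:
        """Look up a parameter by bare or dotted name."""
        holder, name = _resolve(self, key)
        return getattr(holder, name)


def _blocks(p: Parameters):
    for f in fields(p):
        v = getattr(p, f.name)
        if is_dataclass(v):
            yield f.name, v


def _resolve(p: Parameters, key: str):
    if "." in key:
        block, name = key.split(".", 1)
        holder = getattr(p, block)
        if not hasattr(holder, name):
            raise KeyError(f"unknown parameter {key!r}")
        return holder, name
    if hasattr(p, key) and not is_dataclass(getattr(p, key)):
        return p, key
    hits = [(b, v) for b, v in _blocks(p) if hasattr(v, key)]
    if not hits:
        raise KeyError(f"unknown parameter {key!r}")
    if len(hits) > 1:
        names = ", ".join(f"{b}.{key}" for b, _ in hits)
        raise KeyError(f"ambiguous parameter {key!r}; use one of {names}")
    return hits[0][1], key


def _set_param(p: Parameters, key: str, value) -> None:
    holder, name = _resolve(p, key)
    setattr(holder, name, value)
    post = getattr(holder, "__post_init__", None)
    if post is not None:
        post()  # re-validate the block
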
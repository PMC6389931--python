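"""Uniform interface over planar vector fields.

The continuation, Hopf and limit-cycle machinery is written against this thin
wrapper so it runs unchanged on the mosaic model and on the normal-form
benchmark systems.  Parameters are frozen dataclasses; a named parameter is
varied by rebuilding the dataclass, keeping every evaluation pure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Callable

import numpy as np

from . import model
from .model import DerivativeBundle

__all__ = ["PlanarSystem", "mosaic_system", "set_param", "get_param"]


def set_param(p: Any, name: str, value: float) -> Any:
    """Return a copy of the parameter dataclass with one field replaced."""
    return replace(p, **{name: value})


def get_param(p: Any, name: str) -> float:
    return getattr(p, name)


@dataclass(frozen=True)
class PlanarSystem:
    """A planar autonomous ODE with derivative tensors up to third order.

    ``rhs(y, p)`` and ``derivatives(y, p)`` take a length-2 state and a frozen
    parameter dataclass; ``derivatives`` returns a :class:`DerivativeBundle`.
    """

    name: str
    rhs: Callable[[Any, Any], np.ndarray]
    derivatives: Callable[[Any, Any], DerivativeBundle]
    jacobian: Callable[[Any, Any], np.ndarray] | None = None

    def jac(self, y, p) -> np.ndarray:
        if self.jacobian is not None:
            return self.jacobian(y, p)
        return self.derivatives(y, p).jacobian


def mosaic_system() -> PlanarSystem:
    """The forest-grassland mosaic model as a :class:`PlanarSystem`."""
    return PlanarSystem(
        name="mosaic",
        rhs=model.rhs,
        derivatives=model.derivatives,
        jacobian=model.jacobian,
    )
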
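"""Canonical double-gamma hemodynamic response function.

The BOLD impulse response is modelled as the difference of two gamma
densities: a positive response peaking around 5 s and a later, smaller
undershoot.  Parameters follow the common (delay, dispersion)
parameterisation in which the gamma shape is ``delay / dispersion`` and the
scale is the dispersion, so the defaults (6/16 s delays, unit dispersions,
undershoot ratio 1/6, 32 s support) give the widely used canonical kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma

from .errors import ParameterError

__all__ = ["HRFParams", "canonical_hrf"]


@dataclass(frozen=True)
class HRFParams:
    """Parameters of the double-gamma HRF, all in seconds except the ratio.

    ``dt`` is the sampling step of the returned kernel; 1 ms by default so
    that the kernel can be convolved with a 1 kHz stimulus train.
    """

    response_delay: float = 6.0
    undershoot_delay: float = 16.0
    response_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0
    dt: float = 0.001

    def validate(self) -> None:
        for name in (
            "response_delay",
            "undershoot_delay",
            "response_dispersion",
            "undershoot_dispersion",
            "kernel_length",
            "dt",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"HRF parameter {name!r} must be positive")
        if self.undershoot_ratio < 0:
            raise ParameterError("undershoot_ratio must be non-negative")
        if self.kernel_length < self.undershoot_delay:
            raise ParameterError(
                "kernel_length must cover the undershoot delay "
                f"({self.kernel_length} < {self.undershoot_delay})"
            )

    @property
    def n_samples(self) -> int:
        return math.ceil(self.kernel_length / self.dt)


def canonical_hrf(params: HRFParams | None = None) -> np.ndarray:
    """Sample the double-gamma HRF at ``params.dt`` spacing.

    Returns an array of length ``ceil(kernel_length / dt)`` starting at
    t = 0 (where the kernel is exactly 0 for shape > 1).  The kernel is
    normalised so its positive peak equals 1; absolute scale is irrelevant
    downstream because the stimulus series is z-scored.
    """
    params = params or HRFParams()
    params.validate()
    t = np.arange(params.n_samples) * params.dt
    shape1 = params.response_delay / params.response_dispersion
    shape2 = params.undershoot_delay / params.undershoot_dispersion
    kernel = _gamma.pdf(t, shape1, scale=params.response_dispersion)
    if params.undershoot_ratio > 0:
        kernel = kernel - params.undershoot_ratio * _gamma.pdf(
            t, shape2, scale=params.undershoot_dispersion
        )
    peak = kernel.max()
    if peak <= 0:
        raise ParameterError("HRF kernel has no positive peak")
    return kernel / peak
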
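"""Model definition for the generalized Toner-Tu active fluid.

The incompressible velocity field u(x, t) of a dense active suspension
(bacteria, sperm cells) obeys, in nondimensional form,

    dt u + lambda u.grad(u) = -grad(p) - (1 + Lap)^2 u - (alpha + beta |u|^2) u,
    div(u) = 0,

on a doubly periodic square of edge length L.  The Swift-Hohenberg operator
(1 + Lap)^2 drives a linear instability of flow patterns near wavelength
2*pi whenever the activity alpha is sufficiently negative; the cubic term
saturates it.  ``lambda`` (here ``lambda_adv``) models active nematic
stresses through advective self-transport.

The solver integrates the equivalent vorticity form (omega = curl u),
which eliminates the pressure; see :mod:`vortexmelt.solver`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModelParams", "linear_growth_rate"]


@dataclass(frozen=True)
class ModelParams:
    """Nondimensional parameters of one simulation.

    Parameters
    ----------
    lambda_adv : float
        Active advection coefficient (lambda).  Large values correspond to
        strong extensile stresses and favor the active vortex lattice.
    alpha : float
        Activity; negative values drive the Swift-Hohenberg instability.
    beta : float
        Cubic saturation coefficient (> 0); conventionally 0.01.
    L : float
        Domain edge length.  Multiples of 2*pi are recommended so the
        preferred wavelength fits the torus.
    N : int
        Grid points per edge (even, >= 16).
    dt : float
        Time step of the integrator.
    single_precision : bool
        Integrate in float32/complex64 (roughly twice as fast; round-off
        ~1e-7 acts as a tiny seed noise, irrelevant for the statistical
        quantities large ensembles measure).  Default is double.
    """

    lambda_adv: float
    alpha: float
    beta: float = 0.01
    L: float = 20.0 * np.pi
    N: int = 256
    dt: float = 0.005
    single_precision: bool = False

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.N < 16 or self.N % 2:
            raise ValueError(f"N must be even and >= 16, got {self.N}")
        if not self.L > 0:
            raise ValueError(f"L must be > 0, got {self.L}")
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")

    @property
    def dx(self) -> float:
        return self.L / self.N

    @property
    def real_dtype(self):
        return np.float32 if self.single_precision else np.float64

    @property
    def complex_dtype(self):
        return np.complex64 if self.single_precision else np.complex128


def linear_growth_rate(k, alpha):
    """Growth rate sigma(k) = -(1 - k^2)^2 - alpha of a plane-wave mode.

    The most unstable wavenumber is k = 1 (wavelength 2*pi); modes with
    sigma > 0 are linearly unstable.  Accepts scalars or arrays.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("wavenumber magnitude k must be >= 0")
    out = -((1.0 - k**2) ** 2) - alpha
    return out.item() if out.ndim == 0 else out
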
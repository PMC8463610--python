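"""Dealiased pseudo-spectral solver for the vorticity form of the model.

Taking the curl of the velocity equation eliminates the pressure and yields

    dt omega + lambda u.grad(omega) = -(1 + Lap)^2 omega - alpha omega
                                      - beta curl(|u|^2 u),
    dt <u> = -(1 + alpha) <u> - beta <|u|^2 u>,

where omega = dx u_y - dy u_x and <.> is the spatial mean.  The mean
velocity carries the k = 0 mode, which the vorticity cannot see; the mean
vorticity is zero on the torus by construction.

Numerics
--------
* Fourier representation on an N x N grid, stored as the real-transform
  half spectrum (shape ``(N, N//2 + 1)``) so Hermitian symmetry is exact
  by construction.  Nyquist modes are kept at zero.
* Time stepping: classical fourth-order Runge-Kutta combined with an
  integrating factor that propagates the full linear operator
  ``-(1 - k^2)^2 - alpha`` exactly; only the advective and cubic terms are
  treated explicitly.
* Dealiasing: the nonlinear products are evaluated on a 2N grid
  (2x zero padding), which is exact for the cubic nonlinearity.
* Velocity recovery: u = (dy psi, -dx psi) with Lap psi = -omega, plus the
  mean velocity on the zero mode; the discrete divergence vanishes to
  round-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy import fft as sfft

from .model import ModelParams

__all__ = [
    "SpectralState",
    "FieldSnapshot",
    "EnergySeries",
    "BlowupError",
    "init_random",
    "step",
    "run",
    "nonlinear_rhs",
    "velocity_from_vorticity",
    "vorticity_grid",
    "state_from_vorticity",
    "snapshot",
    "energy_density",
    "upscale",
    "upscale_noise_profile",
]

logger = logging.getLogger(__name__)

#: advective stability guard.  The advection operator lambda u.grad has
#: eigenvalues i lambda (u.k), so RK4's imaginary-axis limit 2.83 means
#: max(1, |lambda|) max|u| dt kmax < 2.83, i.e. (with kmax = pi N / L)
#: max(1, |lambda|) max|u| dt N / L < 0.90.  The guard aborts just below
#: that so a violation is caught before the field degrades.
CFL_LIMIT = 0.85


@dataclass
class SpectralState:
    """Evolving solver state: half spectrum of omega, mean velocity, time."""

    omega_hat: np.ndarray  # complex, shape (N, N//2 + 1)
    mean_u: np.ndarray  # float, shape (2,)
    t: float = 0.0

    def copy(self) -> "SpectralState":
        return SpectralState(self.omega_hat.copy(), self.mean_u.copy(), self.t)


@dataclass
class FieldSnapshot:
    """Physical-space snapshot of one instant of a run."""

    omega: np.ndarray  # (N, N) real, indexed [x, y]
    u: np.ndarray  # (N, N, 2) real
    t: float
    params: ModelParams
    seed: int | None = None


@dataclass
class EnergySeries:
    """Kinetic energy density E(t) = <|u|^2>/2 sampled along a run."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("energy density cannot be negative")


class BlowupError(RuntimeError):
    """Raised when the integration leaves its stability region.

    Carries the last finite snapshot (if available) as ``last_snapshot``;
    when raised from :func:`run`, also the energy series collected so far
    as ``partial_energy`` (an :class:`EnergySeries` or None).
    """

    def __init__(self, message: str, last_snapshot: FieldSnapshot | None = None):
        super().__init__(message)
        self.last_snapshot = last_snapshot
        self.partial_energy: "EnergySeries | None" = None


# ----------------------------------------------------------------------
# spectral workspace


class _Workspace:
    """Precomputed grids and integrating factors for one (params) choice."""

    def __init__(self, params: ModelParams):
        N, L, dt = params.N, params.L, params.dt
        self.N, self.M = N, 2 * N
        self.rdtype = params.real_dtype
        self.cdtype = params.complex_dtype
        k0 = 2.0 * np.pi / L
        kx = np.fft.fftfreq(N, d=1.0 / N) * k0  # (N,)
        ky = np.arange(N // 2 + 1) * k0  # (N//2+1,)
        self.KX = kx[:, None].astype(self.rdtype)
        self.KY = ky[None, :].astype(self.rdtype)
        k2 = kx[:, None] ** 2 + ky[None, :] ** 2
        self.k2 = k2
        inv_k2 = np.zeros_like(k2)
        nz = k2 > 0
        inv_k2[nz] = 1.0 / k2[nz]
        self.inv_k2 = inv_k2.astype(self.rdtype)

        # keep-mask: everything except the Nyquist row/column and the mean
        self.mask = np.ones((N, N // 2 + 1), dtype=bool)
        self.mask[N // 2, :] = False
        self.mask[:, N // 2] = False
        self.mask[0, 0] = False

        lin = -((1.0 - k2) ** 2) - params.alpha
        h = dt
        self.E = np.where(self.mask, np.exp(h * lin), 0.0).astype(self.rdtype)
        self.E2 = np.where(self.mask, np.exp(0.5 * h * lin), 0.0).astype(self.rdtype)
        lin_m = -(1.0 + params.alpha)
        self.Em = np.exp(h * lin_m)
        self.Em2 = np.exp(0.5 * h * lin_m)

    # --- padded transforms (2x dealiasing, exact for cubic products) ---

    def to_phys(self, a_hat: np.ndarray) -> np.ndarray:
        N, M = self.N, self.M
        half = N // 2
        out = np.zeros((M, M // 2 + 1), dtype=self.cdtype)
        out[: half + 1, : half + 1] = a_hat[: half + 1, : half + 1]
        out[M - half + 1 :, : half + 1] = a_hat[half + 1 :, : half + 1]
        return sfft.irfft2(out, s=(M, M)) * (M / N) ** 2

    def to_spec(self, a: np.ndarray) -> np.ndarray:
        N, M = self.N, self.M
        half = N // 2
        big = sfft.rfft2(a) * (N / M) ** 2
        out = np.empty((N, N // 2 + 1), dtype=self.cdtype)
        out[: half + 1, :] = big[: half + 1, : half + 1]
        out[half + 1 :, :] = big[M - half + 1 :, : half + 1]
        out[~self.mask] = 0.0
        return out


@lru_cache(maxsize=8)
def _workspace(params: ModelParams) -> _Workspace:
    return _Workspace(params)


def _herm_fix(w: np.ndarray) -> np.ndarray:
    """Re-enforce conjugate symmetry of the ky = 0 column in place.

    In the rfft2 layout that column holds both +kx and -kx entries,
    which must be complex conjugates for the field to be real.  The
    transforms only guarantee this to round-off, and the non-Hermitian
    defect lives in an invisible subspace: the physical-space nonlinear
    terms never touch it, while the integrating factor amplifies it at
    the linear growth rate sigma(k) > 0 — exponential corruption from a
    1e-16 seed unless the constraint is projected out every step.
    """
    c0 = w[:, 0]
    mirror = np.conj(c0[::-1])
    w[:, 0] = 0.5 * (c0 + np.roll(mirror, 1))
    return w


# ----------------------------------------------------------------------
# field recovery and diagnostics


def _uhat(ws: _Workspace, omega_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half spectra of the mean-free velocity from the vorticity spectrum."""
    psi_hat = omega_hat * ws.inv_k2  # Lap psi = -omega
    return 1j * ws.KY * psi_hat, -1j * ws.KX * psi_hat


def velocity_from_vorticity(
    state: SpectralState, params: ModelParams
) -> np.ndarray:
    """Recover the incompressible velocity grid (N, N, 2) from the state."""
    ws = _workspace(params)
    ux_hat, uy_hat = _uhat(ws, state.omega_hat)
    N = params.N
    ux = sfft.irfft2(ux_hat, s=(N, N)) + state.mean_u[0]
    uy = sfft.irfft2(uy_hat, s=(N, N)) + state.mean_u[1]
    return np.stack([ux, uy], axis=-1)


def vorticity_grid(state: SpectralState, params: ModelParams) -> np.ndarray:
    """Physical vorticity field omega(x, y) on the N x N grid."""
    return sfft.irfft2(state.omega_hat, s=(params.N, params.N))


def state_from_vorticity(
    omega: np.ndarray, params: ModelParams, mean_u=(0.0, 0.0), t: float = 0.0
) -> SpectralState:
    """Build a SpectralState from a real vorticity grid (mean removed)."""
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (params.N, params.N):
        raise ValueError(f"omega must be shape {(params.N, params.N)}")
    ws = _workspace(params)
    omega_hat = sfft.rfft2(omega).astype(ws.cdtype)
    omega_hat[~ws.mask] = 0.0
    return SpectralState(_herm_fix(omega_hat), np.asarray(mean_u, dtype=float), t)


def snapshot(
    state: SpectralState, params: ModelParams, seed: int | None = None
) -> FieldSnapshot:
    return FieldSnapshot(
        omega=vorticity_grid(state, params),
        u=velocity_from_vorticity(state, params),
        t=state.t,
        params=params,
        seed=seed,
    )


def energy_density(u: np.ndarray) -> float:
    """Kinetic energy density E = <|u|^2> / 2 of a velocity grid (..., 2)."""
    u = np.asarray(u, dtype=float)
    return 0.5 * float(np.mean(np.sum(u**2, axis=-1)))


# ----------------------------------------------------------------------
# initial conditions


def init_random(
    params: ModelParams,
    seed: int,
    amplitude: float = 0.5,
    kmax_band: float = 2.0,
) -> SpectralState:
    """Band-limited random vorticity with rms ``amplitude``, zero mean flow.

    White Gaussian noise is restricted to the shell |k| <= kmax_band (which
    covers the linearly unstable band for the default) and rescaled so the
    rms vorticity equals ``amplitude`` exactly.  Reproducible given seed.
    """
    if kmax_band <= 0:
        raise ValueError(f"kmax_band must be > 0, got {kmax_band}")
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    ws = _workspace(params)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((params.N, params.N))
    omega_hat = sfft.rfft2(white)
    omega_hat[ws.k2 > kmax_band**2] = 0.0
    omega_hat[~ws.mask] = 0.0
    omega = sfft.irfft2(omega_hat, s=(params.N, params.N))
    rms = np.sqrt(np.mean(omega**2))
    scale = amplitude / rms if rms > 0 else 0.0
    return SpectralState(
        _herm_fix((omega_hat * scale).astype(ws.cdtype)), np.zeros(2), 0.0
    )


# ----------------------------------------------------------------------
# time stepping


def nonlinear_rhs(
    state: SpectralState, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Explicit (non-stiff) part of the right-hand side.

    Returns ``(N_omega_hat, N_mean, umax)`` where ``N_omega_hat`` is the
    spectrum of ``-lambda u.grad(omega) - beta curl(|u|^2 u)``, ``N_mean``
    is ``-beta <|u|^2 u>`` (the nonlinear drag on the mean flow) and
    ``umax`` is max|u| on the dealiasing grid, used by the CFL guard.
    """
    ws = _workspace(params)
    ux_hat, uy_hat = _uhat(ws, state.omega_hat)
    ux = ws.to_phys(ux_hat) + state.mean_u[0]
    uy = ws.to_phys(uy_hat) + state.mean_u[1]
    dox = ws.to_phys(1j * ws.KX * state.omega_hat)
    doy = ws.to_phys(1j * ws.KY * state.omega_hat)
    adv = ux * dox + uy * doy
    u2 = ux * ux + uy * uy
    fx = u2 * ux
    fy = u2 * uy
    adv_hat = ws.to_spec(adv)
    fx_hat = ws.to_spec(fx)
    fy_hat = ws.to_spec(fy)
    lam, beta = params.lambda_adv, params.beta
    n_omega = -lam * adv_hat - beta * (1j * ws.KX * fy_hat - 1j * ws.KY * fx_hat)
    n_mean = -beta * np.array([fx.mean(), fy.mean()])
    umax = float(np.sqrt(u2.max(initial=0.0)))
    return n_omega, n_mean, umax


def _check_finite(state: SpectralState) -> None:
    if not np.all(np.isfinite(state.omega_hat)):
        raise BlowupError("non-finite values in omega_hat (vorticity spectrum)")
    if not np.all(np.isfinite(state.mean_u)):
        raise BlowupError("non-finite values in mean_u (mean velocity)")


def step(state: SpectralState, params: ModelParams) -> SpectralState:
    """Advance one time step dt with integrating-factor RK4.

    The linear operator -(1 - k^2)^2 - alpha (and -(1 + alpha) for the
    mean flow) is propagated exactly via its exponential; the advective
    and cubic terms enter the four explicit Runge-Kutta stages.
    """
    _check_finite(state)
    ws = _workspace(params)
    h = params.dt
    w, m = state.omega_hat, state.mean_u
    E, E2, Em, Em2 = ws.E, ws.E2, ws.Em, ws.Em2

    a_w, a_m, _ = nonlinear_rhs(state, params)
    s1 = SpectralState(E2 * (w + 0.5 * h * a_w), Em2 * (m + 0.5 * h * a_m))
    b_w, b_m, _ = nonlinear_rhs(s1, params)
    s2 = SpectralState(E2 * w + 0.5 * h * b_w, Em2 * m + 0.5 * h * b_m)
    c_w, c_m, _ = nonlinear_rhs(s2, params)
    s3 = SpectralState(E * w + h * E2 * c_w, Em * m + h * Em2 * c_m)
    d_w, d_m, umax = nonlinear_rhs(s3, params)

    w_new = _herm_fix(E * w + (h / 6.0) * (E * a_w + 2.0 * E2 * (b_w + c_w) + d_w))
    m_new = Em * m + (h / 6.0) * (Em * a_m + 2.0 * Em2 * (b_m + c_m) + d_m)
    speed = max(1.0, abs(params.lambda_adv)) * umax
    if speed * h * params.N / params.L > CFL_LIMIT:
        raise BlowupError(
            f"CFL guard tripped: max|u|={umax:.3g} (lambda={params.lambda_adv:g}) "
            f"exceeds the advective stability limit for dt={h}, "
            f"N={params.N}, L={params.L:.4g}"
        )
    return SpectralState(w_new, m_new, state.t + h)


def run(
    params: ModelParams,
    state0: SpectralState,
    T_end: float,
    sample_every: float,
    seed: int | None = None,
    snapshot_every: float | None = None,
    stop_when: Callable[[SpectralState], bool] | None = None,
) -> tuple[EnergySeries, list[FieldSnapshot]]:
    """Integrate to ``T_end``, sampling energy and emitting snapshots.

    Parameters
    ----------
    sample_every : float
        Cadence of the energy-density samples (rounded to whole steps).
        The initial state is always sampled, so ``sample_every == dt``
        yields ``n_steps + 1`` samples.
    snapshot_every : float, optional
        Cadence of full field snapshots.  By default only the final state
        is snapshotted (memory economy); the final state is always included.
    stop_when : callable, optional
        Early-stopping predicate evaluated on the state at every energy
        sample; integration ends at the first sample where it is true.

    Returns
    -------
    (EnergySeries, list of FieldSnapshot)

    Raises
    ------
    BlowupError
        On non-finite values; the exception carries the last finite
        snapshot as ``last_snapshot``.
    """
    if T_end <= state0.t:
        raise ValueError("T_end must exceed the initial time")
    dt = params.dt
    n_steps = int(round((T_end - state0.t) / dt))
    stride = max(1, int(round(sample_every / dt)))
    snap_stride = (
        None if snapshot_every is None else max(1, int(round(snapshot_every / dt)))
    )
    logger.info(
        "run: lambda=%g alpha=%g beta=%g L=%g N=%d dt=%g T_end=%g seed=%s",
        params.lambda_adv, params.alpha, params.beta,
        params.L, params.N, dt, T_end, seed,
    )

    state = state0.copy()
    times = [state.t]
    energies = [energy_density(velocity_from_vorticity(state, params))]
    snaps: list[FieldSnapshot] = []
    if snap_stride is not None:
        snaps.append(snapshot(state, params, seed))
    last_finite = state.copy()

    stopped = False
    for i in range(1, n_steps + 1):
        try:
            state = step(state, params)
        except BlowupError as err:
            err.last_snapshot = snapshot(last_finite, params, seed)
            err.partial_energy = EnergySeries(np.array(times), np.array(energies))
            raise
        if i % stride == 0 or i == n_steps:
            u = velocity_from_vorticity(state, params)
            e = energy_density(u)
            if not np.isfinite(e):
                err = BlowupError(
                    "non-finite energy density",
                    last_snapshot=snapshot(last_finite, params, seed),
                )
                err.partial_energy = EnergySeries(np.array(times), np.array(energies))
                raise err
            times.append(state.t)
            energies.append(e)
            last_finite = state.copy()
            if snap_stride is not None and i % snap_stride == 0:
                snaps.append(snapshot(state, params, seed))
            if stop_when is not None and stop_when(state):
                stopped = True
                break
    if not snaps or snaps[-1].t != state.t:
        snaps.append(snapshot(state, params, seed))
    if stopped:
        logger.info("run: early stop at t=%g", state.t)
    return EnergySeries(np.array(times), np.array(energies)), snaps


# ----------------------------------------------------------------------
# upscaling


def upscale_noise_profile(k):
    """Radial amplitude profile A(k) = k * exp(-(k - 4)^2) of the seed noise.

    Peaked near k = 4, i.e. at scales comparably smaller than the vortex
    scale, so the perturbation breaks the artificial periodicity of the
    tiled field without destroying individual vortices.
    """
    k = np.asarray(k, dtype=float)
    out = k * np.exp(-((k - 4.0) ** 2))
    return out.item() if out.ndim == 0 else out


def upscale(
    state: SpectralState,
    params: ModelParams,
    factor: int = 2,
    noise_scale: float | None = None,
    seed: int = 0,
) -> tuple[SpectralState, ModelParams]:
    """Tile a converged field ``factor x factor`` onto a larger domain.

    The new domain has edge ``factor * L`` and grid ``factor * N``.
    Hermitian random noise with the radial profile
    :func:`upscale_noise_profile` and rms amplitude ``noise_scale``
    (default: 1e-3 times the rms vorticity) is added in spectral space so
    the copies decorrelate.
    """
    if factor not in (2, 8):
        raise ValueError(f"upscale factor must be 2 or 8, got {factor}")
    omega = vorticity_grid(state, params)
    if noise_scale is None:
        noise_scale = 1e-3 * float(np.sqrt(np.mean(omega**2)))
    if noise_scale < 0:
        raise ValueError(f"noise_scale must be >= 0, got {noise_scale}")
    tiled = np.tile(omega, (factor, factor))
    new_params = replace(params, L=factor * params.L, N=factor * params.N)
    ws = _workspace(new_params)
    omega_hat = sfft.rfft2(tiled)
    omega_hat[~ws.mask] = 0.0

    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        white = rng.standard_normal((new_params.N, new_params.N))
        noise_hat = sfft.rfft2(white)
        noise_hat *= upscale_noise_profile(np.sqrt(ws.k2))
        noise_hat[~ws.mask] = 0.0
        noise = sfft.irfft2(noise_hat, s=(new_params.N, new_params.N))
        rms = np.sqrt(np.mean(noise**2))
        if rms > 0:
            omega_hat += noise_hat * (noise_scale / rms)

    return SpectralState(omega_hat, state.mean_u.copy(), state.t), new_params
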
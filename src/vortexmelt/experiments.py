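"""Composite experiment drivers built on the solver and the diagnostics.

These glue functions implement the measurement protocols used throughout
the study: running until a uniform single-polarity lattice has formed
(the 93%-of-capacity criterion), collecting transient-duration
ensembles, and summarizing the crystalline order of a snapshot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import ModelParams
from . import solver as sv
from . import vortexfield as vf
from . import crystal_order as co

__all__ = [
    "OrderSummary",
    "order_summary",
    "run_resilient",
    "measure_transient_duration",
    "transient_ensemble",
    "reference_lattice_spacing",
]

logger = logging.getLogger(__name__)


@dataclass
class OrderSummary:
    """Crystalline-order digest of one vorticity snapshot."""

    n_vortices: int
    n_positive: int
    n_negative: int
    mean_abs_psi6: float
    n_defects: int
    single_polarity: bool

    @classmethod
    def empty(cls) -> "OrderSummary":
        return cls(0, 0, 0, 0.0, 0, False)


def order_summary(
    omega: np.ndarray,
    L: float,
    threshold_frac: float = 0.2,
    min_separation: float = np.pi,
) -> OrderSummary:
    """Detect cores and evaluate polarity balance, psi6 and defect count."""
    vs = vf.detect_vortices(
        omega, L, threshold_frac=threshold_frac, min_separation=min_separation
    )
    n_pos = int((vs.polarity > 0).sum())
    n_neg = int((vs.polarity < 0).sum())
    if len(vs) < 4:
        return OrderSummary(len(vs), n_pos, n_neg, 0.0, 0, n_pos == 0 or n_neg == 0)
    nb = co.periodic_voronoi(vs.positions, L)
    psi = co.psi6_field(vs.positions, nb, L).psi
    defects = co.classify_defects(nb)
    return OrderSummary(
        n_vortices=len(vs),
        n_positive=n_pos,
        n_negative=n_neg,
        mean_abs_psi6=float(np.abs(psi).mean()),
        n_defects=defects.n_defects,
        single_polarity=(n_pos == 0) or (n_neg == 0),
    )


def run_resilient(
    params: ModelParams,
    state0: sv.SpectralState,
    T_end: float,
    sample_every: float,
    stop_when=None,
    max_halvings: int = 3,
):
    """Integrate to ``T_end``, halving dt and resuming after CFL aborts.

    The turbulent phase of a run tolerates a much larger time step than
    the crystallization event, whose packed-lattice amplitudes shrink
    the advective stability region severalfold.  Rather than pricing
    the whole run at the worst-case dt, the integration restarts from
    the last finite snapshot with dt/2 whenever the stability guard
    fires (up to ``max_halvings`` times).  Energy samples from all legs
    are concatenated.

    Returns ``(EnergySeries, final FieldSnapshot, params_of_last_leg)``.
    """
    from dataclasses import replace

    p = params
    state = state0
    times: list[np.ndarray] = []
    values: list[np.ndarray] = []
    for attempt in range(max_halvings + 1):
        try:
            energy, snaps = sv.run(p, state, T_end, sample_every, stop_when=stop_when)
            times.append(energy.times)
            values.append(energy.values)
            t = np.concatenate(times)
            v = np.concatenate(values)
            keep = np.concatenate([[True], np.diff(t) > 0])
            return sv.EnergySeries(t[keep], v[keep]), snaps[-1], p
        except sv.BlowupError as err:
            if err.last_snapshot is None or attempt == max_halvings:
                raise
            if err.partial_energy is not None:
                times.append(err.partial_energy.times)
                values.append(err.partial_energy.values)
            p = replace(p, dt=p.dt / 2)
            snap = err.last_snapshot
            state = sv.state_from_vorticity(
                snap.omega.astype(float), p,
                mean_u=snap.u.reshape(-1, 2).mean(axis=0), t=snap.t,
            )
            logger.info(
                "stability guard fired at t=%.1f; resuming with dt=%g", snap.t, p.dt
            )
    raise AssertionError("unreachable")


def reference_lattice_spacing(
    lambda_adv: float,
    alpha: float,
    L: float,
    N: int,
    dt: float,
    seed: int,
    T_settle: float,
) -> float:
    """Lattice spacing of a converged vortex lattice at these parameters.

    Runs one simulation from random initial conditions for ``T_settle``
    and reads the spacing off the radial spectral peak of the final
    vorticity field.  Used to fix the capacity of the 93% criterion.
    """
    params = ModelParams(lambda_adv, alpha, 0.01, L, N, dt)
    state = sv.init_random(params, seed=seed)
    _, snaps = sv.run(params, state, T_settle, sample_every=max(1.0, 10 * dt))
    return vf.lattice_spacing_from_spectrum(snaps[-1].omega, L)


def measure_transient_duration(
    params: ModelParams,
    seed: int,
    capacity: int,
    fraction: float = 0.93,
    t_max: float = 1500.0,
    check_every: float = 2.0,
    threshold_frac: float = 0.2,
    min_separation: float = np.pi,
    sustain: int = 3,
) -> float | None:
    """Transient time until one polarity reaches ``fraction * capacity``.

    Integrates from a random initial condition, counting strong vortices
    of each sign every ``check_every`` time units; returns the first
    time of a *sustained* crossing (threshold held on ``sustain``
    consecutive checks — the crystal is an absorbing state, while the
    over-detection of a freshly seeded noise field can cross the count
    threshold spuriously for a sample or two).  Returns None if the run
    reaches ``t_max`` unconverged.  CFL aborts are handled by resuming
    with a halved time step (:func:`run_resilient`).
    """
    target = fraction * capacity
    state = sv.init_random(params, seed=seed)
    streak: list[float] = []

    def crossed(s: sv.SpectralState) -> bool:
        omega = np.asarray(sv.vorticity_grid(s, params), dtype=float)
        vs = vf.detect_vortices(
            omega, params.L, threshold_frac=threshold_frac,
            min_separation=min_separation,
        )
        n_pos = int((vs.polarity > 0).sum())
        n_neg = int((vs.polarity < 0).sum())
        if max(n_pos, n_neg) >= target:
            streak.append(s.t)
            return len(streak) >= sustain
        streak.clear()
        return False

    run_resilient(params, state, t_max, sample_every=check_every, stop_when=crossed)
    return streak[0] if len(streak) >= sustain else None


def transient_ensemble(
    params: ModelParams,
    n_runs: int,
    capacity: int,
    seed0: int = 0,
    fraction: float = 0.93,
    t_max: float = 1500.0,
    check_every: float = 2.0,
) -> tuple[np.ndarray, int]:
    """Transient durations for ``n_runs`` random initial conditions.

    Returns ``(durations, n_unconverged)``; unconverged runs (duration
    beyond ``t_max``) are excluded from the returned array.
    """
    durations = []
    n_unconverged = 0
    for k in range(n_runs):
        d = measure_transient_duration(
            params, seed=seed0 + k, capacity=capacity,
            fraction=fraction, t_max=t_max, check_every=check_every,
        )
        if d is None:
            n_unconverged += 1
        else:
            durations.append(d)
        logger.info("transient run %d/%d: T=%s", k + 1, n_runs, d)
    return np.array(durations), n_unconverged
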
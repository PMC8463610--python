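"""Dynamical-state classification on small domains.

On a small torus the system is in exactly one of three states — active
vortex lattice (AVL), active turbulence (AT) or stationary square
flow-lattice — or switches intermittently between AVL and AT near the
coexistence boundary.  Switching shows up as a bimodal probability
density of the kinetic energy density: the packed lattice has high
energy and small fluctuations, turbulence lower energy and large
fluctuations.  The order parameter of the AVL-AT transition is the
fraction of time spent in the AVL state, P(E > E_min), with E_min the
density minimum between the two peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .solver import EnergySeries

__all__ = [
    "EnergyPDF",
    "ScanResult",
    "energy_pdf_analysis",
    "avl_time_fraction",
    "hysteresis_scan",
]


@dataclass
class EnergyPDF:
    """Density estimate of an energy series with peak/valley landmarks."""

    support: np.ndarray
    density: np.ndarray
    peaks: np.ndarray  # energy locations of detected peaks
    e_min: float | None  # inter-peak minimum when exactly two peaks
    degenerate: bool
    burn_in: float

    @property
    def bimodal(self) -> bool:
        return len(self.peaks) == 2


@dataclass
class ScanResult:
    """One branch of a parameter scan of the AVL time fraction."""

    values: np.ndarray  # parameter values in scan order
    order_param: np.ndarray  # T_AVL / T_total per value
    std: np.ndarray
    branch: str  # "increasing" | "decreasing"


def energy_pdf_analysis(
    series: EnergySeries,
    burn_in: float = 200.0,
    prominence_frac: float = 0.05,
    min_samples: int = 1000,
) -> EnergyPDF:
    """Estimate the energy-density PDF and locate its peaks.

    The histogram uses Freedman-Diaconis bins on the post-burn-in
    samples; for peak finding the density is smoothed with a small
    Gaussian (2 bins) and peaks require a prominence of
    ``prominence_frac`` times the peak density.  A near-constant series
    is flagged degenerate (trivially unimodal).
    """
    e = series.values[series.times >= burn_in]
    if e.size < min_samples:
        raise ValueError(
            f"need >= {min_samples} post-burn-in samples, got {e.size}"
        )
    span = np.ptp(e)
    scale = max(np.abs(e).max(), 1.0)
    if span < 1e-10 * scale:
        support = np.array([e.mean()])
        return EnergyPDF(
            support=support,
            density=np.array([np.inf]),
            peaks=support.copy(),
            e_min=None,
            degenerate=True,
            burn_in=burn_in,
        )
    q75, q25 = np.percentile(e, [75, 25])
    iqr = q75 - q25
    fd = 2 * iqr / e.size ** (1 / 3) if iqr > 0 else 0.0
    n_bins = int(np.clip(span / fd if fd > 0 else 64, 16, 512))
    density, edges = np.histogram(e, bins=n_bins, density=True)
    support = 0.5 * (edges[:-1] + edges[1:])
    smooth = ndimage.gaussian_filter1d(density, sigma=2.0, mode="nearest")
    idx, _ = signal.find_peaks(smooth, prominence=prominence_frac * smooth.max())
    # peaks at the support boundary are invisible to find_peaks
    if smooth[0] > smooth[1] and smooth[0] >= prominence_frac * smooth.max():
        idx = np.concatenate([[0], idx])
    if smooth[-1] > smooth[-2] and smooth[-1] >= prominence_frac * smooth.max():
        idx = np.concatenate([idx, [len(smooth) - 1]])
    idx = np.sort(idx)
    peaks = support[idx]
    e_min = None
    if len(idx) == 2:
        between = slice(idx[0], idx[1] + 1)
        e_min = float(support[between][np.argmin(smooth[between])])
    return EnergyPDF(
        support=support,
        density=density,
        peaks=peaks,
        e_min=e_min,
        degenerate=False,
        burn_in=burn_in,
    )


def avl_time_fraction(
    series: EnergySeries,
    pdf: EnergyPDF,
    unimodal_state: str | None = None,
    n_segments: int = 5,
) -> tuple[float, float]:
    """Fraction of time in the AVL state, with a segment-based std.

    For a bimodal PDF this is the empirical probability P(E > E_min).
    For a unimodal PDF the run sits entirely in one state and the caller
    must label it (``unimodal_state`` in {"avl", "at", "square"}); the
    fraction is then 1 or 0 with zero spread.  The standard deviation is
    computed over ``n_segments`` contiguous segments of the post-burn-in
    series.
    """
    e = series.values[series.times >= pdf.burn_in]
    if pdf.e_min is None:
        if pdf.bimodal:
            raise ValueError("bimodal PDF without a located E_min")
        if unimodal_state is None:
            raise ValueError(
                "unimodal energy PDF: provide unimodal_state in "
                "{'avl', 'at', 'square'} to label the run"
            )
        return (1.0, 0.0) if unimodal_state == "avl" else (0.0, 0.0)
    frac = float(np.mean(e > pdf.e_min))
    seg = np.array_split(e, n_segments)
    seg_fracs = np.array([np.mean(s > pdf.e_min) for s in seg if s.size])
    return frac, float(seg_fracs.std())


def hysteresis_scan(
    driver,
    values,
    continuation: bool = True,
) -> tuple[ScanResult, ScanResult]:
    """Run a parameter scan in both directions to expose hysteresis.

    ``driver(value, init_state)`` must run the dynamics at the given
    parameter value, starting from ``init_state`` (None on the first
    value of each branch, otherwise the previous value's final state when
    ``continuation`` is true) and return ``(order_param, std,
    final_state)``.  Bistable dynamics with memory produce branches that
    differ (a hysteresis loop); monostable dynamics give identical
    branches.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty scan")

    def one_branch(vals, branch):
        order, stds = [], []
        state = None
        for i, v in enumerate(vals):
            try:
                op, sd, state_out = driver(v, state)
            except Exception as err:
                raise RuntimeError(
                    f"scan driver failed on {branch} branch at value {v}"
                ) from err
            order.append(op)
            stds.append(sd)
            state = state_out if continuation else None
        return ScanResult(
            values=np.array(vals),
            order_param=np.array(order),
            std=np.array(stds),
            branch=branch,
        )

    up = one_branch(values, "increasing")
    down = one_branch(values[::-1], "decreasing")
    return up, down
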
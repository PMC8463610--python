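"""Synthetic fixtures with exact ground truth for the analysis pipeline.

These generators emulate the statistical structure the diagnostics assume
— triangular vortex lattices with controllable jitter and vacancies,
Gaussian-blob vorticity fields, Poisson point patterns, and trajectory
ensembles with prescribed displacement statistics — without running the
solver.  Every generator returns its ground truth so downstream accuracy
tests have an exact reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .crystal_order import Trajectories
from .vortexfield import VortexSet

__all__ = [
    "LatticeFixture",
    "triangular_lattice_points",
    "vorticity_from_points",
    "gaussian_vortex_field",
    "perturbed_trajectories",
    "poisson_points",
]


@dataclass
class LatticeFixture:
    """A (possibly jittered/defected) triangular lattice on the torus."""

    points: np.ndarray  # (n, 2)
    polarity: np.ndarray  # (n,) +-1
    a: float  # realized lattice spacing
    L: float
    orientation: float
    seed: int
    manifest: dict = field(default_factory=dict)  # vacancies etc.
    adjacency: list | None = None  # ideal 6-neighbor lists (pre-jitter)

    def __len__(self) -> int:
        return len(self.points)

    def as_vortex_set(self, t: float = 0.0) -> VortexSet:
        return VortexSet(
            positions=self.points.copy(),
            polarity=self.polarity.copy(),
            peak_vorticity=self.polarity.astype(float),
            t=t,
            L=self.L,
        )


def triangular_lattice_points(
    L: float,
    a: float,
    orientation: float = 0.0,
    jitter_std: float = 0.0,
    n_vacancies: int = 0,
    seed: int = 0,
    rectangular: bool = False,
) -> LatticeFixture:
    """Triangular lattice on the [0, L)^2 torus, commensurate for orientation 0.

    The requested spacing is rounded to the nearest commensurate value
    (integer columns, even number of rows); the realized spacing is
    reported in the fixture.  An exactly equilateral lattice cannot fit a
    square torus (the row-height ratio sqrt(3)/2 is irrational), so by
    default the rows are slightly compressed to close periodically; with
    ``rectangular=True`` the domain is instead stretched to the exact
    box (nx*a, ny*a*sqrt(3)/2) and the fixture's ``L`` becomes a pair.
    Gaussian positional jitter and random vacancies are applied
    afterwards.  The ideal 6-neighbor adjacency of the pristine lattice
    (restricted to surviving sites) is recorded as ground truth.
    """
    if a > L / 2:
        raise ValueError("lattice spacing a must be <= L/2")
    nx = max(2, int(round(L / a)))
    h = a * np.sqrt(3) / 2
    ny = max(2, int(round(L / h)))
    ny += ny % 2  # even row count for periodic stacking
    if rectangular:
        ax = a
        hy = h
        L = np.array([nx * ax, ny * hy])
    else:
        ax = L / nx
        hy = L / ny
    rng = np.random.default_rng(seed)

    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    x = (ii + 0.5 * (jj % 2)) * ax
    y = jj * hy
    pts = np.column_stack([x.ravel(), y.ravel()])
    n = len(pts)

    def site(i, j):  # flat index with periodic wrap
        return (j % ny) * nx + (i % nx)

    adjacency = []
    for j in range(ny):
        for i in range(nx):
            par = j % 2
            nbrs = [
                site(i - 1, j),
                site(i + 1, j),
                site(i - 1 + par, j - 1),
                site(i + par, j - 1),
                site(i - 1 + par, j + 1),
                site(i + par, j + 1),
            ]
            adjacency.append(sorted(nbrs))

    if orientation != 0.0:
        c, s = np.cos(orientation), np.sin(orientation)
        pts = pts @ np.array([[c, s], [-s, c]]).T

    if jitter_std > 0:
        pts = pts + rng.normal(scale=jitter_std, size=pts.shape)
    pts = np.mod(pts, L)

    vac = np.array([], dtype=int)
    if n_vacancies > 0:
        vac = rng.choice(n, size=n_vacancies, replace=False)
        keep = np.setdiff1d(np.arange(n), vac)
        remap = -np.ones(n, dtype=int)
        remap[keep] = np.arange(len(keep))
        adjacency = [
            [remap[v] for v in adjacency[k] if remap[v] >= 0] for k in keep
        ]
        pts = pts[keep]

    return LatticeFixture(
        points=pts,
        polarity=np.ones(len(pts), dtype=int),
        a=ax,
        L=L,
        orientation=orientation,
        seed=seed,
        manifest={
            "requested_a": a,
            "realized_a": ax,
            "row_height": hy,
            "n_vacancies": int(n_vacancies),
            "vacancy_sites": vac.tolist(),
            "jitter_std": jitter_std,
        },
        adjacency=adjacency,
    )


def gaussian_vortex_field(
    points: np.ndarray,
    polarity: np.ndarray,
    L: float,
    core_radius: float,
    peak: float,
    N: int,
) -> np.ndarray:
    """Periodic superposition of signed Gaussian vorticity blobs.

    Each vortex contributes ``s * peak * exp(-r^2 / (2 core_radius^2))``
    with its minimum-image distance r; blobs are truncated at 5 core
    radii (relative error < 4e-6 of the peak).
    """
    pts = np.asarray(points, dtype=float)
    pol = np.asarray(polarity)
    omega = np.zeros((N, N))
    if peak == 0 or len(pts) == 0:
        return omega
    dx = L / N
    m = int(np.ceil(5 * core_radius / dx))
    off = np.arange(-m, m + 1)
    OI, OJ = np.meshgrid(off, off, indexing="ij")
    for (x, y), s in zip(pts, pol):
        i0 = int(round(x / dx))
        j0 = int(round(y / dx))
        gx = (i0 + OI) * dx
        gy = (j0 + OJ) * dx
        ddx = gx - x - L * np.round((gx - x) / L)
        ddy = gy - y - L * np.round((gy - y) / L)
        blob = s * peak * np.exp(-(ddx**2 + ddy**2) / (2 * core_radius**2))
        np.add.at(omega, ((i0 + OI) % N, (j0 + OJ) % N), blob)
    return omega


def vorticity_from_points(
    fixture: LatticeFixture, core_radius: float, peak: float, N: int
) -> np.ndarray:
    """Vorticity grid emulating detected cores of a lattice fixture."""
    if core_radius >= fixture.a / 2:
        raise ValueError("core_radius must be < a/2 to keep cores resolvable")
    pts = fixture.points
    if len(pts) > 1:
        d = pts[:, None, :] - pts[None, :, :]
        d -= fixture.L * np.round(d / fixture.L)
        r2 = np.sum(d**2, axis=-1)
        np.fill_diagonal(r2, np.inf)
        if r2.min() < (2 * core_radius) ** 2:
            warnings.warn("overlapping vortex cores in fixture", stacklevel=2)
    return gaussian_vortex_field(
        pts, fixture.polarity, fixture.L, core_radius, peak, N
    )


def perturbed_trajectories(
    fixture: LatticeFixture,
    mode: str,
    s: float,
    frames: int,
    seed: int = 0,
    dt: float = 0.1,
) -> Trajectories:
    """Trajectory ensemble with exactly prescribed displacement statistics.

    mode = "rigid": every site translates by the same drift per frame
    (relative displacements vanish, so gamma_L = 0).
    mode = "jitter": iid Gaussian displacement, std ``s`` per component,
    applied independently at every frame including the first
    (gamma_L plateaus at 4 s^2 / a^2).
    mode = "walk": independent Gaussian random walks, step std ``s``
    per component (gamma_L grows linearly with frame count).
    """
    if frames < 2:
        raise ValueError("frames must be >= 2")
    rng = np.random.default_rng(seed)
    x0 = fixture.points
    n = len(x0)
    times = np.arange(frames) * dt
    pos = np.empty((frames, n, 2))
    if mode == "rigid":
        drift = np.array([s, 0.5 * s])
        for f in range(frames):
            pos[f] = x0 + f * drift
    elif mode == "jitter":
        pos[:] = x0[None] + rng.normal(scale=s, size=(frames, n, 2))
    elif mode == "walk":
        steps = rng.normal(scale=s, size=(frames, n, 2))
        steps[0] = 0.0
        pos[:] = x0[None] + np.cumsum(steps, axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Trajectories(
        times=times,
        positions=pos,
        alive=np.ones(n, dtype=bool),
        L=fixture.L,
    )


def poisson_points(
    L: float, n: int, seed: int = 0, min_separation: float = 0.0
) -> np.ndarray:
    """Uniform iid points on the torus; the null model for a liquid.

    With ``min_separation`` > 0, points violating the separation against
    earlier points (periodic) are resampled (simple dart throwing).
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    rng = np.random.default_rng(seed)
    if min_separation <= 0:
        return rng.uniform(0, L, size=(n, 2))
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("min_separation too large for requested n")
        cand = rng.uniform(0, L, size=2)
        ok = True
        for p in pts:
            d = cand - p
            d -= L * np.round(d / L)
            if d @ d < min_separation**2:
                ok = False
                break
        if ok:
            pts.append(cand)
    return np.array(pts)
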
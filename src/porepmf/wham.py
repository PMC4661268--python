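"""Weighted Histogram Analysis Method (WHAM) for 2D umbrella sampling.

Combines the biased (zeta1, zeta2) histograms of many umbrella windows into a
single unbiased potential of mean force. With n_im the count of window i in
bin m, N_i its total count, V_im its bias evaluated at the bin center and
beta = 1/kT, the self-consistent equations are

    p_m  =  sum_i n_im  /  sum_i N_i exp(beta (f_i - V_im))
    exp(-beta f_i)  =  sum_m p_m exp(-beta V_im)

iterated from f_i = 0 until the largest per-iteration change in any window
free energy f_i falls below tolerance. The PMF is F_m = -kT ln p_m, shifted
so its minimum over sampled bins is zero. Unsampled bins are masked (NaN),
never zero-filled, and excluded from minimum/barrier searches.

All sums are evaluated in log space (logsumexp) so that windows restrained
high on the free-energy surface cannot underflow.

The module also provides exchange-symmetrization of the PMF, projection onto
the symmetric-opening diagonal zeta1 = zeta2, and extraction of the closed
minimum, the transition barrier and the opening free energy Delta-G.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from porepmf.constants import kT as thermal_energy
from porepmf.trajectory import RCTrajectory
from porepmf.umbrella import BiasPotential, UmbrellaWindow

DEFAULT_BIN_WIDTH = 0.1  # A
DEFAULT_TOLERANCE = 1e-4  # kcal/mol on max |delta f_i|
DEFAULT_MAX_ITER = 1000
DEFAULT_OPEN_ZETA = 11.5  # A, declared open-state coordinate


class DisconnectedWindowsError(ValueError):
    """A window's sampled region shares no bin with the rest of the set."""


class EmptyProfileError(ValueError):
    """No sampled bins on the requested projection."""


@dataclass
class Histogram2D:
    """Binned (zeta1, zeta2) counts of one window on shared bin edges."""

    edges1: np.ndarray
    edges2: np.ndarray
    counts: np.ndarray
    n_outside: int = 0
    window_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be >= 0")

    @property
    def centers1(self) -> np.ndarray:
        return 0.5 * (self.edges1[:-1] + self.edges1[1:])

    @property
    def centers2(self) -> np.ndarray:
        return 0.5 * (self.edges2[:-1] + self.edges2[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ConvergenceReport:
    """Iteration trace of the WHAM self-consistency loop."""

    iterations: int
    max_delta_f: list[float]
    tolerance: float
    converged: bool


@dataclass
class PMFSurface:
    """2D free-energy grid over (zeta1, zeta2).

    ``values`` holds F in kcal/mol with NaN at unsampled bins; ``sampled`` is
    the corresponding mask. The minimum over sampled bins is zero.
    """

    values: np.ndarray
    sampled: np.ndarray
    centers1: np.ndarray
    centers2: np.ndarray
    bin_width: float
    temperature: float
    window_free_energies: np.ndarray = field(default_factory=lambda: np.empty(0))

    def rezeroed(self) -> "PMFSurface":
        vals = self.values - np.nanmin(self.values)
        return PMFSurface(
            vals,
            self.sampled.copy(),
            self.centers1.copy(),
            self.centers2.copy(),
            self.bin_width,
            self.temperature,
            self.window_free_energies.copy(),
        )


@dataclass
class PMFProfile1D:
    """Free energy along the symmetric-opening diagonal zeta1 = zeta2."""

    zeta: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.zeta) != len(self.values):
            raise ValueError("zeta and values lengths differ")


@dataclass
class StateSummary:
    """Closed minimum, transition barrier and opening free energy of a profile."""

    minimum: tuple[float, float]  # (zeta, F)
    barrier: tuple[float, float] | None  # (zeta, F), absolute profile value
    delta_g_open: float  # F(open zeta) - F(minimum), kcal/mol
    open_zeta: float

    @property
    def barrier_height(self) -> float | None:
        """Barrier relative to the minimum, kcal/mol."""
        if self.barrier is None:
            return None
        return self.barrier[1] - self.minimum[1]


def histogram_windows(
    windows: list,
    bin_width: float = DEFAULT_BIN_WIDTH,
    domain: tuple[float, float] = (8.0, 13.5),
) -> list[Histogram2D]:
    """Bin each window's trajectory on shared edges tiling the domain.

    Accepts :class:`UmbrellaWindow` objects (burn-in already stripped) or bare
    :class:`RCTrajectory` objects. Frames outside the domain are counted in
    ``n_outside``, not silently dropped.
    """
    lo, hi = domain
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = np.linspace(lo, hi, n_bins + 1)

    out = []
    for idx, w in enumerate(windows):
        if isinstance(w, UmbrellaWindow):
            traj, wid = w.trajectory, w.id
        elif isinstance(w, RCTrajectory):
            traj, wid = w, f"w{idx:03d}"
        else:
            raise TypeError(f"cannot histogram {type(w).__name__}")
        if traj is None or len(traj) == 0:
            raise ValueError(f"window {wid} has an empty trajectory")
        counts, _, _ = np.histogram2d(traj.zeta1, traj.zeta2, bins=[edges, edges])
        counts = counts.astype(np.int64)
        out.append(
            Histogram2D(
                edges1=edges,
                edges2=edges,
                counts=counts,
                n_outside=len(traj) - int(counts.sum()),
                window_id=wid,
            )
        )
    return out


def _check_connectivity(sampled_per_window: list[np.ndarray]) -> None:
    if len(sampled_per_window) < 2:
        return
    for i, mine in enumerate(sampled_per_window):
        others = np.zeros_like(mine)
        for j, other in enumerate(sampled_per_window):
            if j != i:
                others |= other
        if not np.any(mine & others):
            raise DisconnectedWindowsError(
                f"window index {i} shares no sampled bin with the other windows"
            )


def wham_solve(
    histograms: list[Histogram2D],
    biases: list[BiasPotential],
    temperature: float = 300.0,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[PMFSurface, ConvergenceReport]:
    """Self-consistent WHAM iteration on shared-binning window histograms.

    Window free energies start at zero (no special initial values are
    needed); each iteration renormalizes the unbiased probabilities and
    updates every f_i, stopping when max |delta f_i| < tolerance. On
    non-convergence at ``max_iter`` the result is still returned with the
    report flagged unconverged.
    """
    if not histograms:
        raise ValueError("need at least one window")
    if len(histograms) != len(biases):
        raise ValueError("one bias per histogram required")
    ref = histograms[0]
    for h in histograms[1:]:
        if not (
            np.array_equal(h.edges1, ref.edges1) and np.array_equal(h.edges2, ref.edges2)
        ):
            raise ValueError("histograms must share bin edges")

    kT = thermal_energy(temperature)
    c1, c2 = ref.centers1, ref.centers2
    grid1, grid2 = np.meshgrid(c1, c2, indexing="ij")
    shape = grid1.shape

    counts = np.stack([h.counts for h in histograms])  # (n_win, n1, n2)
    total = counts.sum(axis=0)
    sampled = total > 0
    _check_connectivity([h.counts > 0 for h in histograms])

    m1, m2 = grid1[sampled], grid2[sampled]
    n_im = counts[:, sampled].astype(float)  # (n_win, n_bins)
    log_ntot = np.log(total[sampled].astype(float))
    log_N = np.log(n_im.sum(axis=1))  # window totals
    # log Boltzmann factors of the biases at sampled bin centers
    A = np.stack([-b.energy(m1, m2) / kT for b in biases])  # (n_win, n_bins)

    g = np.zeros(len(histograms))  # f_i / kT
    trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        log_denom = logsumexp(log_N[:, None] + g[:, None] + A, axis=0)
        log_p = log_ntot - log_denom
        log_p -= logsumexp(log_p)  # normalize: probabilities sum to 1
        g_new = -logsumexp(log_p[None, :] + A, axis=1)
        delta = kT * float(np.max(np.abs(g_new - g)))
        trace.append(delta)
        g = g_new
        if delta < tolerance:
            converged = True
            break

    F = np.full(shape, np.nan)
    F[sampled] = -kT * log_p
    F -= np.nanmin(F)

    surface = PMFSurface(
        values=F,
        sampled=sampled,
        centers1=c1,
        centers2=c2,
        bin_width=float(ref.edges1[1] - ref.edges1[0]) if len(ref.edges1) > 1 else 0.0,
        temperature=temperature,
        window_free_energies=kT * g,
    )
    report = ConvergenceReport(
        iterations=iterations,
        max_delta_f=trace,
        tolerance=tolerance,
        converged=converged,
    )
    return surface, report


def symmetrize(s: PMFSurface) -> PMFSurface:
    """Average the PMF with its exchange mirror F(zeta2, zeta1).

    Where both a bin and its mirror are sampled, their mean is taken; where
    only one is, its value is copied across. Idempotent up to re-zeroing.
    """
    if len(s.centers1) != len(s.centers2) or not np.allclose(s.centers1, s.centers2):
        raise ValueError("symmetrize requires a square grid on identical axes")
    F, Ft = s.values, s.values.T
    samp, sampt = s.sampled, s.sampled.T
    both = samp & sampt
    out = np.full_like(F, np.nan)
    out[both] = 0.5 * (F[both] + Ft[both])
    only_here = samp & ~sampt
    out[only_here] = F[only_here]
    only_there = ~samp & sampt
    out[only_there] = Ft[only_there]
    new = PMFSurface(
        out,
        samp | sampt,
        s.centers1.copy(),
        s.centers2.copy(),
        s.bin_width,
        s.temperature,
        s.window_free_energies.copy(),
    )
    return new.rezeroed()


def project_diagonal(s: PMFSurface) -> PMFProfile1D:
    """Extract F along the symmetric opening line zeta1 = zeta2.

    Returns the sampled bins whose centers satisfy |zeta1 - zeta2| <
    bin_width / 2, ordered by zeta; keeps the parent surface's zero
    reference.
    """
    g1, g2 = np.meshgrid(s.centers1, s.centers2, indexing="ij")
    on_diag = np.abs(g1 - g2) < 0.5 * s.bin_width
    keep = on_diag & s.sampled
    if not np.any(keep):
        raise EmptyProfileError("no sampled bins on the diagonal")
    zeta = 0.5 * (g1[keep] + g2[keep])
    vals = s.values[keep]
    order = np.argsort(zeta)
    return PMFProfile1D(zeta[order], vals[order])


def locate_states(
    p: PMFProfile1D, open_zeta: float = DEFAULT_OPEN_ZETA
) -> StateSummary:
    """Locate the closed minimum, the barrier and the opening free energy.

    The minimum is the profile's global minimum. The barrier is the highest
    interior local maximum strictly between the minimum and the declared
    open-state coordinate (None for a monotone segment). Delta-G_open is
    F(open_zeta) - F(minimum), read at the profile point nearest open_zeta.
    The open-state coordinate is a declared parameter, not auto-detected.
    """
    if len(p.zeta) < 3:
        raise ValueError("profile needs at least 3 points")
    if not p.zeta.min() <= open_zeta <= p.zeta.max():
        raise ValueError(
            f"open zeta {open_zeta} outside profile range "
            f"[{p.zeta.min():.3f}, {p.zeta.max():.3f}]"
        )
    i_min = int(np.argmin(p.values))
    i_open = int(np.argmin(np.abs(p.zeta - open_zeta)))

    lo, hi = sorted((i_min, i_open))
    barrier = None
    best = -np.inf
    for j in range(lo + 1, hi):
        if p.values[j] >= p.values[j - 1] and p.values[j] >= p.values[j + 1]:
            if p.values[j] > best:
                best = p.values[j]
                barrier = (float(p.zeta[j]), float(p.values[j]))

    return StateSummary(
        minimum=(float(p.zeta[i_min]), float(p.values[i_min])),
        barrier=barrier,
        delta_g_open=float(p.values[i_open] - p.values[i_min]),
        open_zeta=open_zeta,
    )
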
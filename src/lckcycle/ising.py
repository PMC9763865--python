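"""Conserved-order-parameter (Kawasaki) Ising model of a lipid mixture.

Ferromagnetic Ising model (coupling J = 1, k_B = 1) on a periodic square
lattice, evolved by Kawasaki-Metropolis spin exchange so the composition
of the two phases is exactly conserved.  The default simulation
temperature 2.28 J/k_B sits just above the exact critical temperature
Tc = 2/ln(1+sqrt(2)) ~= 2.269 J/k_B, in the weak-segregation regime
where composition fluctuations are large but no macroscopic phase
separation occurs.

Protein inclusions are discs of frozen spins imposing a boundary
condition of their preferred phase: disc spins contribute to the
Hamiltonian but are excluded from exchange proposals.  Analyses cover
phase enrichment in annuli around a disc, the bulk correlation length,
and (as an extension) lateral contact statistics of two mobile discs
performing rigid-translation Metropolis moves between Kawasaki sweeps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, FitError

__all__ = [
    "SIM_TEMPERATURE",
    "Lattice",
    "Disc",
    "AnnulusProfile",
    "CorrelationResult",
    "ContactStats",
    "critical_temperature",
    "total_energy",
    "kawasaki_step",
    "run",
    "place_disc",
    "radial_composition",
    "correlation_length",
    "pair_contact_stats",
]

#: default simulation temperature in J/k_B, just above Tc
SIM_TEMPERATURE = 2.28


def critical_temperature() -> float:
    """Exact 2D square-lattice Ising critical temperature, 2/ln(1+sqrt 2)."""
    return 2.0 / math.log(1.0 + math.sqrt(2.0))


def _kernel_py(spins, frozen, sites, dirs, accs, beta):
    """Kawasaki-Metropolis proposals; returns (energy delta, n accepted).

    One entry of ``sites``/``dirs``/``accs`` per proposed exchange: a
    uniformly drawn site, one of its 4 neighbours, and the acceptance
    uniform.  Proposals touching frozen sites or equal spins are no-ops.
    """
    L = spins.shape[0]
    de_total = 0
    n_acc = 0
    for t in range(sites.shape[0]):
        a = sites[t]
        i = a // L
        j = a - i * L
        d = dirs[t]
        if d == 0:
            i2, j2 = (i + 1) % L, j
        elif d == 1:
            i2, j2 = i, (j + 1) % L
        elif d == 2:
            i2, j2 = (i - 1) % L, j
        else:
            i2, j2 = i, (j - 1) % L
        if frozen[i, j] or frozen[i2, j2]:
            continue
        s1 = spins[i, j]
        s2 = spins[i2, j2]
        if s1 == s2:
            continue
        h1 = (spins[(i + 1) % L, j] + spins[(i - 1) % L, j]
              + spins[i, (j + 1) % L] + spins[i, (j - 1) % L] - s2)
        h2 = (spins[(i2 + 1) % L, j2] + spins[(i2 - 1) % L, j2]
              + spins[i2, (j2 + 1) % L] + spins[i2, (j2 - 1) % L] - s1)
        de = 2 * s1 * (h1 - h2)
        if de <= 0 or accs[t] < math.exp(-beta * de):
            spins[i, j] = s2
            spins[i2, j2] = s1
            de_total += de
            n_acc += 1
    return de_total, n_acc


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _kernel = njit(cache=True)(_kernel_py)
except ImportError:  # pragma: no cover
    _kernel = _kernel_py


@dataclass(frozen=True)
class Disc:
    """Frozen (or rigidly mobile) circular inclusion."""

    center: tuple[float, float]
    radius: float
    preferred_phase: int = 1

    def __post_init__(self):
        if self.radius < 0:
            raise ConfigError("disc radius must be >= 0")
        if self.preferred_phase not in (-1, 1):
            raise ConfigError("preferred_phase must be +1 or -1")


class Lattice:
    """Periodic spin field with an immutable inclusion mask.

    ``composition`` is the target fraction of +1 ("black") spins among
    mobile sites; it is restored when discs are placed.
    """

    def __init__(self, spins: np.ndarray, T: float = SIM_TEMPERATURE,
                 seed: int | np.random.Generator = 0,
                 frozen: np.ndarray | None = None,
                 composition: float | None = None):
        spins = np.asarray(spins, dtype=np.int8)
        if spins.ndim != 2 or spins.shape[0] != spins.shape[1]:
            raise ConfigError("spins must be a square 2-D array")
        if not np.isin(spins, (-1, 1)).all():
            raise ConfigError("spins must be +1/-1")
        if T <= 0:
            raise ConfigError("temperature must be positive (use np.inf for T->oo)")
        self.spins = spins
        self.T = float(T)
        self.frozen = (np.zeros(spins.shape, dtype=bool) if frozen is None
                       else np.asarray(frozen, bool).copy())
        self.rng = (seed if isinstance(seed, np.random.Generator)
                    else np.random.default_rng(seed))
        mobile = ~self.frozen
        self.composition = (
            float((spins[mobile] == 1).mean()) if composition is None
            else float(composition))

    @property
    def L(self) -> int:
        return self.spins.shape[0]

    @property
    def beta(self) -> float:
        return 0.0 if math.isinf(self.T) else 1.0 / self.T

    def mobile_magnetization(self) -> int:
        return int(self.spins[~self.frozen].sum())

    def copy(self) -> "Lattice":
        lat = Lattice(self.spins.copy(), T=self.T, seed=self.rng,
                      frozen=self.frozen, composition=self.composition)
        return lat


def total_energy(lattice: Lattice) -> int:
    """Full Hamiltonian E = -J sum_<ij> s_i s_j (includes frozen bonds)."""
    s = lattice.spins.astype(np.int64)
    return int(-(s * np.roll(s, 1, axis=0)).sum()
               - (s * np.roll(s, 1, axis=1)).sum())


def _proposals(lattice: Lattice, n: int):
    sites = lattice.rng.integers(0, lattice.L * lattice.L, n, dtype=np.int64)
    dirs = lattice.rng.integers(0, 4, n, dtype=np.int64)
    accs = lattice.rng.random(n)
    return sites, dirs, accs


def kawasaki_step(lattice: Lattice) -> Lattice:
    """One proposed nearest-neighbour exchange, in place."""
    sites, dirs, accs = _proposals(lattice, 1)
    _kernel(lattice.spins, lattice.frozen, sites, dirs, accs, lattice.beta)
    return lattice


def metropolis_sweeps(lattice: Lattice, n_sweeps: int,
                      max_chunk: int = 64) -> int:
    """Run ``n_sweeps`` sweeps (L^2 proposals each); returns energy delta."""
    steps_left = n_sweeps * lattice.L ** 2
    de = 0
    chunk_cap = max_chunk * lattice.L ** 2
    while steps_left > 0:
        n = min(steps_left, chunk_cap)
        sites, dirs, accs = _proposals(lattice, n)
        d, _ = _kernel(lattice.spins, lattice.frozen, sites, dirs, accs,
                       lattice.beta)
        de += d
        steps_left -= n
    return de


@dataclass
class RunResult:
    lattice: Lattice
    energies: np.ndarray          # energy after each sampling interval
    snapshots: list[np.ndarray]   # spin copies at sampling intervals


def run(lattice: Lattice, n_sweeps: int, sample_every: int | None = None,
        burn_in: int = 0) -> RunResult:
    """Evolve the lattice, recording energy and snapshots.

    ``sample_every`` (sweeps) defaults to no intermediate sampling: only
    the final state is recorded.  Energy is tracked incrementally from
    the kernel's deltas (integer units of J).
    """
    if n_sweeps < 0 or burn_in < 0:
        raise ConfigError("sweep counts must be >= 0")
    if burn_in:
        metropolis_sweeps(lattice, burn_in)
    energy = total_energy(lattice)
    if sample_every is None:
        sample_every = max(n_sweeps, 1)
    energies = []
    snapshots = []
    done = 0
    while done < n_sweeps:
        block = min(sample_every, n_sweeps - done)
        energy += metropolis_sweeps(lattice, block)
        done += block
        energies.append(energy)
        snapshots.append(lattice.spins.copy())
    return RunResult(lattice=lattice,
                     energies=np.asarray(energies, dtype=np.int64),
                     snapshots=snapshots)


def _disc_mask(L: int, disc: Disc) -> np.ndarray:
    yy, xx = np.indices((L, L))
    dy = np.abs(yy - disc.center[0])
    dx = np.abs(xx - disc.center[1])
    dy = np.minimum(dy, L - dy)
    dx = np.minimum(dx, L - dx)
    return dy * dy + dx * dx <= disc.radius ** 2


def place_disc(lattice: Lattice, disc: Disc) -> Lattice:
    """Freeze the disc's sites to its preferred phase, in place.

    The mobile composition is re-balanced to the lattice's target
    concentration by flipping randomly chosen surplus spins.
    """
    mask = _disc_mask(lattice.L, disc)
    if not mask.any():
        raise ConfigError("disc covers no lattice site")
    if (mask & lattice.frozen).any():
        raise ConfigError("disc overlaps an existing inclusion")
    lattice.spins[mask] = disc.preferred_phase
    lattice.frozen |= mask
    _rebalance(lattice)
    return lattice


def _rebalance(lattice: Lattice) -> None:
    mobile = np.flatnonzero(~lattice.frozen.ravel())
    spins = lattice.spins.ravel()
    target_plus = int(round(lattice.composition * mobile.size))
    plus = mobile[spins[mobile] == 1]
    minus = mobile[spins[mobile] == -1]
    if plus.size > target_plus:
        flip = lattice.rng.choice(plus, plus.size - target_plus, replace=False)
        spins[flip] = -1
    elif plus.size < target_plus:
        flip = lattice.rng.choice(minus, target_plus - plus.size, replace=False)
        spins[flip] = 1


@dataclass
class AnnulusProfile:
    """Mean spin versus distance from a disc edge, over an ensemble."""

    bin_centers: np.ndarray
    mean_spin: np.ndarray
    counts: np.ndarray
    bulk_mean: float
    snapshot_means: np.ndarray = field(repr=False, default=None)
    snapshot_bulk: np.ndarray = field(repr=False, default=None)


def radial_composition(snapshots, disc: Disc, frozen: np.ndarray,
                       bin_width: float = 1.0,
                       bulk_min_distance: float | None = None) -> AnnulusProfile:
    """Phase-enrichment profile around a disc.

    Distances are measured from the disc edge (site distance to center
    minus radius) with periodic minimum-image convention; frozen sites
    are excluded; the bulk reference uses sites farther than L/4 from
    the center by default.
    """
    snapshots = [np.asarray(s) for s in snapshots]
    if not snapshots:
        raise ConfigError("need at least one snapshot")
    L = snapshots[0].shape[0]
    yy, xx = np.indices((L, L))
    dy = np.abs(yy - disc.center[0])
    dx = np.abs(xx - disc.center[1])
    dy = np.minimum(dy, L - dy)
    dx = np.minimum(dx, L - dx)
    dist = np.sqrt(dy * dy + dx * dx)
    edge = dist - disc.radius
    mobile = ~np.asarray(frozen, bool)
    if bulk_min_distance is None:
        bulk_min_distance = L / 4.0
    sel = mobile & (edge >= 0)
    bins = np.floor(edge[sel] / bin_width).astype(int)
    n_bins = bins.max() + 1
    stack = np.stack([s[sel] for s in snapshots]).astype(float)
    sums = np.zeros((len(snapshots), n_bins))
    counts = np.bincount(bins, minlength=n_bins)
    if (counts == 0).any():
        raise ConfigError("empty distance bin; increase bin_width")
    for k in range(len(snapshots)):
        sums[k] = np.bincount(bins, weights=stack[k], minlength=n_bins)
    snap_means = sums / counts
    bulk_sel = mobile & (dist >= bulk_min_distance)
    if not bulk_sel.any():
        raise ConfigError("no bulk reference sites beyond bulk_min_distance")
    snap_bulk = np.array([s[bulk_sel].mean() for s in snapshots], float)
    return AnnulusProfile(
        bin_centers=(np.arange(n_bins) + 0.5) * bin_width,
        mean_spin=snap_means.mean(axis=0),
        counts=counts,
        bulk_mean=float(snap_bulk.mean()),
        snapshot_means=snap_means,
        snapshot_bulk=snap_bulk,
    )


@dataclass
class CorrelationResult:
    separation: np.ndarray
    correlation: np.ndarray
    xi: float
    eta: float
    r_squared: float


def correlation_length(snapshots, r_max: float | None = None,
                       eta: float = 0.25) -> CorrelationResult:
    """Radially averaged connected pair correlation and fitted xi.

    The FFT autocorrelation of each (mean-subtracted) snapshot is
    radially averaged and fitted to ``A * r**-eta * exp(-r/xi)`` by a
    linear regression of ``log C + eta*log r`` on r (Ornstein-Zernike
    form with the 2D Ising critical exponent by default).
    """
    snapshots = [np.asarray(s, float) for s in snapshots]
    if len(snapshots) < 50:
        warnings.warn("fewer than 50 snapshots; xi estimate may be noisy")
    L = snapshots[0].shape[0]
    acc = np.zeros((L, L))
    for s in snapshots:
        ds = s - s.mean()
        f = np.fft.fft2(ds)
        acc += np.fft.ifft2(f * np.conj(f)).real / (L * L)
    c2d = acc / len(snapshots)

    idx = np.arange(L)
    d = np.minimum(idx, L - idx)
    rr = np.sqrt(d[:, None] ** 2 + d[None, :] ** 2)
    r_int = np.round(rr).astype(int)
    corr = np.bincount(r_int.ravel(), weights=c2d.ravel()) \
        / np.bincount(r_int.ravel())
    r = np.arange(corr.size, dtype=float)

    if r_max is None:
        r_max = L / 4.0
    # fit only the contiguous positive decay from r=1: beyond the first
    # non-positive value the estimate is noise around zero
    sel = (r >= 1) & (r <= r_max) & (corr > 0)
    first_bad = np.flatnonzero((r >= 1) & (corr <= 0))
    if first_bad.size:
        sel &= r < r[first_bad[0]]
    if sel.sum() < 3:
        raise FitError("too few positive correlation points to fit xi")
    xfit = r[sel]
    yfit = np.log(corr[sel]) + eta * np.log(xfit)
    slope, intercept = np.polyfit(xfit, yfit, 1)
    if slope >= 0:
        raise FitError("non-decaying correlation; xi undefined")
    pred = slope * xfit + intercept
    ss_res = float(((yfit - pred) ** 2).sum())
    ss_tot = float(((yfit - yfit.mean()) ** 2).sum())
    return CorrelationResult(
        separation=r, correlation=corr, xi=float(-1.0 / slope), eta=eta,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0)


@dataclass
class ContactStats:
    separations: np.ndarray   # edge separation per snapshot
    contact_cutoff: float

    @property
    def contact_frequency(self) -> float:
        return float((self.separations <= self.contact_cutoff).mean())


def _periodic_center_distance(a, b, L):
    dy = abs(a[0] - b[0])
    dx = abs(a[1] - b[1])
    return math.hypot(min(dy, L - dy), min(dx, L - dx))


def _attempt_disc_move(lattice: Lattice, discs: list[Disc], which: int) -> None:
    """Rigid unit translation of one disc with Metropolis acceptance.

    Mobile spins covered by the advancing edge are displaced into the
    vacated sites (in index order), so composition is exactly conserved.
    """
    L = lattice.L
    disc = discs[which]
    other = discs[1 - which]
    step_dir = lattice.rng.integers(0, 4)
    dy, dx = ((1, 0), (0, 1), (-1, 0), (0, -1))[step_dir]
    new_center = ((disc.center[0] + dy) % L, (disc.center[1] + dx) % L)
    min_gap = disc.radius + other.radius + 1.0
    if _periodic_center_distance(new_center, other.center, L) < min_gap:
        return
    new_disc = Disc(new_center, disc.radius, disc.preferred_phase)
    old_mask = _disc_mask(L, disc)
    new_mask = _disc_mask(L, new_disc)
    entering = new_mask & ~old_mask
    leaving = old_mask & ~new_mask
    e_before = total_energy(lattice)
    displaced = lattice.spins[entering].copy()
    spins = lattice.spins
    spins[entering] = disc.preferred_phase
    spins[leaving] = displaced  # congruent footprints: same site count
    frozen = lattice.frozen
    frozen[entering] = True
    frozen[leaving] = False
    de = total_energy(lattice) - e_before
    if de <= 0 or lattice.rng.random() < math.exp(-lattice.beta * de):
        discs[which] = new_disc
    else:  # revert
        spins[entering] = displaced
        spins[leaving] = disc.preferred_phase
        frozen[entering] = False
        frozen[leaving] = True


def pair_contact_stats(lattice: Lattice, disc_a: Disc, disc_b: Disc,
                       n_sweeps: int = 500, sample_every: int = 5,
                       burn_in: int = 100, mobile: bool = True,
                       moves_per_sweep: int = 4,
                       contact_cutoff: float = 1.0) -> ContactStats:
    """Lateral proximity statistics of two disc inclusions.

    Discs are placed, then the mixture is evolved by Kawasaki sweeps
    with (optionally) rigid-translation Metropolis moves of the discs
    interleaved; the edge-separation distribution over snapshots and
    the frequency of separations <= ``contact_cutoff`` are returned.
    """
    L = lattice.L
    gap = _periodic_center_distance(disc_a.center, disc_b.center, L) \
        - disc_a.radius - disc_b.radius
    if gap <= 0:
        raise ConfigError("discs overlap")
    if 2 * (disc_a.radius + disc_b.radius + 2) > L:
        raise ConfigError("lattice too small for both discs")
    place_disc(lattice, disc_a)
    place_disc(lattice, disc_b)
    discs = [disc_a, disc_b]

    def one_sweep_block(n):
        for _ in range(n):
            metropolis_sweeps(lattice, 1)
            if mobile:
                for _ in range(moves_per_sweep):
                    which = int(lattice.rng.integers(0, 2))
                    _attempt_disc_move(lattice, discs, which)

    one_sweep_block(burn_in)
    seps = []
    done = 0
    while done < n_sweeps:
        block = min(sample_every, n_sweeps - done)
        one_sweep_block(block)
        done += block
        d = _periodic_center_distance(discs[0].center, discs[1].center, L)
        seps.append(d - discs[0].radius - discs[1].radius)
    return ContactStats(separations=np.asarray(seps),
                        contact_cutoff=contact_cutoff)
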
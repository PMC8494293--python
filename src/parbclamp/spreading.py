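"""1D lattice simulation of clamp loading at parS, sliding, and unloading.

Clamps are injected at the parS site at a constant loading rate, perform an
unbiased continuous-time random walk in 1-bp steps (hop rate ``D`` per
direction, so the macroscopic diffusion coefficient is ``D`` bp^2/s), and are
removed at the effective unloading rate ``k_off * (1 - p_retain)`` — each
hydrolysis event either unloads the clamp or, with the CTP re-capture
probability ``p_retain``, exchanges nucleotide in place and leaves it sliding.
The steady-state occupancy is then a two-sided exponential of decay length
``lambda = sqrt(D / k_off_eff)`` around parS; with unloading switched off
(hydrolysis-dead mutant mode) no steady state exists and the profile broadens
without bound as ``sqrt(2 D t)``.

Roadblocks (reflecting or absorbing lattice sites) model encounters with
transcription/replication machinery and produce asymmetric profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class Roadblock:
    position: int
    behavior: str = "reflect"  # or "absorb"

    def __post_init__(self) -> None:
        if self.behavior not in ("reflect", "absorb"):
            raise ValueError("roadblock behavior must be 'reflect' or 'absorb'")


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry and rates for the spreading simulation.

    Coordinates are 0-based; the window is [0, length_bp).  ``loading_rate``
    is clamps/s injected at parS, ``k_off`` the per-clamp hydrolysis-driven
    unloading attempt rate (use 0 for hydrolysis-dead mutants), ``p_retain``
    the probability that a hydrolysis event exchanges nucleotide without
    unloading.  ``initial_clamps`` places a bolus at parS at t=0, handy for
    pure-diffusion (mutant) runs.
    """

    length_bp: int
    parS_bp: int
    diffusion: float  # bp^2/s
    loading_rate: float  # clamps/s at parS
    k_off: float = 0.0  # per clamp per s
    p_retain: float = 0.0
    roadblocks: tuple = ()
    boundary: tuple = ("reflect", "reflect")
    exclusion: bool = False
    initial_clamps: int = 0

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be > 0")
        if not (0 <= self.parS_bp < self.length_bp):
            raise ValueError("parS_bp must lie inside the window")
        if self.diffusion < 0 or self.loading_rate < 0 or self.k_off < 0:
            raise ValueError("diffusion, loading_rate and k_off must be >= 0")
        if not (0.0 <= self.p_retain <= 1.0):
            raise ValueError("p_retain must be in [0, 1]")
        for rb in self.roadblocks:
            if not (0 <= rb.position < self.length_bp):
                raise ValueError("roadblock positions must lie inside the window")
        for side in self.boundary:
            if side not in ("reflect", "absorb"):
                raise ValueError("boundary behavior must be 'reflect' or 'absorb'")
        if self.initial_clamps < 0:
            raise ValueError("initial_clamps must be >= 0")

    @property
    def k_off_effective(self) -> float:
        """Unloading rate after discounting in-place nucleotide exchange."""
        return self.k_off * (1.0 - self.p_retain)

    @property
    def decay_length(self) -> float:
        """Continuum decay length sqrt(D/k_off_eff) in bp (inf if no unloading)."""
        k = self.k_off_effective
        if k == 0:
            return math.inf
        return math.sqrt(self.diffusion / k)


@dataclass(frozen=True)
class OccupancyProfile:
    """Mean clamp occupancy per bin; bins are 0-based half-open and tile the window."""

    starts: np.ndarray
    bin_size: int
    occupancy: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "occupancy", occ)
        if len(starts) != len(occ):
            raise ValueError("starts and occupancy differ in length")
        if (occ < 0).any():
            raise ValueError("occupancy must be >= 0")
        if len(starts) > 1 and not (np.diff(starts) > 0).all():
            raise ValueError("bin starts must be strictly increasing")

    @property
    def ends(self) -> np.ndarray:
        ends = np.empty_like(self.starts)
        ends[:-1] = self.starts[1:]
        ends[-1] = self.metadata.get("length_bp", self.starts[-1] + self.bin_size)
        return ends

    @property
    def centers(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    @property
    def total(self) -> float:
        return float(self.occupancy.sum())


def _hash_config(config: LatticeConfig) -> str:
    import hashlib

    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def simulate_profile(
    config: LatticeConfig,
    t_end: float,
    seed: int,
    burn_in: Optional[float] = None,
    average: bool = True,
) -> OccupancyProfile:
    """Event-driven exact simulation of the lattice model.

    Returns the time-averaged occupancy over ``[burn_in, t_end]`` when
    ``average`` is true (steady-state readout; default burn-in is
    ``min(10 / k_off_eff, t_end / 2)``, or ``t_end / 2`` without unloading),
    otherwise the terminal snapshot (transient readout, e.g. for tracking the
    sqrt(2 D t) broadening of a mutant bolus).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    rng = np.random.default_rng(seed)
    L = config.length_bp
    hop = config.diffusion  # per-direction hop rate for 1-bp steps
    k_off = config.k_off_effective
    load = config.loading_rate

    if burn_in is None:
        if not average:
            burn_in = 0.0
        elif k_off > 0:
            burn_in = min(10.0 / k_off, 0.5 * t_end)
        else:
            burn_in = 0.5 * t_end
    if burn_in >= t_end:
        raise ValueError("burn_in must be < t_end")

    reflect = {rb.position for rb in config.roadblocks if rb.behavior == "reflect"}
    absorb = {rb.position for rb in config.roadblocks if rb.behavior == "absorb"}
    if config.parS_bp in reflect | absorb:
        raise ValueError("a roadblock cannot sit on parS itself")

    count = np.zeros(L, dtype=np.int64)
    acc = np.zeros(L, dtype=float)
    last = np.zeros(L, dtype=float)

    def touch(site: int, t: float) -> None:
        lo = last[site]
        if t > burn_in and count[site] > 0:
            acc[site] += count[site] * (min(t, t_end) - max(lo, burn_in))
        last[site] = t

    positions: list = []
    count[config.parS_bp] = config.initial_clamps
    positions.extend([config.parS_bp] * config.initial_clamps)

    per_clamp = 2.0 * hop + k_off
    t = 0.0
    capped = False
    block = rng.random(131072)
    bi = len(block)
    while True:
        n = len(positions)
        load_open = load
        if config.exclusion and count[config.parS_bp] > 0 and load > 0:
            load_open = 0.0  # injection blocked while parS occupied
            capped = True
        total = n * per_clamp + load_open
        if total <= 0:
            break
        if bi + 2 > len(block):
            block = rng.random(131072)
            bi = 0
        u1, u2 = block[bi], block[bi + 1]
        bi += 2
        t += -math.log1p(-u1) / total
        if t >= t_end:
            break
        x = u2 * total
        if x < load_open:
            touch(config.parS_bp, t)
            count[config.parS_bp] += 1
            positions.append(config.parS_bp)
            continue
        x -= load_open
        i = int(x / per_clamp)
        if i >= n:  # guard against round-off at the boundary
            i = n - 1
        sub = x - i * per_clamp
        pos = positions[i]
        if sub < k_off:
            # unloading
            touch(pos, t)
            count[pos] -= 1
            positions[i] = positions[-1]
            positions.pop()
            continue
        step = -1 if (sub - k_off) < hop else 1
        target = pos + step
        if target < 0:
            if config.boundary[0] == "reflect":
                continue
            touch(pos, t)
            count[pos] -= 1
            positions[i] = positions[-1]
            positions.pop()
            continue
        if target >= L:
            if config.boundary[1] == "reflect":
                continue
            touch(pos, t)
            count[pos] -= 1
            positions[i] = positions[-1]
            positions.pop()
            continue
        if target in reflect:
            continue
        if target in absorb:
            touch(pos, t)
            count[pos] -= 1
            positions[i] = positions[-1]
            positions.pop()
            continue
        if config.exclusion and count[target] > 0:
            continue
        touch(pos, t)
        touch(target, t)
        count[pos] -= 1
        count[target] += 1
        positions[i] = target

    if capped:
        warnings.warn(
            "exclusion capped injection: parS was occupied during part of the run",
            RuntimeWarning,
            stacklevel=2,
        )

    meta = {
        "config_hash": _hash_config(config),
        "seed": seed,
        "t_end": t_end,
        "burn_in": burn_in,
        "length_bp": L,
        "mode": "time-average" if average else "terminal",
    }
    if average:
        for site in np.nonzero(count)[0]:
            touch(int(site), t_end)
        occ = acc / (t_end - burn_in)
    else:
        occ = count.astype(float)
    return OccupancyProfile(starts=np.arange(L, dtype=np.int64), bin_size=1, occupancy=occ, metadata=meta)


def _discrete_decay_ratio(hop: float, k: float) -> float:
    """Per-site geometric ratio of the discrete diffusion-decay steady state.

    Solves hop*(r + 1/r) = 2*hop + k for the root in (0, 1); equals
    exp(-1/lambda) in the continuum limit k << hop.
    """
    a = 1.0 + k / (2.0 * hop)
    return a - math.sqrt(a * a - 1.0)


def analytic_profile(config: LatticeConfig) -> OccupancyProfile:
    """Closed-form steady-state profile for the free (no-exclusion) lattice.

    Valid only with positive effective unloading, no exclusion, and no
    roadblocks, on a window whose edges are many decay lengths from parS; the
    boundary condition is then irrelevant and the profile is the two-sided
    geometric ``n_j = n_0 r^{|j|}`` with the exact lattice ratio ``r``.  The
    amplitude follows from injection balance and the total clamp number is
    exactly ``loading_rate / k_off_eff``.
    """
    k = config.k_off_effective
    if k <= 0:
        raise ValueError("analytic_profile requires k_off_effective > 0")
    if config.exclusion:
        raise ValueError("analytic_profile is only valid without exclusion")
    if config.roadblocks:
        raise ValueError("analytic_profile is only valid without roadblocks")
    if config.diffusion <= 0:
        raise ValueError("analytic_profile requires diffusion > 0")
    hop = config.diffusion
    r = _discrete_decay_ratio(hop, k)
    j = np.abs(np.arange(config.length_bp, dtype=np.int64) - config.parS_bp)
    # injection balance at the source site: load = n0 * (2 hop + k - 2 hop r)
    n0 = config.loading_rate / (2.0 * hop + k - 2.0 * hop * r)
    occ = n0 * np.power(r, j.astype(float))
    meta = {
        "config_hash": _hash_config(config),
        "length_bp": config.length_bp,
        "decay_ratio": r,
        "decay_length": config.decay_length,
        "mode": "analytic",
    }
    return OccupancyProfile(
        starts=np.arange(config.length_bp, dtype=np.int64), bin_size=1, occupancy=occ, metadata=meta
    )


def peak_width(profile: OccupancyProfile, method: str = "fwhm", q: float = 0.95) -> float:
    """Width of the occupancy peak in bp.

    ``fwhm``: distance between the outermost half-maximum crossings, linearly
    interpolated between bin centers (a two-sided exponential of decay length
    lambda gives 2*lambda*ln 2).  ``central-mass``: length of the smallest
    peak-containing run of bins holding fraction ``q`` of total occupancy,
    grown greedily from the maximum bin.
    """
    occ = profile.occupancy
    peak = occ.max()
    if peak <= 0 or np.allclose(occ, occ[0]):
        raise ValueError("profile is flat: peak width undefined")
    if method == "fwhm":
        half = peak / 2.0
        above = occ >= half
        idx = np.nonzero(above)[0]
        first, last_i = idx[0], idx[-1]
        x = profile.centers.astype(float)
        left = x[first]
        if first > 0:
            y0, y1 = occ[first - 1], occ[first]
            left = x[first - 1] + (half - y0) / (y1 - y0) * (x[first] - x[first - 1])
        right = x[last_i]
        if last_i < len(occ) - 1:
            y0, y1 = occ[last_i], occ[last_i + 1]
            right = x[last_i] + (y0 - half) / (y0 - y1) * (x[last_i + 1] - x[last_i])
        return float(max(right - left, profile.bin_size))
    if method == "central-mass":
        if not (0 < q <= 1):
            raise ValueError("q must be in (0, 1]")
        total = occ.sum()
        lo = hi = int(np.argmax(occ))
        mass = occ[lo]
        while mass < q * total:
            left_val = occ[lo - 1] if lo > 0 else -1.0
            right_val = occ[hi + 1] if hi < len(occ) - 1 else -1.0
            if left_val < 0 and right_val < 0:
                break
            if left_val >= right_val:
                lo -= 1
                mass += occ[lo]
            else:
                hi += 1
                mass += occ[hi]
        return float((hi - lo + 1) * profile.bin_size)
    raise ValueError(f"unknown width method {method!r}")


def bin_profile(profile: OccupancyProfile, bin_size: int) -> OccupancyProfile:
    """Sum occupancy into half-open bins of ``bin_size`` bp (1 kb by default
    in ChIP-style post-processing).

    ``bin_size`` must be a multiple of the current bin size; a trailing
    partial bin is kept so total occupancy is conserved.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if bin_size % profile.bin_size != 0:
        raise ValueError("bin_size must be a multiple of the current bin size")
    factor = bin_size // profile.bin_size
    if factor == 1:
        return profile
    n = len(profile.occupancy)
    n_bins = math.ceil(n / factor)
    occ = np.zeros(n_bins, dtype=float)
    for b in range(n_bins):
        occ[b] = profile.occupancy[b * factor : (b + 1) * factor].sum()
    starts = profile.starts[::factor]
    meta = dict(profile.metadata)
    return OccupancyProfile(starts=starts, bin_size=bin_size, occupancy=occ, metadata=meta)
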
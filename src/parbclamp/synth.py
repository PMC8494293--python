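"""Seeded generators of synthetic assay data with embedded ground truth.

Each generator mirrors the measurement it emulates — Wiseman-shaped injection
heats, plateau-then-exponential sensor traces, linear phosphate accumulation,
Poisson per-bin ChIP-like read counts — adds noise from an explicit
:class:`NoiseSpec`, and records the generating parameters and seed in the
output metadata so fitters can be tested as round trips.  Seeds are mandatory:
no generator touches global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from parbclamp.assays import (
    PhosphateTimeCourse,
    SensorTrace,
    TitrationExperiment,
    injection_heats,
    make_itc_schedule,
)
from parbclamp.spreading import OccupancyProfile


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: gaussian-additive / gaussian-relative / poisson.

    ``scale`` is the standard deviation (additive), the relative standard
    deviation (relative), or ignored (poisson: the mean sets the variance).
    """

    model: str
    scale: float
    seed: int

    def __post_init__(self) -> None:
        if self.model not in ("gaussian-additive", "gaussian-relative", "poisson"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, clean: np.ndarray, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        rng = rng or self.rng()
        clean = np.asarray(clean, dtype=float)
        if self.model == "gaussian-additive":
            return clean + rng.normal(0.0, self.scale, clean.shape)
        if self.model == "gaussian-relative":
            return clean * (1.0 + rng.normal(0.0, self.scale, clean.shape))
        return rng.poisson(np.clip(clean, 0.0, None)).astype(float)


def gen_itc(
    K: float,
    dh: float,
    noise: NoiseSpec,
    schedule: Optional[TitrationExperiment] = None,
) -> TitrationExperiment:
    """Synthetic titration: heats = injection_heats(truth) + noise.

    The default schedule is the standard 280-uL cell at 100 uM protein with a
    2 mM syringe, 20 x 2 uL injections.
    """
    sched = schedule if schedule is not None else make_itc_schedule()
    clean = injection_heats(sched, K, dh)
    heats = noise.apply(clean)
    meta = {"truth": {"K": K, "Kd": 1.0 / K, "dH": dh}, "noise": noise, "seed": noise.seed}
    return TitrationExperiment(
        vo=sched.vo, dv=sched.dv, mt=sched.mt, xt=sched.xt, heats=heats, metadata=meta
    )


def gen_bli(
    k_app: float,
    amplitude: float,
    noise: NoiseSpec,
    offset: float = 0.0,
    baseline_s: float = 30.0,
    association_s: float = 120.0,
    dissociation_s: float = 300.0,
    dt: float = 1.0,
) -> SensorTrace:
    """Synthetic sensor trace: baseline, association plateau, exponential decay.

    The default 5-min dissociation window matches common practice for clamp
    unloading measurements.  The association phase is rendered as a saturating
    rise to ``amplitude`` (its exact shape is not fit); the dissociation phase
    is ``amplitude * exp(-k_app t) + offset`` plus noise.
    """
    if dissociation_s <= 0 or dt <= 0:
        raise ValueError("phase durations and dt must be > 0")
    t_base = np.arange(0.0, baseline_s, dt)
    t_assoc = np.arange(0.0, association_s, dt)
    t_diss = np.arange(0.0, dissociation_s + dt / 2, dt)
    rng = noise.rng()

    y_base = np.full_like(t_base, offset)
    k_rise = 5.0 / max(association_s, dt)  # reaches plateau well within the phase
    y_assoc = offset + amplitude * (1.0 - np.exp(-k_rise * t_assoc))
    y_diss = offset + amplitude * np.exp(-k_app * t_diss)

    times = np.concatenate([t_base, baseline_s + t_assoc, baseline_s + association_s + t_diss])
    clean = np.concatenate([y_base, y_assoc, y_diss])
    signal = noise.apply(clean, rng)
    phases = np.array(
        ["baseline"] * len(t_base) + ["association"] * len(t_assoc) + ["dissociation"] * len(t_diss),
        dtype=object,
    )
    meta = {
        "truth": {"k_app": k_app, "amplitude": amplitude, "offset": offset},
        "noise": noise,
        "seed": noise.seed,
    }
    return SensorTrace(times=times, signal=signal, phases=phases, metadata=meta)


def gen_ctpase(
    rate_per_min: float,
    noise: NoiseSpec,
    protein_conc: float = 10.0,
    duration_min: float = 60.0,
    n_points: int = 13,
    substrate_um: float = 1000.0,
) -> PhosphateTimeCourse:
    """Synthetic phosphate time course: linear accumulation, capped at substrate.

    Defaults mirror the standard assay conditions (10 uM protein, 1 mM CTP,
    1-h incubation).  Phosphate follows ``rate * [protein] * t`` until the
    substrate is exhausted.
    """
    if duration_min <= 0:
        raise ValueError("duration must be > 0")
    t = np.linspace(0.0, duration_min, n_points)
    clean = np.minimum(rate_per_min * protein_conc * t, substrate_um)
    pi = np.clip(noise.apply(clean), 0.0, None)
    meta = {
        "truth": {"rate_per_min": rate_per_min},
        "noise": noise,
        "seed": noise.seed,
        "substrate_um": substrate_um,
    }
    return PhosphateTimeCourse(times=t, protein_conc=protein_conc, phosphate=pi, metadata=meta)


def gen_chip_counts(
    profile: OccupancyProfile,
    depth: float,
    noise: NoiseSpec,
    background: Optional[float] = None,
) -> tuple[OccupancyProfile, OccupancyProfile]:
    """ChIP-like per-bin Poisson read counts: (IP track, flat control track).

    IP counts are Poisson with mean ``depth * (background + occupancy)``;
    the control is Poisson with mean ``depth * background``.  ``background``
    defaults to 10% of the peak occupancy (a free parameter: real input
    samples set it empirically).  The ratio IP/control recovers the profile
    shape as depth grows.
    """
    if noise.model != "poisson":
        raise ValueError("gen_chip_counts requires a poisson NoiseSpec")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    occ = profile.occupancy
    if background is None:
        background = 0.1 * occ.max() if occ.max() > 0 else 1.0
    rng = noise.rng()
    ip = rng.poisson(depth * (background + occ)).astype(float)
    ctrl = rng.poisson(np.full_like(occ, depth * background)).astype(float)
    meta = {
        "truth": {"depth": depth, "background": background},
        "noise": noise,
        "seed": noise.seed,
        "source": profile.metadata,
    }
    ip_prof = OccupancyProfile(
        starts=profile.starts, bin_size=profile.bin_size, occupancy=ip,
        metadata={**meta, "track": "IP", "length_bp": profile.metadata.get("length_bp")},
    )
    ctrl_prof = OccupancyProfile(
        starts=profile.starts, bin_size=profile.bin_size, occupancy=ctrl,
        metadata={**meta, "track": "control", "length_bp": profile.metadata.get("length_bp")},
    )
    return ip_prof, ctrl_prof


def ratio_track(ip: OccupancyProfile, control: OccupancyProfile, pseudocount: float = 1.0) -> OccupancyProfile:
    """IP/control ratio track with a pseudocount, minus its own baseline.

    Subtracting the median ratio leaves a background-free peak suitable for
    width estimation on noisy count data.
    """
    ratio = (ip.occupancy + pseudocount) / (control.occupancy + pseudocount)
    ratio = np.clip(ratio - np.median(ratio), 0.0, None)
    return OccupancyProfile(
        starts=ip.starts, bin_size=ip.bin_size, occupancy=ratio,
        metadata={**ip.metadata, "track": "ratio"},
    )
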
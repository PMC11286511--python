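"""Stochastic fibre-disassembly simulator and single-fibre trace estimators.

A fibre is a contiguous run of subunits (0.84 nm axial rise per subunit by
default).  Two processes shorten it, both modulated by a pH coupling factor:

* end depolymerization — every active fragment end sheds subunits as a
  Poisson process at ``k_end`` subunits/min per end;
* fragmentation — every subunit-subunit junction breaks at ``k_frag``/min,
  after which all fragment ends are active.

The default coupling is the disassembled-state Boltzmann weight of the
equilibrium linkage model, ``10**x / (1 + 10**x)`` with
``x = n_sites * (pKa_eff - pH)``: it saturates at 1 far below the transition
and vanishes above it, reproducing the observed fast-below / stable-above
behaviour around the transition pH.  A bare exponential law is available as
an alternative.

Simulation is exact event-driven sampling (Ogata thinning against the
coupling's supremum over the pH schedule), so there is no time-discretization
error; the recording grid is independent of the event process.  Traces follow
the microscopy conventions: fibre length is the longest remaining fragment,
and each physical end's recession is measured toward the centre of the
initial fibre (half the initial length), saturating there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "PhSchedule",
    "PhCoupling",
    "KineticParams",
    "FibreState",
    "FibreTrace",
    "RateEstimate",
    "EnsembleSummary",
    "coupling",
    "simulate_fibre",
    "simulate_ensemble",
    "estimate_rate",
    "per_end_recession",
    "ensemble_summary",
]

RISE_NM = 0.84  # axial rise per subunit, nm (8.4 Å)


@dataclass(frozen=True)
class PhSchedule:
    """Time-varying pH: constant, step, or exponential approach.

    * constant: pH = ph_start everywhere.
    * step: ph_start before ``switch_time`` min, ph_end after.
    * exponential: after ``switch_time``, pH relaxes from ph_start to ph_end
      with time constant ``tau`` min (a proxy for photoacid activation or
      buffer exchange; the photochemistry itself is out of scope).
    """

    ph_start: float
    ph_end: float | None = None
    switch_time: float = 0.0
    tau: float | None = None
    mode: str = "constant"

    def __post_init__(self):
        for v in (self.ph_start, self.ph_end):
            if v is not None and not (0.0 < v < 14.0):
                raise ValidationError(f"pH {v} outside (0, 14)")
        if self.mode not in ("constant", "step", "exponential"):
            raise ValidationError(f"unknown schedule mode {self.mode!r}")
        if self.mode != "constant" and self.ph_end is None:
            raise ValidationError(f"{self.mode} schedule requires ph_end")
        if self.mode == "exponential" and (self.tau is None or self.tau <= 0):
            raise ValidationError("exponential schedule requires tau > 0")

    @classmethod
    def constant(cls, ph: float) -> "PhSchedule":
        return cls(ph_start=ph, mode="constant")

    @classmethod
    def step(cls, ph_start: float, ph_end: float, switch_time: float) -> "PhSchedule":
        return cls(ph_start=ph_start, ph_end=ph_end, switch_time=switch_time, mode="step")

    @classmethod
    def exponential(
        cls, ph_start: float, ph_end: float, switch_time: float, tau: float
    ) -> "PhSchedule":
        return cls(
            ph_start=ph_start, ph_end=ph_end, switch_time=switch_time, tau=tau,
            mode="exponential",
        )

    def at(self, t: float) -> float:
        if self.mode == "constant" or t < self.switch_time:
            return self.ph_start
        if self.mode == "step":
            return float(self.ph_end)
        decay = np.exp(-(t - self.switch_time) / self.tau)
        return float(self.ph_end + (self.ph_start - self.ph_end) * decay)

    def min_ph(self) -> float:
        """Infimum of pH over all times (the coupling supremum sits here)."""
        if self.mode == "constant":
            return self.ph_start
        return min(self.ph_start, float(self.ph_end))


@dataclass(frozen=True)
class PhCoupling:
    """Rate-multiplier law linking solution pH to disassembly kinetics."""

    law: str = "linkage"  # or "exponential"
    pKa_eff: float = 3.25
    n_sites: int = 6

    def __post_init__(self):
        if self.law not in ("linkage", "exponential"):
            raise ValidationError(f"unknown coupling law {self.law!r}")
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")


def coupling(ph: float | np.ndarray, law: PhCoupling) -> float | np.ndarray:
    """Dimensionless rate multiplier at the given pH (>= 0).

    linkage: 10**x / (1 + 10**x), x = n_sites * (pKa_eff - pH) — the
    disassembled-state Boltzmann weight, in [0, 1].
    exponential: bare 10**x (unbounded below pKa_eff).
    """
    x = law.n_sites * (law.pKa_eff - np.asarray(ph, dtype=float))
    if law.law == "linkage":
        # logistic form, evaluated stably for large |x|
        out = np.where(x > 0, 1.0 / (1.0 + 10.0**(-x)), 10.0**np.minimum(x, 300.0) / (1.0 + 10.0**np.minimum(x, 300.0)))
    else:
        out = 10.0**x
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class KineticParams:
    """Disassembly rates: ``k_end`` subunits/min per active end, ``k_frag``
    breaks/min per junction, both multiplied by the pH coupling.
    ``end_factors`` scale the two physical ends of the initial fibre (set one
    to 0 to emulate an end pinned to the surface); ends created by
    fragmentation carry factor 1."""

    k_end: float = 0.0
    k_frag: float = 0.0
    ph_coupling: PhCoupling = field(default_factory=PhCoupling)
    end_factors: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        if self.k_end < 0 or self.k_frag < 0:
            raise ValidationError("rates must be >= 0")
        if any(f < 0 for f in self.end_factors):
            raise ValidationError("end factors must be >= 0")


@dataclass
class FibreState:
    """Snapshot of a fibre: fragments as [a, b) intervals in subunit units on
    the initial fibre's coordinate line, with per-end rate factors."""

    subunit_count: int
    fragments: list[tuple[float, float, float, float]]  # (a, b, left_f, right_f)
    rise_per_subunit: float = RISE_NM

    @property
    def fragment_lengths(self) -> list[int]:
        return [int(b - a) for a, b, _, _ in self.fragments]

    @property
    def total_subunits(self) -> int:
        return sum(self.fragment_lengths)


@dataclass
class FibreTrace:
    """Recorded length-vs-time series for one simulated fibre (nm, minutes)."""

    times: np.ndarray
    length_total: np.ndarray
    length_longest: np.ndarray
    end1_recession: np.ndarray
    end2_recession: np.ndarray
    seed: int

    def __post_init__(self):
        n = len(self.times)
        for name in ("length_total", "length_longest", "end1_recession", "end2_recession"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must match times length {n}")
            setattr(self, name, arr)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.length_longest > self.length_total + 1e-9):
            raise ValidationError("length_longest cannot exceed length_total")
        if np.any(self.length_total < 0):
            raise ValidationError("lengths must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "length_total_nm": self.length_total,
                "length_longest_nm": self.length_longest,
                "end1_nm": self.end1_recession,
                "end2_nm": self.end2_recession,
            }
        )


def simulate_fibre(
    L0: float,
    params: KineticParams,
    schedule: PhSchedule,
    t_end: float,
    dt_record: float,
    seed: int,
) -> FibreTrace:
    """Exact event-driven simulation of one fibre under a pH schedule.

    ``L0`` is the initial length in nm (converted to subunits at 0.84
    nm/subunit).  Events are sampled by thinning against the coupling's
    supremum over the schedule, so time-varying pH is handled without
    discretization error.  Deterministic per seed.
    """
    if L0 <= 0:
        raise ValidationError("L0 must be > 0")
    if t_end <= 0 or dt_record <= 0:
        raise ValidationError("t_end and dt_record must be > 0")
    rng = np.random.default_rng(seed)
    n0 = max(1, int(round(L0 / RISE_NM)))
    f1, f2 = params.end_factors
    fragments: list[list[float]] = [[0.0, float(n0), f1, f2]]
    c_max = coupling(schedule.min_ph(), params.ph_coupling)

    times = np.arange(0.0, t_end + dt_record / 2.0, dt_record)
    rec_total = np.zeros_like(times)
    rec_longest = np.zeros_like(times)
    rec_end1 = np.zeros_like(times)
    rec_end2 = np.zeros_like(times)

    half = n0 / 2.0

    def record(idx: int):
        lengths = [b - a for a, b, _, _ in fragments]
        total = sum(lengths)
        rec_total[idx] = RISE_NM * total
        rec_longest[idx] = RISE_NM * (max(lengths) if lengths else 0.0)
        left = min((a for a, b, _, _ in fragments), default=half)
        right = max((b for a, b, _, _ in fragments), default=half)
        rec_end1[idx] = RISE_NM * min(left, half)
        rec_end2[idx] = RISE_NM * min(n0 - right, half)

    t = 0.0
    rec_idx = 0
    while True:
        # per-state rates at unit coupling
        end_weight = sum(lf + rf for _, _, lf, rf in fragments)
        junctions = sum(max(0.0, b - a - 1.0) for a, b, _, _ in fragments)
        base_rate = params.k_end * end_weight + params.k_frag * junctions
        bound = base_rate * c_max
        if bound <= 0.0:
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / bound)
        while rec_idx < len(times) and times[rec_idx] <= t_next + 1e-12:
            record(rec_idx)
            rec_idx += 1
        if rec_idx >= len(times) or not np.isfinite(t_next):
            break
        t = t_next
        # thinning: accept with probability coupling(t)/c_max
        c_now = coupling(schedule.at(t), params.ph_coupling)
        if rng.random() > (c_now / c_max if c_max > 0 else 0.0):
            continue
        # choose event kind proportional to unit-coupling rates
        u = rng.random() * base_rate
        if u < params.k_end * end_weight:
            # pick an end weighted by its factor
            pick = rng.random() * end_weight
            acc = 0.0
            for frag in fragments:
                a, b, lf, rf = frag
                if pick < acc + lf:
                    frag[0] = a + 1.0
                    break
                acc += lf
                if pick < acc + rf:
                    frag[1] = b - 1.0
                    break
                acc += rf
        else:
            # fragmentation: pick a junction uniformly
            pick = rng.random() * junctions
            acc = 0.0
            for i, (a, b, lf, rf) in enumerate(fragments):
                nj = max(0.0, b - a - 1.0)
                if pick < acc + nj:
                    cut = a + 1.0 + float(int(pick - acc))
                    fragments[i : i + 1] = [[a, cut, lf, 1.0], [cut, b, 1.0, rf]]
                    break
                acc += nj
        fragments = [f for f in fragments if f[1] - f[0] > 0.5]
    return FibreTrace(
        times=times,
        length_total=rec_total,
        length_longest=rec_longest,
        end1_recession=rec_end1,
        end2_recession=rec_end2,
        seed=seed,
    )


def simulate_ensemble(
    L0: float,
    params: KineticParams,
    schedule: PhSchedule,
    t_end: float,
    dt_record: float,
    seeds: Sequence[int],
) -> list[FibreTrace]:
    """Simulate one fibre per seed (convenience wrapper)."""
    return [simulate_fibre(L0, params, schedule, t_end, dt_record, s) for s in seeds]


@dataclass(frozen=True)
class RateEstimate:
    """Linear-fit disassembly rate (nm/min, positive = shrinking) with the
    OLS standard error of the slope."""

    rate: float
    stderr: float
    n_points: int


def _window_mask(times: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones_like(times, dtype=bool)
    lo, hi = window
    return (times >= lo) & (times <= hi)


def estimate_rate(
    trace: FibreTrace, window: tuple[float, float] | None = None
) -> RateEstimate:
    """OLS slope of longest-fragment length vs time, sign-flipped so that a
    shrinking fibre reports a positive nm/min rate."""
    mask = _window_mask(trace.times, window)
    t = trace.times[mask]
    y = trace.length_longest[mask]
    if len(t) < 3:
        raise InsufficientDataError(f"need >= 3 points in window, got {len(t)}")
    res = stats.linregress(t, y)
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return RateEstimate(rate=float(-res.slope), stderr=stderr, n_points=len(t))


def per_end_recession(
    trace: FibreTrace, window: tuple[float, float] | None = None
) -> tuple[RateEstimate, RateEstimate]:
    """Recession rate of each physical end toward the fibre centre (nm/min).

    Follows the microscopy convention: the centre of the initial fibre (half
    the initial length) is the second endpoint for each measurement, so each
    recession saturates at half the initial length.  Only time points where
    material remains are used; a fully vanished fibre raises
    :class:`InsufficientDataError`.
    """
    mask = _window_mask(trace.times, window) & (trace.length_total > 0)
    t = trace.times[mask]
    if len(t) < 3:
        raise InsufficientDataError(
            "fibre fully disassembled (or window too small): "
            f"only {len(t)} usable points"
        )
    out = []
    for series in (trace.end1_recession[mask], trace.end2_recession[mask]):
        res = stats.linregress(t, series)
        stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
        out.append(RateEstimate(rate=float(res.slope), stderr=stderr, n_points=len(t)))
    return out[0], out[1]


@dataclass(frozen=True)
class EnsembleSummary:
    """Cross-sectional mean ± s.d. of longest-fragment length at one time."""

    mean: float
    sd: float
    n: int


def ensemble_summary(
    traces: Sequence[FibreTrace], t: float, include_vanished: bool = False
) -> EnsembleSummary:
    """Mean ± s.d. of length at time ``t`` across fibres.

    Fully disassembled fibres are excluded by default (matching declining
    object counts in ensemble imaging); pass ``include_vanished=True`` to
    zero-count them instead.
    """
    if len(traces) < 1:
        raise ValidationError("need >= 1 trace")
    lengths = np.array(
        [float(np.interp(t, tr.times, tr.length_longest)) for tr in traces]
    )
    if not include_vanished:
        lengths = lengths[lengths > 0]
    n = len(lengths)
    if n == 0:
        return EnsembleSummary(mean=0.0, sd=0.0, n=0)
    sd = float(np.std(lengths, ddof=1)) if n > 1 else 0.0
    return EnsembleSummary(mean=float(lengths.mean()), sd=sd, n=n)
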
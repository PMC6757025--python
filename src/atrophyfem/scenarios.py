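"""Atrophy schedules: per-region volume-retention trajectories υ(t).

Two clinically motivated modes are provided:

* **generalized** atrophy — whole-brain tissue loss, by default reaching the
  endpoint retentions υ_gray = 0.80 and υ_white = 0.90 (i.e. −20% / −10%
  volume) over a 48-month course;
* **focal** atrophy — loss confined to one labeled region (a tissue or a
  named subregion), e.g. −50% in gray or −25% in white matter.

Endpoint schedules interpolate geometrically in pseudo-time, υ(t) =
υ_end^(t/T), so every increment applies the same relative shrink and the
endpoint is hit exactly regardless of the number of increments. Rate mode
accumulates linearly, υ(t) = 1 + rate·t, matching how monthly atrophy
rates are reported clinically. Note the two parameterizations differ
slightly at the endpoint (a −0.4%/month rate over 48 months gives υ =
0.808 linearly, not 0.80); endpoint mode is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanics import DomainError, GRAY, WHITE
from .mesh import TriMesh

__all__ = ["AtrophySchedule", "generalized_schedule", "focal_schedule",
           "upsilon_at", "upsilon_field"]


@dataclass(frozen=True)
class RegionEntry:
    """Volume-loss prescription for one region label."""

    region: str
    endpoint: float | None = None  # υ(duration), used in endpoint mode
    rate: float | None = None      # dυ/dt, fraction/month, used in rate mode


@dataclass(frozen=True)
class AtrophySchedule:
    """Per-region υ(t) trajectory over [0, duration] months."""

    mode: str                      # 'generalized' | 'focal'
    stepping: str                  # 'endpoint' (geometric) | 'rate' (linear)
    duration: float                # months
    n_increments: int
    entries: tuple = ()            # RegionEntry tuple

    def __post_init__(self):
        if self.duration <= 0:
            raise DomainError("schedule duration must be > 0 months")
        if self.n_increments < 1:
            raise DomainError("n_increments must be ≥ 1")
        if self.stepping not in ("endpoint", "rate"):
            raise DomainError(f"unknown stepping {self.stepping!r}")
        for e in self.entries:
            if self.stepping == "endpoint":
                if e.endpoint is None or not (0.0 < e.endpoint <= 1.0):
                    raise DomainError(
                        f"region {e.region!r}: endpoint υ must lie in (0, 1], "
                        f"got {e.endpoint}")
            else:
                if e.rate is None or e.rate > 0:
                    raise DomainError(
                        f"region {e.region!r}: atrophy rate must be ≤ 0, "
                        f"got {e.rate}")
                if 1.0 + e.rate * self.duration <= 0.0:
                    raise DomainError(
                        f"region {e.region!r}: rate {e.rate}/month drives υ ≤ 0 "
                        f"within {self.duration} months")

    @property
    def times(self) -> np.ndarray:
        """Pseudo-times of the increments, excluding t = 0."""
        return np.linspace(0.0, self.duration, self.n_increments + 1)[1:]

    def regions(self) -> tuple:
        return tuple(e.region for e in self.entries)


def generalized_schedule(delta_gray: float = -0.20, delta_white: float = -0.10,
                         duration: float = 48.0, n_increments: int = 48,
                         stepping: str = "endpoint",
                         rate_gray: float = -0.004,
                         rate_white: float = -0.002) -> AtrophySchedule:
    """Whole-brain schedule.

    Endpoint mode (default) reaches υ = 1 + Δυ exactly at t = duration via
    equal geometric per-increment factors; rate mode accumulates υ(t) =
    1 + rate·t. Defaults: Δυ = −20% gray / −10% white over 48 months
    (rates −0.4%/−0.2% per month).
    """
    entries = (
        RegionEntry(GRAY, endpoint=1.0 + delta_gray, rate=rate_gray),
        RegionEntry(WHITE, endpoint=1.0 + delta_white, rate=rate_white),
    )
    return AtrophySchedule("generalized", stepping, duration, n_increments, entries)


def focal_schedule(target_region: str, delta_upsilon: float,
                   duration: float = 48.0, n_increments: int = 48,
                   available_regions: tuple | None = None) -> AtrophySchedule:
    """Schedule atrophying only ``target_region``; υ ≡ 1 elsewhere."""
    if available_regions is not None and target_region not in available_regions:
        raise KeyError(
            f"unknown region {target_region!r}; available: "
            f"{sorted(set(available_regions))}")
    entries = (RegionEntry(target_region, endpoint=1.0 + delta_upsilon,
                           rate=delta_upsilon / duration),)
    return AtrophySchedule("focal", "endpoint", duration, n_increments, entries)


def upsilon_at(schedule: AtrophySchedule, t: float, region: str) -> float:
    """Retention factor of ``region`` at pseudo-time t (months).

    Regions not named in the schedule keep υ = 1. Monotone non-increasing
    in t; matches the prescribed endpoint exactly at t = duration.
    """
    if not (0.0 <= t <= schedule.duration + 1e-12):
        raise DomainError(
            f"t = {t} outside schedule span [0, {schedule.duration}] months")
    for e in schedule.entries:
        if e.region == region:
            if schedule.stepping == "endpoint":
                return float(e.endpoint ** (t / schedule.duration))
            return float(1.0 + e.rate * t)
    return 1.0


def upsilon_field(schedule: AtrophySchedule, mesh: TriMesh, t: float) -> np.ndarray:
    """Per-element υ at pseudo-time t; subregion labels shadow tissue labels."""
    ups = np.ones(mesh.n_elements)
    tissue = [r for r in schedule.regions() if r in (GRAY, WHITE)]
    named = [r for r in schedule.regions() if r not in (GRAY, WHITE)]
    for region in tissue:
        ups[mesh.element_region == region] = upsilon_at(schedule, t, region)
    for region in named:  # subregions shadow their parent tissue
        ups[mesh.element_subregion == region] = upsilon_at(schedule, t, region)
    return ups
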
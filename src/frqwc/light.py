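"""Light protocols: constant conditions, light-dark cycles and photic T-cycles."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class LightProtocol:
    """A piecewise-constant light schedule.

    mode
        ``DD`` (constant darkness), ``LL`` (constant light), ``LD``
        (light-dark cycle of length T with photoperiod P) or ``TCYCLE``
        (symmetric photic cycle: light for exactly half the cycle).
    cycle_length
        External cycle length T in hours (``inf`` for DD/LL).
    photoperiod
        Duration P of the light phase (h), 0 <= P <= T. Dawn is at time 0
        within the cycle plus ``dawn_time``; dusk falls at dawn + P.
    """

    mode: str = "DD"
    cycle_length: float = math.inf
    photoperiod: float = 0.0
    dawn_time: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("DD", "LL", "LD", "TCYCLE"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.mode in ("LD", "TCYCLE"):
            if not math.isfinite(self.cycle_length) or self.cycle_length <= 0:
                raise ValueError("forced protocols need a finite positive cycle length")
            if not 0 <= self.photoperiod <= self.cycle_length:
                raise ValueError("photoperiod must lie in [0, T]")
            if self.mode == "TCYCLE" and not math.isclose(
                self.photoperiod, self.cycle_length / 2, abs_tol=1e-9
            ):
                raise ValueError("symmetric T-cycles require P = T/2")

    # -- conventions ---------------------------------------------------

    @property
    def forced(self) -> bool:
        return self.mode in ("LD", "TCYCLE")

    @property
    def dusk_time(self) -> float:
        """Absolute time of lights-off within the cycle (h after dawn)."""
        if not self.forced:
            raise ValueError(f"{self.mode} protocol has no dusk")
        return self.dawn_time + self.photoperiod

    def light_level(self, t: float) -> float:
        """L(t) in {0, 1} (before intensity scaling)."""
        if self.mode == "DD":
            return 0.0
        if self.mode == "LL":
            return 1.0
        return 1.0 if (t - self.dawn_time) % self.cycle_length < self.photoperiod else 0.0

    def segments(self, t0: float, t1: float) -> list[tuple[float, float, float]]:
        """Decompose [t0, t1] into maximal intervals of constant light.

        Returns (start, end, level) triples; the integrator steps through
        them so that the square-wave discontinuities fall on segment
        boundaries.
        """
        if self.mode in ("DD", "LL"):
            return [(t0, t1, self.light_level(t0))]
        T, P = self.cycle_length, self.photoperiod
        edges = [t0]
        # first cycle boundary at or after t0
        kmin = math.floor((t0 - self.dawn_time) / T)
        t = self.dawn_time + kmin * T
        while t < t1:
            for edge in (t, t + P):
                if t0 < edge < t1:
                    edges.append(edge)
            t += T
        edges.append(t1)
        edges = sorted(set(edges))
        return [
            (a, b, self.light_level((a + b) / 2))
            for a, b in zip(edges[:-1], edges[1:])
            if b > a
        ]

    # -- constructors / serialisation ---------------------------------

    @classmethod
    def DD(cls) -> "LightProtocol":
        return cls(mode="DD")

    @classmethod
    def LL(cls) -> "LightProtocol":
        return cls(mode="LL")

    @classmethod
    def LD(cls, photoperiod: float, cycle_length: float = 24.0, dawn_time: float = 0.0) -> "LightProtocol":
        return cls(mode="LD", cycle_length=cycle_length, photoperiod=photoperiod, dawn_time=dawn_time)

    @classmethod
    def tcycle(cls, cycle_length: float, dawn_time: float = 0.0) -> "LightProtocol":
        return cls(
            mode="TCYCLE",
            cycle_length=cycle_length,
            photoperiod=cycle_length / 2,
            dawn_time=dawn_time,
        )

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "cycle_length": None if math.isinf(self.cycle_length) else self.cycle_length,
            "photoperiod": self.photoperiod,
            "dawn_time": self.dawn_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightProtocol":
        d = dict(d)
        if d.get("cycle_length") is None:
            d["cycle_length"] = math.inf
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LightProtocol":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
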
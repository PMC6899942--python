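"""Scanner hardware limits for diffusion-encoding gradient waveforms."""

from __future__ import annotations

from dataclasses import dataclass

#: Proton gyromagnetic ratio, rad/(s*T).
GAMMA_PROTON = 2.6752218744e8


class InfeasibleWaveformError(ValueError):
    """Requested b-value cannot be reached within the hardware limits."""


class DiffusionTimeRangeError(ValueError):
    """Requested diffusion time lies outside the allowed range."""


@dataclass(frozen=True)
class HardwareLimits:
    """Gradient hardware and protocol limits.

    Parameters
    ----------
    g_max : float
        Maximum gradient amplitude, mT/m.
    slew_max : float
        Maximum slew rate, mT/m/ms.
    t_min, t_max : float
        Allowed diffusion-time range, ms.
    gamma : float
        Gyromagnetic ratio, rad/(s*T).
    """

    g_max: float = 45.0
    slew_max: float = 200.0
    t_min: float = 40.0
    t_max: float = 100.0
    gamma: float = GAMMA_PROTON

    def __post_init__(self) -> None:
        for name in ("g_max", "slew_max", "t_min", "t_max", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.t_min > self.t_max:
            raise ValueError("t_min must not exceed t_max")

    def check_T(self, T: float) -> None:
        if not (self.t_min <= T <= self.t_max):
            raise DiffusionTimeRangeError(
                f"diffusion time T={T} ms outside [{self.t_min}, {self.t_max}] ms"
            )


DEFAULT_HARDWARE = HardwareLimits()
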
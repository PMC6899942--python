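"""Two-compartment flow-compensated IVIM forward signal model.

The diffusion-weighted signal at acquisition setting (b, T, beta) is

    S = S0 * [ (1 - f) * exp(-b D)
               + f * F(b, T, beta, tau, v) * exp(-b * D_blood(beta)) ],

where D is the tissue diffusivity (mm^2/s), f the perfusion signal fraction,
tau the characteristic vessel-segment traversal time (ms), v the blood speed
(mm/s), F the Monte-Carlo perfusion attenuation factor and D_blood the
apparent diffusion coefficient of blood for the given gradient shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gradients import max_b
from .hardware import DEFAULT_HARDWARE, HardwareLimits

SCHEME_COLUMNS = ("b_s_mm2", "T_ms", "beta", "n_repeats")


@dataclass(frozen=True)
class TissueParams:
    """FC-IVIM tissue parameters.

    D in mm^2/s, f a fraction in [0, 1], tau in ms, v in mm/s, S0 arbitrary.
    """

    D: float
    f: float
    tau: float
    v: float
    S0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.D, self.f, self.tau, self.v, self.S0) < 0:
            raise ValueError("tissue parameters must be non-negative")
        if self.f > 1:
            raise ValueError("perfusion fraction f must be <= 1")

    def as_array(self) -> np.ndarray:
        """(S0, D, f, tau, v) in fit ordering."""
        return np.array([self.S0, self.D, self.f, self.tau, self.v])

    @classmethod
    def from_array(cls, x) -> "TissueParams":
        return cls(S0=x[0], D=x[1], f=x[2], tau=x[3], v=x[4])


#: Liver literature parameters used for the SNR / f sweeps.
LIVER_LITERATURE = TissueParams(D=1.12e-3, f=0.347, tau=144.0, v=4.60)
#: Pancreas literature parameters used for the SNR / f sweeps.
PANCREAS_LITERATURE = TissueParams(D=1.88e-3, f=0.287, tau=224.0, v=3.91)


@dataclass(frozen=True)
class BloodADC:
    """Apparent diffusion coefficients of blood, mm^2/s, per gradient shape."""

    d_bipolar: float = 1.30e-3
    d_fc: float = 1.54e-3

    def __post_init__(self) -> None:
        if self.d_bipolar <= 0 or self.d_fc <= 0:
            raise ValueError("blood ADCs must be positive")
        if self.d_fc < self.d_bipolar:
            raise ValueError("d_fc must be >= d_bipolar")

    def for_beta(self, beta) -> np.ndarray:
        beta = np.asarray(beta)
        return np.where(beta == 1, self.d_fc, self.d_bipolar)


DEFAULT_BLOOD = BloodADC()


@dataclass(frozen=True)
class AcquisitionPoint:
    """One (b, T, beta) measurement setting."""

    b: float
    T: float
    beta: int
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("b must be non-negative")
        if self.beta not in (0, 1):
            raise ValueError("beta must be 0 or 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class AcquisitionScheme:
    """Ordered list of acquisition points.

    A fittable scheme needs at least five points (five free model parameters)
    and at least one b = 0 point for normalization; both are enforced here.
    """

    points: list
    label: str = ""
    n_directions: int = 6

    def __post_init__(self) -> None:
        self.points = list(self.points)
        if len(self.points) < 5:
            raise ValueError("a scheme needs >= 5 acquisitions for identifiability")
        if not any(p.b == 0 for p in self.points):
            raise ValueError("a scheme needs at least one b = 0 acquisition")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def b(self) -> np.ndarray:
        return np.array([p.b for p in self.points])

    @property
    def T(self) -> np.ndarray:
        return np.array([p.T for p in self.points])

    @property
    def beta(self) -> np.ndarray:
        return np.array([p.beta for p in self.points])

    @property
    def n_repeats(self) -> np.ndarray:
        return np.array([p.n_repeats for p in self.points])

    def with_point(self, point: AcquisitionPoint, label=None) -> "AcquisitionScheme":
        return AcquisitionScheme(
            self.points + [point],
            self.label if label is None else label,
            self.n_directions,
        )

    def expanded(self) -> "AcquisitionScheme":
        """Unroll n_repeats into duplicated rows."""
        pts = []
        for p in self.points:
            pts.extend([replace(p, n_repeats=1)] * p.n_repeats)
        return AcquisitionScheme(pts, self.label, self.n_directions)

    def validate_feasible(self, hw: HardwareLimits = DEFAULT_HARDWARE) -> None:
        bad = []
        for i, p in enumerate(self.points):
            try:
                hw.check_T(p.T)
                if p.b > max_b(p.beta, p.T, hw) * (1 + 1e-9):
                    bad.append(i)
            except Exception:
                bad.append(i)
        if bad:
            raise ValueError(f"infeasible acquisition rows: {bad}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "b_s_mm2": self.b,
                "T_ms": self.T,
                "beta": self.beta,
                "n_repeats": self.n_repeats,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label="", n_directions=6) -> "AcquisitionScheme":
        pts = [
            AcquisitionPoint(
                float(r.b_s_mm2), float(r.T_ms), int(r.beta), int(getattr(r, "n_repeats", 1))
            )
            for r in df.itertuples()
        ]
        return cls(pts, label, n_directions)


@dataclass
class SignalCurve:
    """Per-acquisition-point signal values tied to a scheme."""

    values: np.ndarray
    scheme: AcquisitionScheme
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.size != len(self.scheme):
            raise ValueError("signal length must match the scheme")

    def to_frame(self) -> pd.DataFrame:
        df = self.scheme.to_dataframe()
        df["signal"] = self.values
        return df


def forward_signal(
    scheme: AcquisitionScheme,
    tissue: TissueParams,
    blood: BloodADC = DEFAULT_BLOOD,
    tables: dict | None = None,
    method: str = "table",
    n_spins: int = 10_000,
    seed=None,
    hw: HardwareLimits = DEFAULT_HARDWARE,
) -> SignalCurve:
    """Evaluate the FC-IVIM forward model for every point of ``scheme``.

    ``method='table'`` (default) uses cached phase tables and is
    deterministic; ``method='mc'`` runs a fresh Monte-Carlo phase simulation
    per point (used as an oracle in tests).
    """
    b, T, beta = scheme.b, scheme.T, scheme.beta
    if method == "table":
        if tables is None:
            from .phase import default_tables

            tables = default_tables(hw)
        F = np.empty(len(scheme))
        for bb in (0, 1):
            m = beta == bb
            if np.any(m):
                F[m] = np.atleast_1d(tables[bb].F(b[m], T[m], tissue.tau, tissue.v))
    elif method == "mc":
        from .phase import attenuation

        rngseq = np.random.SeedSequence(seed).spawn(len(scheme))
        F = np.array(
            [
                attenuation(bi, Ti, bi_beta, tissue.tau, tissue.v, n_spins, s, hw)
                for bi, Ti, bi_beta, s in zip(b, T, beta, rngseq)
            ]
        )
    else:
        raise ValueError("method must be 'table' or 'mc'")
    S = tissue.S0 * (
        (1.0 - tissue.f) * np.exp(-b * tissue.D)
        + tissue.f * F * np.exp(-b * blood.for_beta(beta))
    )
    return SignalCurve(S, scheme)
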
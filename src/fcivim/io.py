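"""CSV readers/writers for schemes, curves and estimate tables.

Everything round-trips through plain CSV; schemes are validated against the
hardware limits on read so infeasible protocols fail early with the offending
rows named.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gradients import max_b
from .hardware import DEFAULT_HARDWARE, HardwareLimits
from .model import SCHEME_COLUMNS, AcquisitionScheme, SignalCurve


class SchemeFormatError(ValueError):
    """Malformed or infeasible scheme table."""


def write_scheme(scheme: AcquisitionScheme, path) -> None:
    scheme.to_dataframe().to_csv(path, index=False)


def read_scheme(
    path,
    hw: HardwareLimits | None = DEFAULT_HARDWARE,
    label: str = "",
    n_directions: int = 6,
) -> AcquisitionScheme:
    """Read a scheme CSV (b_s_mm2, T_ms, beta, n_repeats) and validate it.

    ``hw=None`` skips the feasibility check.
    """
    df = pd.read_csv(path)
    missing = [c for c in SCHEME_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise SchemeFormatError(f"scheme file {path} missing columns {missing}")
    if "n_repeats" not in df.columns:
        df["n_repeats"] = 1
    bad = df.index[~df["beta"].isin([0, 1])].tolist()
    if bad:
        raise SchemeFormatError(f"rows with invalid beta (must be 0 or 1): {bad}")
    bad = df.index[(df["b_s_mm2"] < 0) | (df["n_repeats"] < 1)].tolist()
    if bad:
        raise SchemeFormatError(f"rows with negative b or n_repeats < 1: {bad}")
    if hw is not None:
        infeasible = []
        for i, r in df.iterrows():
            try:
                hw.check_T(float(r["T_ms"]))
                if r["b_s_mm2"] > max_b(int(r["beta"]), float(r["T_ms"]), hw) * (1 + 1e-9):
                    infeasible.append(int(i))
            except Exception:
                infeasible.append(int(i))
        if infeasible:
            raise SchemeFormatError(
                f"rows infeasible under hardware limits {hw}: {infeasible}"
            )
    return AcquisitionScheme.from_dataframe(df, label=label, n_directions=n_directions)


def write_curve(curve: SignalCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_curve(path, hw: HardwareLimits | None = DEFAULT_HARDWARE) -> SignalCurve:
    df = pd.read_csv(path)
    if "signal" not in df.columns:
        raise SchemeFormatError(f"curve file {path} needs a 'signal' column")
    if "n_repeats" not in df.columns:
        df["n_repeats"] = 1
    scheme = AcquisitionScheme.from_dataframe(df)
    if hw is not None:
        scheme.validate_feasible(hw)
    return SignalCurve(df["signal"].to_numpy(float), scheme)


def write_estimates(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"subject", "organ", "occasion"}
    if not needed.issubset(df.columns):
        raise SchemeFormatError(f"estimates table {path} needs columns {sorted(needed)}")
    return df


def write_series_collection(series_list, path) -> None:
    """Long-format CSV of ROI series (one row per acquisition)."""
    frames = []
    for s in series_list:
        df = s.scheme.to_dataframe()
        df.insert(0, "subject", s.subject)
        df.insert(1, "organ", s.organ)
        df.insert(2, "occasion", s.occasion)
        df["time_s"] = s.times_s
        df["signal"] = s.signals
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_series_collection(path, hw: HardwareLimits | None = DEFAULT_HARDWARE):
    """Inverse of :func:`write_series_collection`; returns list of ROISeries."""
    from .repeatability import ROISeries

    df = pd.read_csv(path)
    out = []
    for (subject, organ, occasion), g in df.groupby(
        ["subject", "organ", "occasion"], sort=False
    ):
        scheme = AcquisitionScheme.from_dataframe(g.reset_index(drop=True))
        if hw is not None:
            scheme.validate_feasible(hw)
        out.append(
            ROISeries(
                str(subject),
                str(organ),
                str(occasion),
                g["signal"].to_numpy(float),
                g["time_s"].to_numpy(float),
                scheme,
            )
        )
    return out
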
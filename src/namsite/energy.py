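"""Binding-free-energy aggregation and sampling-convergence auditing.

Post-processing of per-frame energy components from an MM-PBSA-style
decomposition: the binding free energy is assembled as ΔG = ΔH − TΔS
from frame means, dispersion is reported as the standard deviation of
sliding-window means (window 200 frames by default), and convergence is
audited through cumulative means at fixed checkpoints and the change in
cumulative mean between two sampling depths.  No force-field terms are
computed here — inputs are the already-decomposed component series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnergySeries",
    "BindingEnergyResult",
    "binding_free_energy",
    "cumulative_convergence",
    "convergence_delta",
    "read_energy_table",
    "write_energy_table",
]

_COMPONENT_LABELS = ("enthalpy", "entropy_TdS", "free_energy")


@dataclass
class EnergySeries:
    """Per-frame values of one energy component, kcal/mol."""

    values: np.ndarray
    frame_interval_ps: float = 1.0
    label: str = "free_energy"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("energy series must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("energy series contains non-finite values")
        if self.label not in _COMPONENT_LABELS:
            raise ValueError(
                f"label must be one of {_COMPONENT_LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BindingEnergyResult:
    """Aggregated ΔH, TΔS and ΔG with per-component dispersion.

    ``dG = dH_mean - TdS_mean`` holds exactly; dispersions are SDs of
    sliding-window means unless raw-frame SD was requested.
    """

    dH_mean: float
    TdS_mean: float
    dG: float
    dH_sd: float
    TdS_sd: float
    dG_sd: float
    n_frames: int
    window: int
    dispersion_kind: str = "window_means"

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": ["dH", "TdS", "dG"],
                "mean_kcal_mol": [self.dH_mean, self.TdS_mean, self.dG],
                "sd_kcal_mol": [self.dH_sd, self.TdS_sd, self.dG_sd],
            }
        )


def _as_values(series) -> np.ndarray:
    if isinstance(series, EnergySeries):
        return series.values
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if arr.ndim != 1 or len(arr) == 0:
        raise ValueError("energy series must be non-empty and 1-D")
    return arr


def _window_mean_sd(values: np.ndarray, window: int) -> float:
    means = np.lib.stride_tricks.sliding_window_view(values, window).mean(axis=1)
    return float(np.std(means))


def binding_free_energy(
    dH_series,
    TdS_series,
    window: int = 200,
    dispersion: str = "window_means",
) -> BindingEnergyResult:
    """Aggregate enthalpy and entropy series into a ΔG = ΔH − TΔS result.

    Means are taken over all frames.  A TΔS series of length 1 is
    treated as a single repeated value (entropy estimates are often
    computed far more sparsely than enthalpies) and broadcast to the
    enthalpy length.  Dispersion per component is the population SD of
    sliding-window means with the given window; ``dispersion="raw"``
    reports the SD of raw frames instead.
    """
    dH = _as_values(dH_series)
    TdS = _as_values(TdS_series)
    if len(TdS) == 1 and len(dH) > 1:
        TdS = np.full_like(dH, TdS[0])
    if len(dH) != len(TdS):
        raise ValueError(
            f"component length mismatch: dH has {len(dH)} frames, TdS {len(TdS)}"
        )
    n = len(dH)
    if not 1 <= window <= n:
        raise ValueError(f"window must lie in [1, {n}], got {window}")
    if dispersion not in ("window_means", "raw"):
        raise ValueError("dispersion must be 'window_means' or 'raw'")
    dG_series = dH - TdS
    if dispersion == "window_means":
        sds = [_window_mean_sd(s, window) for s in (dH, TdS, dG_series)]
    else:
        sds = [float(np.std(s)) for s in (dH, TdS, dG_series)]
    dH_mean = float(dH.mean())
    TdS_mean = float(TdS.mean())
    return BindingEnergyResult(
        dH_mean=dH_mean,
        TdS_mean=TdS_mean,
        dG=dH_mean - TdS_mean,
        dH_sd=sds[0],
        TdS_sd=sds[1],
        dG_sd=sds[2],
        n_frames=n,
        window=window,
        dispersion_kind=dispersion,
    )


def cumulative_convergence(series, checkpoint_interval: int = 100) -> list[tuple[int, float]]:
    """Cumulative means of the first n values at n = interval, 2·interval, …"""
    values = _as_values(series)
    if checkpoint_interval < 1:
        raise ValueError("checkpoint_interval must be >= 1")
    if len(values) < checkpoint_interval:
        raise ValueError(
            f"series length {len(values)} shorter than checkpoint interval "
            f"{checkpoint_interval}"
        )
    csum = np.cumsum(values)
    checkpoints = []
    n = checkpoint_interval
    while n <= len(values):
        checkpoints.append((n, float(csum[n - 1] / n)))
        n += checkpoint_interval
    return checkpoints


def convergence_delta(series, n1: int = 1400, n2: int = 1500) -> float:
    """|cumulative mean over first n2 − cumulative mean over first n1|.

    A small value at the sampling depths used for production estimates
    indicates the cumulative average has stabilised.
    """
    values = _as_values(series)
    if not (0 < n1 < n2):
        raise ValueError("need 0 < n1 < n2")
    if len(values) < n2:
        raise ValueError(f"series length {len(values)} shorter than n2={n2}")
    return float(abs(values[:n2].mean() - values[:n1].mean()))


# ---------------------------------------------------------------------------
# TSV interchange: (frame, component, value)


def read_energy_table(path) -> dict[str, EnergySeries]:
    """Read a TSV of per-frame components into series keyed by label.

    Expected columns: ``frame``, ``component``, ``value``; components
    must be among enthalpy / entropy_TdS / free_energy.  Malformed rows
    raise with their line number.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse energy table ({exc})") from exc
    required = {"frame", "component", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: energy table needs columns {sorted(required)}")
    bad = ~df["component"].isin(_COMPONENT_LABELS)
    if bad.any():
        lineno = int(df.index[bad][0]) + 2  # header + 1-based
        raise ValueError(
            f"{path}: unknown component {df.loc[bad, 'component'].iloc[0]!r} "
            f"at line {lineno}"
        )
    out = {}
    for label, grp in df.groupby("component", sort=False):
        grp = grp.sort_values("frame")
        out[label] = EnergySeries(grp["value"].to_numpy(), label=label)
    return out


def write_energy_table(path, series_by_label: dict[str, EnergySeries]) -> None:
    rows = []
    for label, series in series_by_label.items():
        for frame, value in enumerate(series.values):
            rows.append({"frame": frame, "component": label, "value": value})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
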
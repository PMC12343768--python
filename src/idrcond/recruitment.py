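"""Synthetic-condensate recruitment time-series pipeline.

Condensate tracks (long-format tables, one row per condensate per
2-minute frame, with scaffold / YAP / partner channel intensities) are
filtered on track quality, corrected for non-specific recruitment and
photobleaching with a mono-exponential fit to fluorophore-only control
tracks, gated on the YAP recruitment amplitude, pooled into mean +/- SEM
time courses, and compared between arms (e.g. transcription-inhibitor
treated versus vehicle) as difference curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

FRAME_INTERVAL_MIN = 2.0

REQUIRED_COLUMNS = (
    "track_id",
    "frame",
    "t_min",
    "area",
    "scaffold",
    "yap",
    "partner",
    "nucleus_id",
    "experiment_id",
    "arm",
)


@dataclass(frozen=True)
class FilterRules:
    """Condensate-track quality rules (applied conjunctively)."""

    must_start_at_frame0: bool = True
    min_frames: int = 10  # = 18 min at 2-min sampling
    area_range: tuple[float, float] = (0.45, 1.55)
    require_nuclear: bool = True

    def __post_init__(self) -> None:
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")
        if not self.area_range[0] < self.area_range[1]:
            raise ValueError("area_range must be (low, high) with low < high")


@dataclass
class CorrectionModel:
    """Mono-exponential I(t) = a exp(-t/tau) + c fitted to the pooled
    control-construct partner intensity; captures non-specific
    recruitment plus photobleaching."""

    a: float
    tau: float
    c: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a * np.exp(-t / self.tau) + self.c


def _validate(df: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns {sorted(missing)}")


def filter_tracks(
    tracks: pd.DataFrame, rules: FilterRules = FilterRules()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the track-quality rules; returns (kept rows, rejection ledger).

    Rules: the track must start at frame 0, span at least ``min_frames``
    frames, have a per-track mean area inside ``area_range``, and lie in
    a nucleus (non-null nucleus_id). The ledger counts, per rule, how
    many tracks violate it (a track may violate several rules).
    """
    _validate(tracks)
    g = tracks.groupby("track_id")
    starts_ok = g["frame"].min() == 0
    length_ok = g["frame"].nunique() >= rules.min_frames
    mean_area = g["area"].mean()
    area_ok = (mean_area >= rules.area_range[0]) & (mean_area <= rules.area_range[1])
    nuclear_ok = g["nucleus_id"].first().notna()
    keep = pd.Series(True, index=starts_ok.index)
    ledger = {"n_tracks": int(len(starts_ok))}
    for name, ok, active in (
        ("start_frame", starts_ok, rules.must_start_at_frame0),
        ("min_frames", length_ok, True),
        ("area_range", area_ok, True),
        ("nuclear", nuclear_ok, rules.require_nuclear),
    ):
        if active:
            ledger[f"rejected_{name}"] = int((~ok).sum())
            keep &= ok
    ledger["kept"] = int(keep.sum())
    kept_ids = keep.index[keep]
    return tracks[tracks["track_id"].isin(kept_ids)].copy(), ledger


def pooled_mean(tracks: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Per-time-point mean of a channel across tracks (no corrections)."""
    _validate(tracks)
    out = tracks.groupby("t_min")[channel].agg(["mean", "sem", "count"])
    return out.reset_index()


def fit_control_correction(
    control_tracks: pd.DataFrame,
    channel: str = "partner",
    background: float = 0.0,
) -> CorrectionModel:
    """Fit the mono-exponential correction to the pooled control mean.

    The background is subtracted before fitting, so the model describes
    the background-free non-specific signal and its bleaching.
    """
    mean = pooled_mean(control_tracks, channel)
    t = mean["t_min"].to_numpy(float)
    y = mean["mean"].to_numpy(float) - background
    if t.size < 5:
        raise ValueError("control pooled mean needs >= 5 time points")
    span = max(y.max() - y.min(), 1e-9)
    p0 = (span, max(t.max() / 2, 1.0), y.min())
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, 1e6, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"control correction fit did not converge: {exc}")
    return CorrectionModel(*map(float, popt))


def correct_partner(
    tracks: pd.DataFrame,
    model: CorrectionModel,
    background: float = 0.0,
    channel: str = "partner",
) -> pd.DataFrame:
    """Subtract background, then the fitted control curve, pointwise.

    Returns a copy with a ``{channel}_corrected`` column. Applying a
    model to the very control tracks it was fit on leaves residuals
    near zero (the self-consistency check of the correction).
    """
    _validate(tracks)
    out = tracks.copy()
    out[f"{channel}_corrected"] = (
        out[channel].to_numpy(float) - background - model(out["t_min"].to_numpy(float))
    )
    return out


def gate_by_recruitment(
    tracks: pd.DataFrame,
    channel: str = "yap",
    threshold: float = 250.0,
    gate_time: float = 16.0,
    interval: float = FRAME_INTERVAL_MIN,
) -> pd.DataFrame:
    """Keep tracks whose baseline-subtracted channel at ``gate_time``
    reaches ``threshold``.

    The value at gate time is read from the nearest frame within one
    frame interval; tracks not covering the gate time raise.
    """
    _validate(tracks)
    kept = []
    for tid, grp in tracks.groupby("track_id"):
        t = grp["t_min"].to_numpy(float)
        y = grp[channel].to_numpy(float)
        i = int(np.argmin(np.abs(t - gate_time)))
        if abs(t[i] - gate_time) > interval:
            raise ValueError(
                f"track {tid}: gate time {gate_time} min outside track span"
            )
        baseline = y[int(np.argmin(t))]
        if y[i] - baseline >= threshold:
            kept.append(tid)
    return tracks[tracks["track_id"].isin(kept)].copy()


def pool_and_average(
    tracks: pd.DataFrame,
    channel: str,
    baseline_subtract: bool = True,
) -> pd.DataFrame:
    """Mean +/- SEM time course over tracks on their common time grid.

    Each track is first baseline-subtracted (its value at its earliest
    shared time point), then the tracks are averaged frame-wise on the
    intersection of their time grids.
    """
    _validate(tracks)
    if tracks.empty:
        raise ValueError("no tracks to pool")
    grids = [set(g["t_min"]) for _, g in tracks.groupby("track_id")]
    common = sorted(set.intersection(*grids))
    if not common:
        raise ValueError("tracks share no common time points")
    rows = []
    for _, grp in tracks.groupby("track_id"):
        grp = grp.set_index("t_min").loc[common]
        y = grp[channel].to_numpy(float)
        if baseline_subtract:
            y = y - y[0]
        rows.append(y)
    mat = np.vstack(rows)
    sem = (
        mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        if mat.shape[0] > 1
        else np.zeros(mat.shape[1])
    )
    return pd.DataFrame(
        {
            "t_min": common,
            "mean": mat.mean(axis=0),
            "sem": sem,
            "n_tracks": mat.shape[0],
        }
    )


def drb_difference(
    treated_mean: pd.DataFrame, control_mean: pd.DataFrame
) -> pd.DataFrame:
    """Difference curve (treated minus control) on the shared time grid."""
    shared = np.intersect1d(
        treated_mean["t_min"].to_numpy(), control_mean["t_min"].to_numpy()
    )
    if shared.size == 0:
        raise ValueError("time grids are disjoint")
    a = treated_mean.set_index("t_min").loc[shared, "mean"]
    b = control_mean.set_index("t_min").loc[shared, "mean"]
    return pd.DataFrame({"t_min": shared, "difference": (a - b).to_numpy()})
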
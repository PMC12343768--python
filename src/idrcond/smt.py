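"""Single-molecule dwell-time analysis.

Chromatin-bound molecules appear as immobile spots in fast (150 ms
frame interval) single-molecule movies; an external tracker links them
into tracks with gap closing across blinks of up to two frames. The
dwell time of a track is its total span, gap-inclusive. The survival
function (1-CDF) of the pooled dwell times is bi-exponential:
S(t) = A exp(-t/tau_ns) + (1-A) exp(-t/tau_s), with a short-lived
non-specific population (tau_ns) and a long-lived specific population
(tau_s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_FRAME_INTERVAL = 0.15  # seconds
DEFAULT_BIN_EDGES = (1.2, 7.0, 10.0)  # seconds; non-specific/specific population bins

#: column aliases accepted when ingesting tracker-export CSVs
_TRACK_ALIASES = {
    "TRACK_ID": "track_id",
    "FRAME": "frame",
    "POSITION_X": "x",
    "POSITION_Y": "y",
    "MEAN_INTENSITY": "intensity",
    "MEAN_INTENSITY_CH1": "intensity",
}


class DwellExtractionError(ValueError):
    pass


@dataclass
class DwellSample:
    """A collection of dwell times (seconds) from one experiment."""

    dwells: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    experiment_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.dwells, dtype=float)
        if d.size and (not np.all(np.isfinite(d)) or d.min() < self.frame_interval - 1e-12):
            raise ValueError(
                "dwells must be finite and >= one frame interval"
            )
        self.dwells = d

    def __len__(self) -> int:
        return self.dwells.size


@dataclass
class SurvivalFit:
    """Bi-exponential survival fit: S(t)=A exp(-t/tau_ns)+(1-A) exp(-t/tau_s)."""

    A: float
    tau_ns: float
    tau_s: float
    rss: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.A < 1.0):
            raise ValueError("A must lie in (0, 1)")
        if not (0.0 < self.tau_ns <= self.tau_s):
            raise ValueError("require 0 < tau_ns <= tau_s")

    def survival(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A * np.exp(-t / self.tau_ns) + (1 - self.A) * np.exp(
            -t / self.tau_s
        )


def read_track_csv(path) -> pd.DataFrame:
    """Ingest a tracker-export CSV (TRACK_ID/FRAME/POSITION_X/... dialect
    or already-normalized lowercase columns). Frames are integers,
    0-based."""
    df = pd.read_csv(path)
    df = df.rename(columns=_TRACK_ALIASES)
    missing = {"track_id", "frame"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    df["frame"] = df["frame"].astype(int)
    return df


def extract_dwells(
    tracks: pd.DataFrame,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    min_frames: int = 2,
    max_frame_gap: int = 2,
    experiment_id: str = "",
) -> DwellSample:
    """Per-track dwell times from a track table.

    dwell = (last_frame - first_frame + 1) * frame_interval; blink gaps
    (up to ``max_frame_gap`` missing frames) count toward the dwell — a
    molecule is presumed bound across a short blink. Tracks with fewer
    than ``min_frames`` detections are dropped (unlinked detections are
    not binding events).
    """
    if tracks.duplicated(subset=["track_id", "frame"]).any():
        raise DwellExtractionError("duplicate (track_id, frame) rows")
    dwells = []
    for _, grp in tracks.groupby("track_id"):
        frames = np.sort(grp["frame"].to_numpy())
        if frames.size < min_frames:
            continue
        gaps = np.diff(frames) - 1
        if gaps.size and gaps.max() > max_frame_gap:
            raise DwellExtractionError(
                f"track has a gap of {int(gaps.max())} frames "
                f"(> max_frame_gap={max_frame_gap}); re-run gap closing"
            )
        dwells.append((frames[-1] - frames[0] + 1) * frame_interval)
    return DwellSample(np.array(dwells), frame_interval, experiment_id)


def survival_curve(sample: DwellSample | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical survival function S(t) = P(dwell > t).

    Returned at t=0 (S=1) and every sorted unique dwell time; S drops
    below 1 at the smallest observed dwell and reaches 0 at the largest.
    """
    d = sample.dwells if isinstance(sample, DwellSample) else np.asarray(sample, float)
    if d.size == 0:
        raise ValueError("empty dwell sample")
    d_sorted = np.sort(d)
    t = np.unique(d_sorted)
    n = d.size
    s = (n - np.searchsorted(d_sorted, t, side="right")) / n
    return np.concatenate(([0.0], t)), np.concatenate(([1.0], s))


def _biexp_log10(t, a, tau1, tau2):
    return np.log10(
        a * np.exp(-t / tau1) + (1 - a) * np.exp(-t / tau2)
    )


def fit_biexponential(
    t: np.ndarray,
    s: np.ndarray,
    log_fit: bool = True,
    degenerate_ratio: float = 1.05,
) -> SurvivalFit:
    """Least-squares bi-exponential fit of a survival curve.

    By default the fit is performed on log10 S (equal weight per unique
    dwell time), which stabilizes the rare long tail; set
    ``log_fit=False`` to fit the raw survival values. Points with S <= 0
    are excluded. Initialization reads tau_ns from the time S crosses
    0.5 (the median dwell), tau_s from the 0.1 crossing (90th
    percentile), and A = 0.7. The component labels are resolved by
    ordering tau_ns < tau_s; a near-single-exponential result
    (tau_s / tau_ns < ``degenerate_ratio``) is flagged degenerate.
    """
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    keep = s > 0
    t, s = t[keep], s[keep]
    if np.unique(t).size < 6:
        raise ValueError("need >= 6 distinct time points with S > 0")

    def crossing(level: float) -> float:
        below = np.flatnonzero(s <= level)
        return t[below[0]] if below.size else t[-1]

    tau1_0 = max(crossing(0.5), 1e-3)
    tau2_0 = max(crossing(0.1), tau1_0 * 2)
    x0 = np.array([0.7, tau1_0, tau2_0])
    if log_fit:
        target = np.log10(s)

        def resid(p):
            return _biexp_log10(t, *p) - target

    else:

        def resid(p):
            a, tau1, tau2 = p
            return a * np.exp(-t / tau1) + (1 - a) * np.exp(-t / tau2) - s

    res = optimize.least_squares(
        resid,
        x0,
        bounds=([1e-6, 1e-4, 1e-4], [1 - 1e-6, 1e4, 1e4]),
        method="trf",
    )
    if not res.success:
        raise RuntimeError(
            f"bi-exponential fit failed to converge from x0={x0}: {res.message}"
        )
    a, tau1, tau2 = res.x
    if tau1 > tau2:
        a, tau1, tau2 = 1 - a, tau2, tau1
    degenerate = bool(tau2 / tau1 < degenerate_ratio)
    return SurvivalFit(
        A=float(a),
        tau_ns=float(tau1),
        tau_s=float(tau2),
        rss=float(2 * res.cost),
        n=t.size,
        degenerate=degenerate,
    )


def fit_dwell_sample(sample: DwellSample, **kwargs) -> SurvivalFit:
    """Convenience: survival curve + bi-exponential fit in one call."""
    t, s = survival_curve(sample)
    return fit_biexponential(t, s, **kwargs)


def dwell_bin_fractions(
    sample: DwellSample | np.ndarray,
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> dict[str, float]:
    """Population-bin fractions: events below the first edge and at or
    above each edge. The upper bins overlap by design (>=1.2 s contains
    >=7 s contains >=10 s); frac(<e0) + frac(>=e0) = 1."""
    d = sample.dwells if isinstance(sample, DwellSample) else np.asarray(sample, float)
    if d.size == 0:
        raise ValueError("empty dwell sample")
    out = {f"<{edges[0]:g}s": float((d < edges[0]).mean())}
    for e in edges:
        out[f">={e:g}s"] = float((d >= e).mean())
    return out


def fold_change_stats(
    condition: dict[str, np.ndarray],
    control: dict[str, np.ndarray],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-bin fold change of condition over control across experiments.

    Inputs map bin label -> per-experiment fractions. Fold change is
    mean(condition) / mean(control); per-experiment fold changes
    (condition_i / mean(control)) feed the two-sided unpaired t-test
    (Student's equal-variance by default; Welch with
    ``equal_var=False``). Bins with a zero control mean are flagged.
    """
    rows = []
    for bin_label in condition:
        cond = np.asarray(condition[bin_label], float)
        ctrl = np.asarray(control[bin_label], float)
        if cond.size < 2 or ctrl.size < 2:
            raise ValueError("need >= 2 experiments per arm")
        ctrl_mean = ctrl.mean()
        if ctrl_mean == 0:
            rows.append(
                {
                    "bin": bin_label,
                    "fold_change": np.nan,
                    "p_value": np.nan,
                    "undefined": True,
                }
            )
            continue
        tt = stats.ttest_ind(cond, ctrl, equal_var=equal_var)
        rows.append(
            {
                "bin": bin_label,
                "fold_change": cond.mean() / ctrl_mean,
                "per_experiment_fold": (cond / ctrl_mean).tolist(),
                "p_value": float(tt.pvalue),
                "undefined": False,
            }
        )
    return pd.DataFrame(rows).set_index("bin")


# ---------------------------------------------------------------------------
# expression-range gating


@dataclass(frozen=True)
class ExpressionGate:
    """Endogenous expression window from wild-type nuclear intensities.

    Bounds are the 1st and 99th percentiles of the wild-type population;
    ``corr_fix`` rescales fixed-cell stain intensities to the live-
    imaging scale (mean live / mean fixed) before gating.
    """

    lower: float
    upper: float
    corr_fix: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")
        if self.corr_fix <= 0:
            raise ValueError("corr_fix must be positive")


def expression_gate(
    wt_intensities: np.ndarray,
    live_means: np.ndarray,
    fixed_means: np.ndarray,
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> ExpressionGate:
    wt = np.asarray(wt_intensities, float)
    if wt.size == 0 or np.asarray(live_means).size == 0:
        raise ValueError("empty inputs")
    if wt.size < 100:
        warnings.warn(
            f"only {wt.size} wild-type nuclei; percentile bounds will be noisy",
            stacklevel=2,
        )
    lo, hi = np.percentile(wt, percentiles)
    corr = float(np.mean(live_means) / np.mean(fixed_means))
    return ExpressionGate(float(lo), float(hi), corr)


def apply_gate(
    intensities: np.ndarray, gate: ExpressionGate, fixed: bool = False
) -> np.ndarray:
    """Boolean mask of nuclei strictly inside the expression window.

    With ``fixed=True`` the intensities come from a fixed stain and are
    mapped to the live scale by corr_fix first. Values exactly on a
    bound are excluded (strict inequalities)."""
    x = np.asarray(intensities, float)
    if fixed:
        x = x * gate.corr_fix
    return (x > gate.lower) & (x < gate.upper)
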
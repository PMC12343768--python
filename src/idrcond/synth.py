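"""Synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here:
two-exponential dwell-time mixtures discretized to the camera frame
interval, tracker-style track tables with blinking, IDR sequences with
controlled charge blockiness plus IDRome-like background sets, nuclear
images with Gaussian clusters of known molecule number, and condensate
recruitment time courses from a phenomenological feedback ODE with
multiplicative photobleaching. All generators are seeded and
reproducible, and every generator returns machine-readable ground
truth next to its data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .grammar import AA_ORDER, patterning_delta, UndefinedStatisticError
from .seqio import DEFAULT_GROUPS, IDRSequence
from .smt import DwellSample

# ---------------------------------------------------------------------------
# dwell times


@dataclass(frozen=True)
class DwellSimConfig:
    """Two-exponential dwell mixture, camera-discretized and truncated.

    Defaults mirror the measured chromatin-binding populations:
    non-specific tau 1.2 s, specific tau 7 s, 150 ms frames, 80 s
    longest observable dwell. The fast fraction A = 0.7 is an assumed
    mixing weight (the fitted fraction is not reported by the
    measurements the simulation emulates).
    """

    n: int = 10_000
    A: float = 0.7
    tau_fast: float = 1.2
    tau_slow: float = 7.0
    frame_interval: float = 0.15
    t_max: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.A < 1.0):
            raise ValueError("A must lie in (0, 1)")
        if not (0.0 < self.tau_fast < self.tau_slow):
            raise ValueError("require 0 < tau_fast < tau_slow")
        if self.t_max <= self.tau_slow:
            raise ValueError("t_max must exceed tau_slow")
        if self.n < 0:
            raise ValueError("n must be non-negative")


def sim_dwells(cfg: DwellSimConfig) -> tuple[DwellSample, dict]:
    """Draw dwells from the mixture, round up to whole frames, truncate.

    Rounding up models a molecule present for any part of a frame being
    detected in it (mean bias +dt/2).
    """
    rng = np.random.default_rng(cfg.seed)
    fast = rng.random(cfg.n) < cfg.A
    tau = np.where(fast, cfg.tau_fast, cfg.tau_slow)
    raw = rng.exponential(tau)
    dt = cfg.frame_interval
    disc = np.ceil(np.maximum(raw, 1e-12) / dt) * dt
    # truncate at the longest observable dwell, kept on the frame grid
    disc = np.minimum(disc, np.floor(cfg.t_max / dt) * dt)
    truth = {**asdict(cfg), "n_fast": int(fast.sum()), "raw_mean": float(raw.mean()) if cfg.n else 0.0}
    return DwellSample(disc, dt, experiment_id=f"sim-seed{cfg.seed}"), truth


def sim_track_table(
    cfg: DwellSimConfig,
    n_noise_tracks: int = 0,
    blink_rate: float = 0.0,
    fov_px: float = 50.0,
    movie_frames: int = 600,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tracker-style table of bound-molecule tracks.

    Each simulated dwell becomes a run of consecutive frames; interior
    frames blink off with probability ``blink_rate`` (runs of more than
    two missing frames are repaired, matching the tracker's gap-closing
    limit). Noise tracks are single-frame detections. Returns
    (table, truth) where truth maps track_id to the ground-truth dwell.
    """
    sample, _ = sim_dwells(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    dt = cfg.frame_interval
    rows, truth_rows = [], []
    tid = 0
    for dwell in sample.dwells:
        n_frames = max(int(round(dwell / dt)), 1)
        start = int(rng.integers(0, max(movie_frames - n_frames, 1)))
        frames = list(range(start, start + n_frames))
        if blink_rate > 0 and n_frames > 2:
            interior = frames[1:-1]
            kept = [frames[0]]
            dropped_run = 0
            for f in interior:
                if rng.random() < blink_rate and dropped_run < 2:
                    dropped_run += 1
                else:
                    kept.append(f)
                    dropped_run = 0
            kept.append(frames[-1])
            frames = kept
        x, y = rng.uniform(0, fov_px, 2)
        for f in frames:
            rows.append(
                {
                    "track_id": tid,
                    "frame": f,
                    "x": x + rng.normal(0, 0.1),
                    "y": y + rng.normal(0, 0.1),
                    "intensity": rng.normal(100, 10),
                    "nucleus_id": 0,
                }
            )
        truth_rows.append({"track_id": tid, "dwell_s": float(dwell)})
        tid += 1
    for _ in range(n_noise_tracks):
        x, y = rng.uniform(0, fov_px, 2)
        rows.append(
            {
                "track_id": tid,
                "frame": int(rng.integers(0, movie_frames)),
                "x": x,
                "y": y,
                "intensity": rng.normal(50, 10),
                "nucleus_id": 0,
            }
        )
        truth_rows.append({"track_id": tid, "dwell_s": np.nan})
        tid += 1
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# IDR sequences

#: disorder-like amino-acid frequencies used for IDRome-style backgrounds
#: (disorder-promoting residues P/S/Q/E/K/G enriched, hydrophobics and
#: aromatics depleted)
IDR_BASE_FREQS = {
    "A": 0.08, "C": 0.01, "D": 0.06, "E": 0.09, "F": 0.02,
    "G": 0.09, "H": 0.025, "I": 0.02, "K": 0.07, "L": 0.05,
    "M": 0.015, "N": 0.04, "P": 0.08, "Q": 0.06, "R": 0.05,
    "S": 0.12, "T": 0.06, "V": 0.04, "W": 0.005, "Y": 0.015,
}


@dataclass(frozen=True)
class IDRSimConfig:
    """Random IDR at a controlled group composition, optionally driven
    toward a target charge-patterning delta by Monte-Carlo swaps."""

    length: int = 100
    composition: tuple[tuple[str, float], ...] = (("neg", 0.2), ("pos", 0.1))
    target_delta: float | None = None
    x_group: str = "neg"
    y_group: str = "pos"
    tolerance: float = 1e-3
    max_iter: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 12:
            raise ValueError("length must be >= 12")
        total = sum(f for _, f in self.composition)
        if total > 1.0 + 1e-9:
            raise ValueError("composition fractions must sum to <= 1")


def _compose_residues(cfg: IDRSimConfig, rng: np.random.Generator) -> list[str]:
    residues: list[str] = []
    for group, frac in cfg.composition:
        members = sorted(DEFAULT_GROUPS[group])
        count = int(round(frac * cfg.length))
        residues.extend(rng.choice(members, size=count).tolist())
    filler = cfg.length - len(residues)
    if filler < 0:
        raise ValueError("composition counts exceed sequence length")
    neutral = list("GS")
    residues.extend(rng.choice(neutral, size=filler).tolist())
    return residues


def sim_idr(cfg: IDRSimConfig) -> tuple[str, float, bool]:
    """Random sequence at the requested composition.

    Without a target delta the arrangement is a uniform shuffle. With
    ``target_delta`` set, seeded position swaps are accepted whenever
    they move delta toward the target, stopping at ``tolerance`` or
    ``max_iter``; returns (sequence, achieved delta, target_reached).
    A target outside the reachable range ends best-effort with
    ``target_reached=False``.
    """
    rng = np.random.default_rng(cfg.seed)
    residues = _compose_residues(cfg, rng)
    rng.shuffle(residues)
    seq = residues

    def delta_of(s: list[str]) -> float:
        return patterning_delta("".join(s), cfg.x_group, cfg.y_group)

    current = delta_of(seq)
    if cfg.target_delta is None:
        return "".join(seq), current, True
    target = cfg.target_delta
    best_err = abs(current - target)
    for _ in range(cfg.max_iter):
        if best_err < cfg.tolerance:
            break
        i, j = rng.integers(0, cfg.length, 2)
        if seq[i] == seq[j]:
            continue
        seq[i], seq[j] = seq[j], seq[i]
        cand = delta_of(seq)
        err = abs(cand - target)
        if err < best_err:
            best_err, current = err, cand
        else:
            seq[i], seq[j] = seq[j], seq[i]
    return "".join(seq), current, best_err < cfg.tolerance


def blocky_arrangement(cfg: IDRSimConfig) -> str:
    """Fully segregated arrangement of the same composition (contiguous
    group blocks) — the delta-maximizing layout."""
    rng = np.random.default_rng(cfg.seed)
    residues = _compose_residues(cfg, rng)
    groups = dict(DEFAULT_GROUPS)

    def key(a: str) -> int:
        order = [cfg.x_group, cfg.y_group]
        for rank, g in enumerate(order):
            if a in groups[g]:
                return rank
        return len(order)

    return "".join(sorted(residues, key=key))


def sim_idrome(
    n: int = 500,
    seed: int = 0,
    length_range: tuple[int, int] = (40, 300),
    composition_sampler=None,
) -> list[IDRSequence]:
    """Background set of disorder-like random sequences.

    The default composition sampler jitters the base disordered-residue
    frequencies with a Dirichlet draw, so background IDRs vary in
    composition the way a proteome-wide IDR set does.
    """
    rng = np.random.default_rng(seed)
    aas = list(IDR_BASE_FREQS)
    base = np.array([IDR_BASE_FREQS[a] for a in aas])
    out = []
    for i in range(n):
        if composition_sampler is not None:
            probs = composition_sampler(rng)
        else:
            probs = rng.dirichlet(base * 120)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(aas, size=length, p=probs))
        out.append(IDRSequence(f"bg{i:05d}", 1, length, seq))
    return out


# ---------------------------------------------------------------------------
# cluster scenes


def sim_cluster_scene(
    shape: tuple[int, int] = (64, 64),
    background: float = 100.0,
    clusters: list[tuple[float, float, float]] = (),
    unitary: float = 100.0,
    psf_sigma: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    nucleus_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Flat-background nucleus with Gaussian clusters of known size.

    Each cluster (x, y, molecules) adds an isotropic Gaussian whose
    full-plane integral is molecules * unitary. Gaussian read noise is
    added everywhere. Returns (image, nucleus_mask, truth table).
    Warns when two cluster centers sit closer than 3 sigma (fits will
    interfere).
    """
    rng = np.random.default_rng(seed)
    img = np.full(shape, float(background))
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    centers = [(c[0], c[1]) for c in clusters]
    for i, (x1, y1) in enumerate(centers):
        for x2, y2 in centers[i + 1 :]:
            if math.hypot(x1 - x2, y1 - y2) < 3 * psf_sigma:
                warnings.warn(
                    f"cluster centers ({x1},{y1}) and ({x2},{y2}) are closer "
                    f"than 3 sigma; fits may interfere",
                    stacklevel=2,
                )
    rows = []
    for x0, y0, molecules in clusters:
        total = molecules * unitary
        amp = total / (2 * np.pi * psf_sigma**2)
        img += amp * np.exp(
            -(((xx - x0) ** 2) + (yy - y0) ** 2) / (2 * psf_sigma**2)
        )
        rows.append(
            {
                "x": x0,
                "y": y0,
                "molecules": molecules,
                "total_integral": total,
                "psf_sigma": psf_sigma,
            }
        )
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, shape)
    if nucleus_mask is None:
        nucleus_mask = np.ones(shape, dtype=bool)
    return img, nucleus_mask, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recruitment time courses


@dataclass(frozen=True)
class RecruitmentSimConfig:
    """Phenomenological condensate-recruitment ODE on a 2-minute grid.

    Y (YAP on condensates) is driven after rapamycin addition and
    amplified by Mediator through a positive-feedback gain; M (Med1)
    follows Y; P (Pol2) follows M but is suppressed by accumulated
    transcript R (delayed negative feedback -> adaptive response).
    Setting ``drb_time`` zeroes transcript production from that time,
    emulating elongation inhibition. Rates are per minute and are
    phenomenological — chosen for realistic curve shapes, not measured.
    Observed intensities are (truth + baseline + noise) scaled by
    multiplicative photobleaching exp(-t / bleach_tau).
    """

    t_max_min: float = 120.0
    dt_min: float = 2.0
    rapamycin_time: float = 2.0
    k_on_yap: float = 100.0
    k_fb: float = 0.01
    d_y: float = 0.1
    k_med_on: float = 0.05
    k_med_off: float = 0.2
    k_pol_on: float = 0.02
    d_pol: float = 0.05
    k_neg: float = 0.01
    k_rna: float = 0.02
    k_rna_decay: float = 0.01
    drb_time: float | None = None
    bleach_tau: float = 600.0
    noise_sd: float = 10.0
    yap_baseline: float = 100.0
    partner_baseline: float = 200.0
    track_cv: float = 0.1
    n_tracks: int = 40
    n_control_tracks: int = 40
    partner: str = "med1"  # which species is read out as the partner channel
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "k_on_yap", "k_fb", "d_y", "k_med_on", "k_med_off",
            "k_pol_on", "d_pol", "k_neg", "k_rna", "k_rna_decay",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drb_time is not None and not (
            0 <= self.drb_time <= self.t_max_min
        ):
            raise ValueError("drb_time must lie within the acquisition window")
        if self.partner not in ("med1", "pol2"):
            raise ValueError("partner must be 'med1' or 'pol2'")
        if self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be positive")


def _integrate_truth(cfg: RecruitmentSimConfig, control: bool) -> dict[str, np.ndarray]:
    """RK4 integration of the feedback ODE on a fine grid, sampled at the
    2-minute acquisition grid. Control arms have no Med1/Pol2 coupling."""
    k_med_on = 0.0 if control else cfg.k_med_on
    k_pol_on = 0.0 if control else cfg.k_pol_on

    def rhs(t, state):
        y, m, p, r = state
        drive = cfg.k_on_yap if t >= cfg.rapamycin_time else 0.0
        k_rna = cfg.k_rna
        if cfg.drb_time is not None and t >= cfg.drb_time:
            k_rna = 0.0
        return np.array(
            [
                drive + cfg.k_fb * m - cfg.d_y * y,
                k_med_on * y - cfg.k_med_off * m,
                k_pol_on * m - cfg.d_pol * p - cfg.k_neg * r * p,
                k_rna * p - cfg.k_rna_decay * r,
            ]
        )

    h = 0.05  # minutes; piecewise-constant drives make adaptive steppers moot
    n_steps = int(round(cfg.t_max_min / h))
    state = np.zeros(4)
    t_grid = np.arange(0.0, cfg.t_max_min + 1e-9, cfg.dt_min)
    out = np.zeros((t_grid.size, 4))
    out[0] = state
    next_idx = 1
    for i in range(n_steps):
        t = i * h
        k1 = rhs(t, state)
        k2 = rhs(t + h / 2, state + h / 2 * k1)
        k3 = rhs(t + h / 2, state + h / 2 * k2)
        k4 = rhs(t + h, state + h * k3)
        state = state + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t_next = (i + 1) * h
        while next_idx < t_grid.size and t_next >= t_grid[next_idx] - 1e-9:
            out[next_idx] = state
            next_idx += 1
    return {
        "t_min": t_grid,
        "Y": out[:, 0],
        "M": out[:, 1],
        "P": out[:, 2],
        "R": out[:, 3],
    }


def sim_recruitment(cfg: RecruitmentSimConfig) -> tuple[pd.DataFrame, dict]:
    """Long-format condensate track table plus ground-truth curves.

    Arms: ``yap`` (full coupling) and ``control`` (fluorophore-only:
    no Med1/Pol2 response, partner channel shows baseline + bleaching
    only). Per-track amplitudes vary log-normally (CV ``track_cv``);
    per-frame Gaussian noise and multiplicative bleaching are applied to
    the observed channels.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = {
        "yap": _integrate_truth(cfg, control=False),
        "control": _integrate_truth(cfg, control=True),
    }
    partner_key = "M" if cfg.partner == "med1" else "P"
    rows = []
    tid = 0
    for arm, n_arm in (("yap", cfg.n_tracks), ("control", cfg.n_control_tracks)):
        tr = truth[arm]
        t = tr["t_min"]
        bleach = np.exp(-t / cfg.bleach_tau)
        for _ in range(n_arm):
            amp = rng.lognormal(0.0, cfg.track_cv)
            area = float(np.clip(rng.normal(1.0, 0.15), 0.2, 2.5))
            scaffold = 1000.0 * area
            yap_obs = (
                tr["Y"] * amp + cfg.yap_baseline + rng.normal(0, cfg.noise_sd, t.size)
            ) * bleach
            partner_truth = tr[partner_key] * amp if arm == "yap" else np.zeros(t.size)
            partner_obs = (
                partner_truth
                + cfg.partner_baseline
                + rng.normal(0, cfg.noise_sd, t.size)
            ) * bleach
            for i, tm in enumerate(t):
                rows.append(
                    {
                        "track_id": tid,
                        "frame": i,
                        "t_min": float(tm),
                        "area": area,
                        "scaffold": scaffold + rng.normal(0, cfg.noise_sd),
                        "yap": float(yap_obs[i]),
                        "partner": float(partner_obs[i]),
                        "nucleus_id": tid % 10,
                        "experiment_id": f"sim-seed{cfg.seed}",
                        "arm": arm,
                    }
                )
            tid += 1
    truth_out = {
        "config": asdict(cfg),
        "t_min": truth["yap"]["t_min"].tolist(),
        "Y": truth["yap"]["Y"].tolist(),
        "M": truth["yap"]["M"].tolist(),
        "P": truth["yap"]["P"].tolist(),
        "R": truth["yap"]["R"].tolist(),
        "partner_truth": truth["yap"][partner_key].tolist(),
    }
    return pd.DataFrame(rows), truth_out
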
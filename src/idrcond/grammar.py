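"""Charge profiles, composition features, and patterning statistics.

The patterning statistic delta follows the kappa family of charge-
patterning descriptors: for a pair of disjoint residue groups (X, Y) it
measures how much the window-level asymmetry between X and Y deviates
from the whole-sequence asymmetry. Blocky (segregated) arrangements give
large delta; well-mixed arrangements give small delta. Significance is
assessed as a z-score against compositionally identical shuffles, and
composition features are scored against an IDRome background
(mean/SD over a large set of disordered regions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .seqio import DEFAULT_GROUPS, IDRSequence, validate_groups

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_WINDOWS = (5, 6)


class UndefinedStatisticError(ValueError):
    """Patterning statistic undefined (no residues of either group)."""


# ---------------------------------------------------------------------------
# charge profile


def charge_profile(seq: str, window: int) -> np.ndarray:
    """Sliding net-charge profile.

    For every full window of length ``window`` the fraction of positive
    residues (K, R) minus the fraction of negative residues (D, E) is
    computed; each residue is then assigned the mean over all full windows
    that contain it, so residues near the termini average fewer windows.
    Values lie in [-1, 1] and are identically zero for charge-free
    sequences.
    """
    n = len(seq)
    if window < 1 or window > n:
        raise ValueError(f"window {window} invalid for sequence length {n}")
    charge = np.array(
        [1.0 if a in "KR" else -1.0 if a in "DE" else 0.0 for a in seq]
    )
    # window means, then per-residue average over containing windows
    kernel = np.ones(window) / window
    w = np.convolve(charge, kernel, mode="valid")  # length n - window + 1
    out = np.zeros(n)
    counts = np.zeros(n)
    # residue i (0-based) is in windows max(0, i-window+1) .. min(i, n-window)
    for i in range(n):
        lo = max(0, i - window + 1)
        hi = min(i, n - window)
        out[i] = w[lo : hi + 1].sum()
        counts[i] = hi - lo + 1
    return out / counts


# ---------------------------------------------------------------------------
# composition


def composition_features(
    seq: str, groups: dict[str, frozenset[str]] | None = None
) -> dict[str, float]:
    """Composition feature vector: 20 amino-acid fractions, group
    fractions, FCR (fraction of charged residues) and NCPR (net charge
    per residue)."""
    if not seq:
        raise ValueError("empty sequence")
    groups = dict(groups or DEFAULT_GROUPS)
    validate_groups(groups)
    n = len(seq)
    feats: dict[str, float] = {}
    for aa in AA_ORDER:
        feats[f"frac_{aa}"] = seq.count(aa) / n
    for name, members in groups.items():
        feats[f"frac_{name}"] = sum(seq.count(a) for a in members) / n
    fpos = sum(seq.count(a) for a in "KR") / n
    fneg = sum(seq.count(a) for a in "DE") / n
    feats["FCR"] = fpos + fneg
    feats["NCPR"] = fpos - fneg
    return feats


# ---------------------------------------------------------------------------
# patterning


def _resolve_groups(
    group_x, group_y, groups: dict[str, frozenset[str]]
) -> tuple[frozenset[str], frozenset[str], str, str]:
    if isinstance(group_x, str):
        name_x, set_x = group_x, groups[group_x]
    else:
        set_x = frozenset(group_x)
        name_x = "+".join(sorted(set_x))
    if group_y is None:
        set_y = frozenset(AA_ORDER) - set_x
        name_y = "other"
    elif isinstance(group_y, str):
        name_y, set_y = group_y, groups[group_y]
    else:
        set_y = frozenset(group_y)
        name_y = "+".join(sorted(set_y))
    if set_x & set_y:
        raise ValueError(
            f"patterning groups must be disjoint; {name_x} and {name_y} "
            f"share {sorted(set_x & set_y)}"
        )
    return set_x, set_y, name_x, name_y


def _window_sums(indicator: np.ndarray, g: int) -> np.ndarray:
    """Row-wise sliding-window sums of a (rows, L) 0/1 array."""
    cs = np.cumsum(indicator, axis=-1, dtype=np.float64)
    zero = np.zeros(cs.shape[:-1] + (1,))
    cs = np.concatenate([zero, cs], axis=-1)
    return cs[..., g:] - cs[..., :-g]


def _delta_rows(
    ix: np.ndarray, iy: np.ndarray, windows: tuple[int, ...]
) -> np.ndarray:
    """delta for each row of indicator arrays ``ix``, ``iy`` (rows, L)."""
    ix = np.atleast_2d(ix).astype(np.float64)
    iy = np.atleast_2d(iy).astype(np.float64)
    L = ix.shape[-1]
    fx_all = ix.sum(axis=-1) / L
    fy_all = iy.sum(axis=-1) / L
    denom_all = fx_all + fy_all
    sigma_bar = np.where(
        denom_all > 0, (fx_all - fy_all) ** 2 / np.where(denom_all > 0, denom_all, 1.0), 0.0
    )
    deltas = []
    for g in windows:
        if g > L:
            raise ValueError(f"window {g} exceeds sequence length {L}")
        fx = _window_sums(ix, g) / g
        fy = _window_sums(iy, g) / g
        denom = fx + fy
        sigma = np.where(denom > 0, (fx - fy) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
        deltas.append(((sigma - sigma_bar[..., None]) ** 2).mean(axis=-1))
    return np.mean(deltas, axis=0)


def patterning_delta(
    seq: str,
    group_x="neg",
    group_y="pos",
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    groups: dict[str, frozenset[str]] | None = None,
) -> float:
    """Kappa-style patterning statistic for groups X vs Y.

    For each window size g, sigma_i = (fX_i - fY_i)^2 / (fX_i + fY_i) over
    full windows (0 where the window holds no X or Y residue) and
    sigma_bar is the same quantity from whole-sequence fractions;
    delta_g is the mean squared deviation of sigma_i around sigma_bar.
    The returned delta is the mean of delta_g over ``windows``.
    Pass ``group_y=None`` to score segregation of X against everything
    else.
    """
    groups = dict(groups or DEFAULT_GROUPS)
    set_x, set_y, _, _ = _resolve_groups(group_x, group_y, groups)
    ix = np.array([a in set_x for a in seq])
    iy = np.array([a in set_y for a in seq])
    if not (ix.any() or iy.any()):
        raise UndefinedStatisticError(
            "sequence has no residues of either patterning group"
        )
    return float(_delta_rows(ix, iy, windows)[0])


@dataclass(frozen=True)
class PatterningStat:
    group_x: str
    group_y: str
    delta: float
    z: float
    n_shuffles: int
    seed: int | None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be non-negative")


def _shuffle_matrix(n_shuffles: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """(n_shuffles, length) array of permutation indices."""
    return np.argsort(rng.random((n_shuffles, length)), axis=1)


def patterning_zscore(
    seq: str,
    group_x="neg",
    group_y="pos",
    n_shuffles: int = 10_000,
    seed: int | None = 0,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    groups: dict[str, frozenset[str]] | None = None,
    _perm: np.ndarray | None = None,
) -> PatterningStat:
    """z-score of the observed delta against uniform-shuffle nulls.

    z > 0 means the sequence is more segregated (blocky) than
    compositionally identical random sequences. If every shuffle yields
    the same delta (e.g. a homopolymer) the null is degenerate and z is
    reported as 0 with ``degenerate=True``.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    groups = dict(groups or DEFAULT_GROUPS)
    set_x, set_y, name_x, name_y = _resolve_groups(group_x, group_y, groups)
    ix = np.array([a in set_x for a in seq])
    iy = np.array([a in set_y for a in seq])
    if not (ix.any() or iy.any()):
        raise UndefinedStatisticError(
            "sequence has no residues of either patterning group"
        )
    obs = float(_delta_rows(ix, iy, windows)[0])
    if _perm is None:
        rng = np.random.default_rng(seed)
        _perm = _shuffle_matrix(n_shuffles, len(seq), rng)
    null = _delta_rows(ix[_perm], iy[_perm], windows)
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        return PatterningStat(name_x, name_y, obs, 0.0, n_shuffles, seed, True)
    z = (obs - float(null.mean())) / sd
    return PatterningStat(name_x, name_y, obs, float(z), n_shuffles, seed, False)


# ---------------------------------------------------------------------------
# IDRome background and reports


@dataclass
class IDRomeBackground:
    """Per-feature mean and SD over a set of background IDRs."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_background: int

    def __post_init__(self) -> None:
        if self.n_background < 2:
            raise ValueError("background needs >= 2 IDRs")


def build_background(
    idrs: list[IDRSequence | str],
    groups: dict[str, frozenset[str]] | None = None,
) -> IDRomeBackground:
    """Composition-feature statistics over a background IDR set."""
    if len(idrs) < 2:
        raise ValueError("background needs >= 2 IDRs")
    seqs = [i.sequence if isinstance(i, IDRSequence) else i for i in idrs]
    rows = [composition_features(s, groups) for s in seqs]
    keys = rows[0].keys()
    mat = {k: np.array([r[k] for r in rows]) for k in keys}
    return IDRomeBackground(
        mean={k: float(v.mean()) for k, v in mat.items()},
        sd={k: float(v.std(ddof=1)) for k, v in mat.items()},
        n_background=len(seqs),
    )


def composition_zscores(
    seq: str,
    background: IDRomeBackground,
    groups: dict[str, frozenset[str]] | None = None,
) -> tuple[dict[str, float], dict[str, bool]]:
    """Per-feature z against the background; returns (z, degenerate flags).

    Features whose background SD is zero are flagged degenerate and
    reported as z = 0.
    """
    feats = composition_features(seq, groups)
    z: dict[str, float] = {}
    degenerate: dict[str, bool] = {}
    for k, x in feats.items():
        sd = background.sd[k]
        if sd == 0.0:
            z[k] = 0.0
            degenerate[k] = True
        else:
            z[k] = (x - background.mean[k]) / sd
            degenerate[k] = False
    return z, degenerate


@dataclass
class GrammarReport:
    """Composition and patterning z-scores for one IDR.

    ``display_mask`` marks features with |z| >= 1, the conventional
    display threshold for grammar heat maps.
    """

    idr_id: str
    composition_z: dict[str, float]
    patterning_z: dict[str, float]
    degenerate: dict[str, bool] = field(default_factory=dict)

    @property
    def all_z(self) -> dict[str, float]:
        return {**self.composition_z, **self.patterning_z}

    @property
    def display_mask(self) -> dict[str, bool]:
        return {k: abs(v) >= 1.0 for k, v in self.all_z.items()}

    def to_json(self) -> str:
        return json.dumps(
            {
                "idr_id": self.idr_id,
                "composition_z": self.composition_z,
                "patterning_z": self.patterning_z,
                "degenerate": self.degenerate,
                "display_mask": self.display_mask,
            },
            indent=2,
            sort_keys=True,
        )


def _patterning_pairs(
    groups: dict[str, frozenset[str]]
) -> list[tuple[str, str | None]]:
    """Self-patterning of each group plus all disjoint group pairs."""
    names = list(groups)
    pairs: list[tuple[str, str | None]] = [(n, None) for n in names]
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if not (groups[a] & groups[b]):
                pairs.append((a, b))
    return pairs


def grammar_report(
    idr: IDRSequence | str,
    background: IDRomeBackground,
    groups: dict[str, frozenset[str]] | None = None,
    n_shuffles: int = 10_000,
    seed: int | None = 0,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
) -> GrammarReport:
    """Full grammar report: composition z vs the IDRome background plus
    self and pairwise patterning z vs shuffle nulls.

    One shared set of shuffles is drawn per IDR and reused across all
    patterning features (the null permutations are feature-independent).
    """
    groups = dict(groups or DEFAULT_GROUPS)
    validate_groups(groups)
    if isinstance(idr, IDRSequence):
        idr_id, seq = idr.id, idr.sequence
    else:
        idr_id, seq = "idr", idr
    comp_z, degen = composition_zscores(seq, background, groups)
    rng = np.random.default_rng(seed)
    perm = _shuffle_matrix(n_shuffles, len(seq), rng)
    patt_z: dict[str, float] = {}
    for gx, gy in _patterning_pairs(groups):
        key = f"patt_{gx}_vs_{gy or 'other'}"
        try:
            stat = patterning_zscore(
                seq, gx, gy, n_shuffles, seed, windows, groups, _perm=perm
            )
        except UndefinedStatisticError:
            patt_z[key] = 0.0
            degen[key] = True
            continue
        patt_z[key] = stat.z
        degen[key] = stat.degenerate
    return GrammarReport(idr_id, comp_z, patt_z, degen)


def report_table(reports: list[GrammarReport], masked: bool = True):
    """Feature x IDR z-matrix as a pandas DataFrame.

    With ``masked=True`` only features with |z| >= 1 in at least one IDR
    are kept (the conventional display rule for grammar heat maps).
    """
    import pandas as pd

    df = pd.DataFrame({r.idr_id: r.all_z for r in reports})
    if masked:
        df = df[(df.abs() >= 1.0).any(axis=1)]
    return df
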
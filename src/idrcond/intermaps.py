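"""Mean-field intermolecular interaction maps between two IDRs.

For every pair of residue windows (one from each sequence, stride 1,
full windows only) the map entry is the mean pairwise contact weight
w(a, b) over all residue pairs in the two windows. The weight matrix is
pluggable: the default is a documented simplified electrostatic/aromatic
potential, and any 20x20 matrix (e.g. one derived from a coarse-grained
force field) can be loaded from TSV. Sign convention: negative epsilon
means attraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grammar import AA_ORDER

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

DEFAULT_WINDOW = 31


@dataclass(frozen=True)
class PairMatrix:
    """Symmetric 20x20 residue-pair weight matrix, negative = attractive."""

    values: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 20):
            raise ValueError("pair matrix must be 20x20")
        if not np.all(np.isfinite(v)):
            raise ValueError("pair matrix entries must be finite")
        if not np.allclose(v, v.T):
            raise ValueError("pair matrix must be symmetric")
        object.__setattr__(self, "values", v)

    def w(self, a: str, b: str) -> float:
        try:
            return float(self.values[_AA_INDEX[a], _AA_INDEX[b]])
        except KeyError as exc:
            raise ValueError(f"residue {exc.args[0]!r} not in matrix alphabet")

    @classmethod
    def from_pairs(cls, pairs: dict[tuple[str, str], float], name: str = "custom"):
        v = np.zeros((20, 20))
        for (a, b), val in pairs.items():
            v[_AA_INDEX[a], _AA_INDEX[b]] = val
            v[_AA_INDEX[b], _AA_INDEX[a]] = val
        return cls(v, name)

    @classmethod
    def from_tsv(cls, path, name: str | None = None):
        """Load from a TSV with a header row/column of one-letter codes."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.loc[list(AA_ORDER), list(AA_ORDER)]
        return cls(df.to_numpy(dtype=float), name or str(path))

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=list(AA_ORDER), columns=list(AA_ORDER)).to_csv(
            path, sep="\t"
        )


def default_matrix() -> PairMatrix:
    """Simplified electrostatic + aromatic potential.

    Opposite charges attract (-1.0), like charges repel (+1.0),
    aromatic-aromatic stacking attracts (-0.7), cation-pi attracts
    (-0.5); every other pair is neutral. Positive residues are K and R
    (H neutral at physiological pH).
    """
    pos, neg, aro = "KR", "DE", "FWY"
    pairs: dict[tuple[str, str], float] = {}
    for p in pos:
        for n in neg:
            pairs[(p, n)] = -1.0
    for a in pos:
        for b in pos:
            pairs[(a, b)] = 1.0
    for a in neg:
        for b in neg:
            pairs[(a, b)] = 1.0
    for a in aro:
        for b in aro:
            pairs[(a, b)] = -0.7
    for a in aro:
        for p in pos:
            pairs[(a, p)] = -0.5
    return PairMatrix.from_pairs(pairs, name="simple-electrostatic")


def _onehot(seq: str) -> np.ndarray:
    try:
        idx = np.array([_AA_INDEX[a] for a in seq])
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in matrix alphabet")
    oh = np.zeros((len(seq), 20))
    oh[np.arange(len(seq)), idx] = 1.0
    return oh


def _window_counts(seq: str, window: int) -> np.ndarray:
    """(n_windows, 20) residue counts for each full window."""
    oh = _onehot(seq)
    cs = np.vstack([np.zeros(20), np.cumsum(oh, axis=0)])
    return cs[window:] - cs[:-window]


def window_epsilon(win_a: str, win_b: str, matrix: PairMatrix) -> float:
    """Mean-field interaction of two residue windows:
    epsilon = mean over all residue pairs (i in A, j in B) of w(a_i, b_j).
    Order-independent within each window."""
    if not win_a or not win_b:
        raise ValueError("windows must be non-empty")
    ca = _onehot(win_a).sum(axis=0)
    cb = _onehot(win_b).sum(axis=0)
    return float(ca @ matrix.values @ cb / (len(win_a) * len(win_b)))


@dataclass
class InterMap:
    """Window x window interaction map plus per-residue attractive vectors."""

    id_a: str
    id_b: str
    window: int
    epsilon: np.ndarray  # (n_a - L + 1, n_b - L + 1)
    attractive_a: np.ndarray  # per residue of A, <= 0
    attractive_b: np.ndarray  # per residue of B, <= 0


def _attractive_vector(eps_neg_rowmean: np.ndarray, n: int, window: int) -> np.ndarray:
    """Average the per-window attractive means over the windows containing
    each residue (termini average fewer windows)."""
    out = np.zeros(n)
    for i in range(n):
        lo = max(0, i - window + 1)
        hi = min(i, n - window)
        out[i] = eps_neg_rowmean[lo : hi + 1].mean()
    return out


def intermap(
    seq_a: str,
    seq_b: str,
    window: int = DEFAULT_WINDOW,
    matrix: PairMatrix | None = None,
    id_a: str = "A",
    id_b: str = "B",
) -> InterMap:
    """Full window-by-window map between two sequences (stride 1).

    Map axes are 1-based window start positions. The per-residue
    attractive vector averages min(epsilon, 0) over every map cell whose
    window contains the residue, so only attractive (negative) cells
    contribute.
    """
    if len(seq_a) < window or len(seq_b) < window:
        raise ValueError(
            f"both sequences must be at least window={window} residues long"
        )
    matrix = matrix or default_matrix()
    ca = _window_counts(seq_a, window)  # (na, 20)
    cb = _window_counts(seq_b, window)  # (nb, 20)
    eps = ca @ matrix.values @ cb.T / (window * window)
    neg = np.minimum(eps, 0.0)
    att_a = _attractive_vector(neg.mean(axis=1), len(seq_a), window)
    att_b = _attractive_vector(neg.mean(axis=0), len(seq_b), window)
    return InterMap(id_a, id_b, window, eps, att_a, att_b)


def summarize_interaction(map_wt: InterMap, map_variant: InterMap) -> dict:
    """Compare two maps against the same partner: minimum epsilon, mean
    attractive epsilon, and attractive-cell fraction, with differences
    (variant minus wild type)."""
    if map_wt.window != map_variant.window:
        raise ValueError("maps were computed with different window sizes")
    if map_wt.epsilon.shape[1] != map_variant.epsilon.shape[1]:
        raise ValueError("maps have different partner sequences")

    def stats(m: InterMap) -> dict:
        e = m.epsilon
        att = e[e < 0]
        return {
            "min_epsilon": float(e.min()),
            "mean_attractive_epsilon": float(att.mean()) if att.size else 0.0,
            "attractive_fraction": float((e < 0).mean()),
        }

    s_wt, s_var = stats(map_wt), stats(map_variant)
    return {
        "wt": s_wt,
        "variant": s_var,
        "difference": {k: s_var[k] - s_wt[k] for k in s_wt},
    }
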
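"""Well-mixed-charge sequence design.

Given a wild-type protein whose IDRs carry blocky charge, produce a
variant in which the charged residues are dispersed ("well mixed") while
keeping the overall composition, the per-IDR net charge, the structured
inter-IDR segments, and a set of anchored negative positions exactly as
in the wild type. The variant is a pure permutation of the charged
residues among the charged positions of each IDR.

Conventions: extraction treats D/E as negative and K/R/H as positive
(histidine joins the positive pool so the two pools are of comparable
size), but the net-charge conservation check scores H as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

from .grammar import UndefinedStatisticError, patterning_delta, patterning_zscore


def _safe_delta(seq: str) -> float:
    """delta(neg, pos), or NaN when the statistic is undefined
    (charge-free sequence, or shorter than the analysis windows)."""
    try:
        return patterning_delta(seq, "neg", "pos")
    except (UndefinedStatisticError, ValueError):
        return math.nan

NEG_SET = frozenset("DE")
POS_SET = frozenset("KRH")

#: charge scheme for the net-charge conservation check (H is neutral here)
CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1, "H": 0}


@dataclass(frozen=True)
class DesignSpec:
    wt_sequence: str
    idr_regions: tuple[tuple[int, int], ...]
    fixed_negative_positions: tuple[int, ...] = ()
    neg_set: frozenset = NEG_SET
    pos_set: frozenset = POS_SET

    def __post_init__(self) -> None:
        n = len(self.wt_sequence)
        spans = sorted(self.idr_regions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("idr_regions overlap")
        for s, e in self.idr_regions:
            if not (1 <= s <= e <= n):
                raise ValueError(f"region ({s}, {e}) out of bounds")
        for p in self.fixed_negative_positions:
            if not any(s <= p <= e for s, e in self.idr_regions):
                raise ValueError(f"fixed position {p} outside the IDR regions")
            if self.wt_sequence[p - 1] not in self.neg_set:
                raise ValueError(
                    f"fixed position {p} holds "
                    f"{self.wt_sequence[p - 1]!r}, not a negative residue"
                )


@dataclass
class DesignResult:
    variant_sequence: str
    swapped_positions: list[int]
    net_charge_before: dict[str, int]
    net_charge_after: dict[str, int]
    delta_before: float
    delta_after: float


def _net_charge(seq: str) -> int:
    return sum(CHARGE.get(a, 0) for a in seq)


def _region_slice(seq: str, region: tuple[int, int]) -> str:
    s, e = region
    return seq[s - 1 : e]


def design_well_mixed(spec: DesignSpec, seed: int | None = None) -> DesignResult:
    """Disperse charged residues within each IDR region.

    Within each region (independently, so per-IDR net charge is conserved
    exactly) the charged positions — excluding anchored negatives — are
    emptied; their residues are split into a negative and a positive pool
    kept in N-to-C extraction order; the positions are then refilled in
    N-to-C order drawing alternately from the pools, negative first, so
    charges end up mostly every other. When one pool runs out the
    remainder of the other is appended in extraction order. Residues
    outside the regions, non-charged residues, and anchored positions are
    untouched. Deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic modules but unused by the default
    alternation.
    """
    seq = list(spec.wt_sequence)
    charged = spec.neg_set | spec.pos_set
    fixed = set(spec.fixed_negative_positions)
    swapped: list[int] = []
    for region in spec.idr_regions:
        s, e = region
        positions = [
            p
            for p in range(s, e + 1)
            if spec.wt_sequence[p - 1] in charged and p not in fixed
        ]
        neg_pool = [
            spec.wt_sequence[p - 1]
            for p in positions
            if spec.wt_sequence[p - 1] in spec.neg_set
        ]
        pos_pool = [
            spec.wt_sequence[p - 1]
            for p in positions
            if spec.wt_sequence[p - 1] in spec.pos_set
        ]
        pools = [neg_pool, pos_pool]
        take = 0  # alternation phase: 0 = negative next
        for p in positions:
            if not pools[take]:
                take = 1 - take  # one pool exhausted: drain the other
            residue = pools[take].pop(0)
            if seq[p - 1] != residue:
                swapped.append(p)
            seq[p - 1] = residue
            if pools[1 - take]:
                take = 1 - take
    variant = "".join(seq)
    region_ids = [f"{s}-{e}" for s, e in spec.idr_regions]
    before = {
        rid: _net_charge(_region_slice(spec.wt_sequence, r))
        for rid, r in zip(region_ids, spec.idr_regions)
    }
    after = {
        rid: _net_charge(_region_slice(variant, r))
        for rid, r in zip(region_ids, spec.idr_regions)
    }
    idr_wt = "".join(_region_slice(spec.wt_sequence, r) for r in spec.idr_regions)
    idr_var = "".join(_region_slice(variant, r) for r in spec.idr_regions)
    return DesignResult(
        variant_sequence=variant,
        swapped_positions=swapped,
        net_charge_before=before,
        net_charge_after=after,
        delta_before=_safe_delta(idr_wt),
        delta_after=_safe_delta(idr_var),
    )


def validate_variant(
    wt: str,
    variant: str,
    spec: DesignSpec,
    n_shuffles: int = 1000,
    seed: int | None = 0,
) -> dict:
    """Check the design contract and report patterning statistics.

    Checks: equal length, identical residue multiset, identical per-IDR
    net charge (H scored 0), anchored positions untouched, and identity
    outside the IDR regions. Also reports delta(neg vs pos) and its
    shuffle-null z for both sequences over the concatenated IDR
    segments.
    """
    if len(wt) != len(variant):
        raise ValueError("wt and variant must have equal length")
    checks: dict[str, bool] = {}
    checks["composition_identical"] = sorted(wt) == sorted(variant)
    region_ids = [f"{s}-{e}" for s, e in spec.idr_regions]
    checks["net_charge_per_idr"] = all(
        _net_charge(_region_slice(wt, r)) == _net_charge(_region_slice(variant, r))
        for r in spec.idr_regions
    )
    checks["fixed_positions_unchanged"] = all(
        wt[p - 1] == variant[p - 1] for p in spec.fixed_negative_positions
    )
    in_region = [False] * len(wt)
    for s, e in spec.idr_regions:
        for p in range(s, e + 1):
            in_region[p - 1] = True
    checks["non_idr_unchanged"] = all(
        w == v for w, v, r in zip(wt, variant, in_region) if not r
    )
    idr_wt = "".join(_region_slice(wt, r) for r in spec.idr_regions)
    idr_var = "".join(_region_slice(variant, r) for r in spec.idr_regions)
    try:
        stat_wt = patterning_zscore(idr_wt, "neg", "pos", n_shuffles, seed)
        stat_var = patterning_zscore(idr_var, "neg", "pos", n_shuffles, seed)
    except UndefinedStatisticError:

        class _NoStat:
            delta = math.nan
            z = math.nan

        stat_wt = stat_var = _NoStat()
    failures = [k for k, ok in checks.items() if not ok]
    return {
        "checks": checks,
        "passed": not failures,
        "failures": failures,
        "net_charge_wt": {
            rid: _net_charge(_region_slice(wt, r))
            for rid, r in zip(region_ids, spec.idr_regions)
        },
        "net_charge_variant": {
            rid: _net_charge(_region_slice(variant, r))
            for rid, r in zip(region_ids, spec.idr_regions)
        },
        "delta_wt": stat_wt.delta,
        "delta_variant": stat_var.delta,
        "z_wt": stat_wt.z,
        "z_variant": stat_var.z,
    }
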
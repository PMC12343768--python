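"""Single-molecule dwell-time survival analysis on simulated tracks.

Simulates the two-population chromatin-binding mixture (non-specific
tau 1.2 s, specific tau 7 s, fast fraction 0.7) discretized to 150 ms
frames, runs the full track-table round trip (extraction with
gap-inclusive dwells), fits the bi-exponential survival function, and
computes the population-bin fractions. A second arm with the long-lived
population halved emulates a solubilizing perturbation; per-experiment
bin fractions feed the fold-change t-test.

Writes results/dwell_fit.json and results/dwell_fold_change.csv.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from idrcond import smt, synth

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=10_000)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    table, truth = synth.sim_track_table(
        synth.DwellSimConfig(n=args.n, seed=args.seed), n_noise_tracks=200
    )
    sample = smt.extract_dwells(table)
    fit = smt.fit_dwell_sample(sample)
    bins = smt.dwell_bin_fractions(sample)
    print(
        f"{len(sample)} dwells -> A={fit.A:.2f}, tau_ns={fit.tau_ns:.2f} s, "
        f"tau_s={fit.tau_s:.2f} s (truth 0.70 / 1.2 s / 7 s)"
    )
    print("bin fractions:", {k: round(v, 3) for k, v in bins.items()})

    # perturbation arm: halve the slow (specific) fraction per experiment
    n_exp = 4
    ctrl_bins, cond_bins = [], []
    for e in range(n_exp):
        c, _ = synth.sim_dwells(
            synth.DwellSimConfig(n=3000, A=0.7, seed=args.seed + 10 + e)
        )
        p, _ = synth.sim_dwells(
            synth.DwellSimConfig(n=3000, A=0.85, seed=args.seed + 20 + e)
        )
        ctrl_bins.append(smt.dwell_bin_fractions(c))
        cond_bins.append(smt.dwell_bin_fractions(p))
    labels = list(ctrl_bins[0])
    stats = smt.fold_change_stats(
        {k: np.array([b[k] for b in cond_bins]) for k in labels},
        {k: np.array([b[k] for b in ctrl_bins]) for k in labels},
    )
    print("fold changes (perturbed / control):")
    for label, row in stats.iterrows():
        print(f"  {label}: {row['fold_change']:.2f} (p={row['p_value']:.3g})")

    (RESULTS / "dwell_fit.json").write_text(
        json.dumps(
            {
                "n_dwells": len(sample),
                "A": fit.A,
                "tau_ns_s": fit.tau_ns,
                "tau_s_s": fit.tau_s,
                "bin_fractions": bins,
            },
            indent=2,
        )
    )
    stats.drop(columns=["per_experiment_fold"]).to_csv(RESULTS / "dwell_fold_change.csv")
    print(f"wrote {RESULTS / 'dwell_fit.json'}")


if __name__ == "__main__":
    main()
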
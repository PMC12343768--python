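"""Cluster quantification: molecule counting and phase decomposition.

Calibrates the unitary (single-molecule) intensity and PSF width on a
clean sparse-label scene, then recovers molecule counts from noiseless
and noisy cluster scenes, builds the cluster-size survival curve, and
decomposes nuclei into dense and dilute phases across an expression
series (with no dense-phase buffering in the generator, the dilute
phase rises linearly with total intensity).

Writes results/cluster_recovery.csv and results/phase_series.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from idrcond import clusters as cl
from idrcond import synth

RESULTS = Path(__file__).resolve().parents[1] / "results"


def calibrate(seed: int) -> tuple[float, float]:
    spots = [(12 + 18 * i, 12 + 18 * j, 1) for i in range(5) for j in range(5)]
    img, _, _ = synth.sim_cluster_scene(
        shape=(104, 104), clusters=spots, unitary=100.0, noise_sd=0.5, seed=seed
    )
    recs = [cl.fit_gaussian2d(img, (x, y)) for x, y, _ in spots]
    unit = cl.calibrate_unitary([r.integral for r in recs])
    psf = float(np.median([(r.sigma_x + r.sigma_y) / 2 for r in recs]))
    return unit, psf


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    unit, psf = calibrate(args.seed + 99)
    print(f"calibration: unitary {unit:.1f} a.u., PSF sigma {psf:.2f} px")

    rows = []
    for noise, label in ((0.0, "noiseless"), (100.0, "noise=unitary")):
        for mol in (5, 15, 40):
            spots = [(14 + 17 * i, 14 + 17 * j, mol) for i in range(5) for j in range(5)]
            ests = []
            n_rejected = 0
            for rep in range(4):
                img, _, _ = synth.sim_cluster_scene(
                    shape=(96, 96), clusters=spots, unitary=100.0,
                    noise_sd=noise, seed=args.seed + rep,
                )
                for x, y, _ in spots:
                    kwargs = (
                        {"fixed_sigma": psf, "center_slack": 0.0} if noise else {}
                    )
                    try:
                        rec = cl.fit_gaussian2d(img, (x, y), **kwargs)
                    except cl.ClusterFitError:
                        n_rejected += 1  # expected for dim spots at high noise
                        continue
                    ests.append(rec.integral / unit)
            mean = float(np.mean(ests))
            rows.append(
                {"condition": label, "molecules": mol, "recovered_mean": mean,
                 "rel_error": mean / mol - 1, "n_spots": len(ests),
                 "n_rejected": n_rejected}
            )
            print(
                f"{label}: {mol} molecules -> {mean:.1f} "
                f"({(mean/mol-1)*100:+.1f}%, {n_rejected} rejected fits)"
            )
    pd.DataFrame(rows).to_csv(RESULTS / "cluster_recovery.csv", index=False)

    # expression series: dilute phase tracks total linearly (no buffering)
    series = []
    for i, bglevel in enumerate((50, 100, 150, 200, 250)):
        spots = [(20, 20, 20), (50, 50, 30), (75, 25, 12)]
        img, mask, _ = synth.sim_cluster_scene(
            shape=(96, 96), background=bglevel, clusters=spots,
            unitary=100.0, noise_sd=2.0, seed=args.seed + i,
        )
        recs = [cl.fit_gaussian2d(img, (x, y)) for x, y, _ in spots]
        cl.annotate_molecules(recs, unit)
        phase = cl.phase_decomposition(img, mask, recs, min_molecules=10)
        series.append(
            {"background": bglevel, "dense": phase.dense,
             "dilute": phase.dilute, "total": phase.total,
             "n_dense_clusters": phase.n_clusters_dense}
        )
    sdf = pd.DataFrame(series)
    sdf.to_csv(RESULTS / "phase_series.csv", index=False)
    reg = sstats.linregress(sdf["total"], sdf["dilute"])
    print(
        f"dilute vs total: slope {reg.slope:.2f}, R^2 {reg.rvalue**2:.4f} "
        f"(linear rise = no dense-phase buffering in the generator)"
    )
    print(f"wrote {RESULTS / 'phase_series.csv'}")


if __name__ == "__main__":
    main()
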
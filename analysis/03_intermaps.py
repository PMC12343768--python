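"""Mean-field interaction maps: blocky vs well-mixed query against a
basic-blocky partner.

Recomputes the wild-type and well-mixed variant from the design step,
maps each IDR2 stand-in against a basic blocky partner IDR with the
default electrostatic/aromatic pair potential (window 31), and
summarizes how charge dispersion weakens the predicted attraction.

Writes results/intermap_{wt,variant}.tsv and results/intermap_summary.json.
"""

import argparse
import importlib.util
import json
from pathlib import Path

import numpy as np

from idrcond import design, intermaps, synth

HERE = Path(__file__).resolve().parent
RESULTS = HERE.parent / "results"

_spec = importlib.util.spec_from_file_location("design_step", HERE / "02_design_well_mixed.py")
design_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(design_step)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--window", type=int, default=31)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    wt, regions = design_step.build_protein(args.seed)
    spec = design.DesignSpec(wt, regions)
    variant = design.design_well_mixed(spec).variant_sequence
    s2, e2 = regions[1]
    wt_idr2 = wt[s2 - 1 : e2]
    var_idr2 = variant[s2 - 1 : e2]
    partner = synth.blocky_arrangement(
        synth.IDRSimConfig(
            length=150,
            composition=(("pos", 0.22), ("neg", 0.06)),
            x_group="pos",
            y_group="neg",
            seed=args.seed + 1,
        )
    )
    matrix = intermaps.default_matrix()
    m_wt = intermaps.intermap(wt_idr2, partner, args.window, matrix, "idr2_wt", "partner")
    m_var = intermaps.intermap(var_idr2, partner, args.window, matrix, "idr2_mixed", "partner")
    summary = intermaps.summarize_interaction(m_wt, m_var)

    vectors = {
        "residue_wt": list(range(1, len(wt_idr2) + 1)),
        "attractive_wt": np.round(m_wt.attractive_a, 5).tolist(),
        "attractive_variant": np.round(m_var.attractive_a, 5).tolist(),
    }
    (RESULTS / "intermap_attractive_vectors.json").write_text(
        json.dumps(vectors, indent=None)
    )
    (RESULTS / "intermap_summary.json").write_text(json.dumps(summary, indent=2))

    print(f"window {args.window}, matrix {matrix.name}")
    print(
        f"min epsilon: wt {summary['wt']['min_epsilon']:.3f} vs "
        f"well-mixed {summary['variant']['min_epsilon']:.3f} "
        f"(difference {summary['difference']['min_epsilon']:+.3f})"
    )
    print(
        f"mean attractive epsilon: wt {summary['wt']['mean_attractive_epsilon']:.3f} "
        f"vs well-mixed {summary['variant']['mean_attractive_epsilon']:.3f}"
    )
    print(f"wrote {RESULTS / 'intermap_summary.json'}")


if __name__ == "__main__":
    main()
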
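"""Calibration metrics for the default rate table.

Evaluates the behavioral constraints that the shipped rate constants were
fitted against, plus the semi-quantitative information-transmission metrics,
at a configurable population size.  Run from the repository root:

    python scripts/calibrate.py [--n-cells 300] [--seed 0] [--override k=v ...]

Overrides allow quick what-if scans of individual rate constants, which is
how the shipped table was found (coordinate-wise scans against the metrics
printed here, tightening one constraint at a time).
"""

import argparse
import json

import numpy as np

from nfkbinfo import infotheory as it
from nfkbinfo import nfkb_ssa as ns


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-cells", type=int, default=300)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--override", nargs="*", default=[], metavar="NAME=VALUE")
    args = ap.parse_args()
    overrides = {}
    for item in args.override:
        name, value = item.split("=", 1)
        overrides[name] = float(value)
    rates = ns.load_rates(overrides)
    n = args.n_cells
    out = {}

    cell = ns.draw_cell(
        ns.ExtrinsicNoiseSpec(intrinsic_only=True), np.random.default_rng(0), rates=rates
    )
    # mean trajectory at the top dose: peak time and amplitude
    nucs = [
        ns.simulate_cell(cell, 10.0, t_end=60, rng=1000 + s).species("nfkb_nuc")
        for s in range(30)
    ]
    nuc = np.mean(nucs, axis=0)
    times = np.arange(nuc.size) * 0.5
    out["peak_time_10ng_min"] = float(times[nuc.argmax()])
    out["peak_fraction_10ng"] = float(nuc.max() / 1.5e5)

    # 15-min vs 30-min responses below 1 ng/ml
    for d in (0.1, 0.3):
        nn = np.mean(
            [
                ns.simulate_cell(cell, d, t_end=30, rng=2000 + s).species("nfkb_nuc")
                for s in range(30)
            ],
            axis=0,
        )
        out[f"nuc_15min_{d}ng"] = float(nn[30])
        out[f"nuc_30min_{d}ng"] = float(nn[60])

    tr0 = ns.simulate_cell(cell, 0.0, t_end=30, rng=11)
    out["resting_nuclear_fraction"] = float(
        tr0.species("nfkb_nuc").mean() / cell.nfkb_translocatable
    )

    panels = {
        "intrinsic": ns.run_dose_panel(
            n_cells=n, noise=ns.ExtrinsicNoiseSpec(intrinsic_only=True),
            seed=args.seed, rates=rates,
        ),
        "sigma0": ns.run_dose_panel(
            n_cells=n, noise=ns.ExtrinsicNoiseSpec(sigma_tnfr=0.0),
            seed=args.seed + 1, rates=rates,
        ),
        "sigma0.3": ns.run_dose_panel(
            n_cells=n, noise=ns.ExtrinsicNoiseSpec(sigma_tnfr=0.3),
            seed=args.seed + 2, rates=rates,
        ),
    }
    means = [s.values.mean() for s in panels["sigma0"]["nfkb_nuc_norm"].samples]
    top = means[5:]
    out["saturation_spread_1_3_10"] = float((max(top) - min(top)) / np.mean(top))
    pI = panels["intrinsic"]["nfkb_nuc_norm"]
    out["ks_0.1_0.3_intrinsic"] = it.ks_distance(pI.samples[3], pI.samples[4]).ks
    pci = panels["sigma0.3"]["nfkb_nuc_norm_ci"]
    out["ks_0_10_with_ci"] = it.ks_distance(pci.samples[0], pci.samples[7]).ks
    out["mi_nfkb_intrinsic"] = it.maximize_mi(pI, seed=1).mi_bits
    out["mi_nfkb_sigma0"] = it.maximize_mi(panels["sigma0"]["nfkb_nuc_norm"], seed=1).mi_bits
    out["mi_tnfr_sigma0"] = it.maximize_mi(panels["sigma0"]["tnfr_a"], seed=1).mi_bits
    out["mi_ikkk_sigma0"] = it.maximize_mi(panels["sigma0"]["ikkk_a"], seed=1).mi_bits

    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
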
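#!/usr/bin/env python
"""Estimate fibril twist periodicity from synthetic AFM height profiles.

Generates 40 height profiles modulated at the half-crossover period implied
by the helical symmetry (43.2 nm; 1 nm amplitude, 0.2 nm noise), estimates
each profile's dominant period by FFT, aggregates to mean ± sd, and writes
the per-profile table.  The experimental comparison interval is
43.1 ± 4.8 nm from 40 measured fibrils.
"""

import argparse
from pathlib import Path

from fapkit.afm import aggregate_periods, estimate_period, write_period_table
from fapkit.helix import HelicalParams, half_period_nm
from fapkit.synth import synth_height_profile


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n", type=int, default=40)
    ap.add_argument("--out", type=Path, default=Path("results/afm"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    period = half_period_nm(HelicalParams(14.4, -6.0))
    estimates = []
    for i in range(1, args.n + 1):
        profile, _ = synth_height_profile(
            period, amplitude_nm=1.0, noise_sd_nm=0.2,
            length_nm=1000.0, dx_nm=2.0, seed=args.seed * 1000 + i,
        )
        estimates.append(estimate_period(profile))
    stats = aggregate_periods(estimates)
    write_period_table(estimates, stats, args.out / "periods.tsv")

    sd = f"{stats.sd_nm:.2f}" if stats.sd_nm is not None else "n/a"
    print(f"ground-truth period: {period:.1f} nm (half of the 86.4 nm crossover)")
    print(f"estimated over {stats.n_detected} profiles: "
          f"{stats.mean_nm:.2f} ± {sd} nm "
          f"({stats.n_absent} profiles without a significant peak)")
    print(f"inside the measured 43.1 ± 4.8 nm interval: "
          f"{abs(stats.mean_nm - 43.1) <= 4.8}")


if __name__ == "__main__":
    main()
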
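"""Extract the 26-year harmonic and scan lags against the exponent series.

Reads the synthetic climate index and the windowed exponent table, refits
the fixed-period sinusoid, and scans lags 0..max_lag of the cycle against
(i) the windowed b series (window midpoints) and (ii) the generating
exponent signal itself.  The contrast measures the moving-window
derivative confound: under smooth exponential stock growth the windowed
OLS slope is dominated by an amplified derivative of the exponent, so its
scan does NOT peak at the generating lag even though a scan on the
exponent signal itself recovers it exactly.
"""

import argparse
from pathlib import Path

import pandas as pd

from cushingsr import SyntheticConfig, extract_harmonic, lag_scan, read_climate_index
from cushingsr.pipeline import lag_recovery_rate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--index", type=Path, default=Path("results/climate_index.csv"))
    ap.add_argument("--local-b", type=Path, default=Path("results/local_b.csv"))
    ap.add_argument("--max-lag", type=int, default=8)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--reps", type=int, default=100)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    index = read_climate_index(args.index)
    cycle = extract_harmonic(index, period=26)
    print(f"harmonic: period 26, amplitude {cycle.amplitude:.3f}, "
          f"phase {cycle.phase:.2f}, offset {cycle.offset:+.3f}")

    local = pd.read_csv(args.local_b)
    # window midpoints: a trailing 9-year window delays the signal by 4 years
    centered_years = local["year"].to_numpy() - 4
    scan = lag_scan(centered_years, local["b"].to_numpy(), cycle, max_lag=args.max_lag)
    scan.table.to_csv(args.outdir / "lag_scan.csv", index=False, float_format="%.6g")
    print(f"windowed-b scan: best lag {scan.best_lag} (r = {scan.best_r:+.3f}); "
          f"table written to {args.outdir}/lag_scan.csv")

    cfg = SyntheticConfig(seed=args.seed)
    rate, table = lag_recovery_rate(cfg, n_reps=args.reps, seed=args.seed + 7,
                                    max_lag=args.max_lag)
    table.to_csv(args.outdir / "lag_recovery.csv", index=False)
    print(f"windowed-b lag recovery over {args.reps} replicates: {rate:.2f} "
          f"(generating lag {cfg.lag})")
    if rate < 0.5:
        print("finding: the windowed exponent series does not identify the "
              "generating lag — the window's amplified-derivative confound "
              "shifts its phase by about a quarter period (see docs/methods.md)")


if __name__ == "__main__":
    main()
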
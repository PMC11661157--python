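#!/usr/bin/env python
"""Simulate a structure-database stand-in with planted loop-stem compensation.

Draws per-loop free-energy records for a mixture of hairpins, bulges, and
internal loops across several synthetic RNA families (each with its own net
stability offset), and writes them as the tabular record format consumed by
the downstream statistics.
"""

import argparse
from pathlib import Path

import numpy as np

from lsc.lsc_stats import write_records_tsv
from lsc.synthetic_data import SimulationConfig, simulate_net_energy_records


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-structures", type=int, default=4000)
    ap.add_argument("--out", type=Path, default=Path("results/database_records.tsv"))
    args = ap.parse_args()

    config = SimulationConfig(
        n_structures=args.n_structures,
        loops_per_structure=("uniform", 4, 8),
        compensation_slope=1.0,
        compensation_offset=3.0,
        noise_sd=0.7,
        loop_kind_probs={"hairpin": 0.6, "bulge": 0.25, "internal": 0.15},
        family_offsets={"tRNA-like": -0.5, "rRNA-like": 0.0, "pre-miRNA-like": 1.5},
        rng_seed=args.seed,
    )
    records = simulate_net_energy_records(config)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_records_tsv(records, args.out)

    nets = np.array([r.net_dg for r in records])
    kinds = {k: sum(r.loop_kind == k for r in records)
             for k in ("hairpin", "bulge", "internal")}
    print(f"wrote {len(records)} records for {args.n_structures} structures "
          f"-> {args.out}")
    print(f"loop kinds: {kinds}")
    print(f"net dG: median {np.median(nets):+.2f} kcal/mol, "
          f"SD {nets.std():.2f} (planted compensation keeps it near "
          f"-{config.compensation_offset:g})")


if __name__ == "__main__":
    main()
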
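#!/usr/bin/env python
"""Generate the three designed variant libraries and apply the filters.

One library per studied loop type (hairpin, bulge, internal) on the
triply-bulged hairpin scaffold; writes FASTA, the name/dot-bracket CSV, the
region-mask JSON, and an energy-annotated ste file for the first variant of
each library.
"""

import argparse
from pathlib import Path

import numpy as np

from lsc.energy_model import default_params, structure_energy
from lsc.library_design import (
    bulge_template,
    c_repeat_filter,
    generate_library,
    hairpin_template,
    internal_template,
    length_filter,
    write_design_csv,
    write_fasta,
    write_masks_json,
)
from lsc.structure_io import annotate_from_dotbracket, write_ste


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=600)
    ap.add_argument("--outdir", type=Path, default=Path("results/libraries"))
    args = ap.parse_args()

    params = default_params()
    args.outdir.mkdir(parents=True, exist_ok=True)
    for factory in (hairpin_template, bulge_template, internal_template):
        template = factory()
        lib = generate_library(template, args.n, rng_seed=args.seed)
        lib, n_len = length_filter(lib)
        kept, removed = c_repeat_filter(lib)
        nets = np.array([v.net_dg for v in kept])
        print(f"{template.kind:9s} {args.n} generated, {n_len} outside the "
              f"20% length band, {len(removed)} with C repeats > 4; "
              f"{len(kept)} kept; net dG [{nets.min():+.1f}, {nets.max():+.1f}] "
              f"median {np.median(nets):+.1f} kcal/mol")

        stem = args.outdir / template.kind
        write_fasta(kept, stem.with_suffix(".fasta"))
        write_design_csv(kept, stem.with_suffix(".designs.csv"))
        write_masks_json(kept, stem.with_suffix(".masks.json"))

        v = kept[0]
        st = annotate_from_dotbracket(v.sequence, v.designed_dotbracket, v.name)
        res = structure_energy(st, params)
        stem.with_suffix(".example.ste").write_text(
            write_ste(st, res.components))
    print(f"library files under {args.outdir}/")


if __name__ == "__main__":
    main()
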
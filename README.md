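# lsc — local stability compensation in RNA secondary structure

RNA structures are usually judged by their *global* minimum free energy, but
functional RNAs appear to budget stability locally: a destabilizing loop is
offset chiefly by its **adjacent** stem(s), not by helices elsewhere in the
molecule.  This package implements that *local stability compensation* (LSC)
analysis end to end for structural bioinformaticians and RNA designers:

* **Component free energies** — Turner 2004 nearest-neighbor energies
  evaluated *per substructure* (stems, hairpin loops, bulges, internal
  loops, multiloops), so a structure's energy decomposes exactly into local
  contributions (`structure_io`, `energy_model`).
* **Net ΔG statistics** — per loop, `net ΔG = ΔG_loop + ΔG_stem` (the single
  adjacent stem for hairpins, the mean of the two flanking stems for bulges
  and internal loops); binned loop-vs-stem regressions, an in-structure
  rotation control, variance tests, and per-family comparisons
  (`lsc_stats`).
* **Constrained refolding** — repair of "under-folded" database structures
  by refolding with trusted base pairs as hard constraints through a
  pluggable engine (ViennaRNA backend included) (`constrained_refold`).
* **Designed libraries** — randomized variant libraries on a triply-bulged
  hairpin scaffold with A/C-only loops, constant-energy distal stems, and
  pairwise-distance constraints (`library_design`).
* **Folding-fidelity analysis** — DMS reactivity versus designed structure:
  AUROC over A/C residues (designed-unpaired = positives) in global/local/
  distal scopes, per-position stem profiles, and a Hill fit of binned local
  AUROC whose 0.9 crossing gives the minimum net stability for consistent
  folding (`reactivity_analysis`).
* **Synthetic data** — seeded generators for database-like energy records
  with a planted compensation slope, and two-state
  (`p = 1/(1+exp(ΔG_net/RT))`) reactivity profiles, so every stage is
  testable without downloads (`synthetic_data`).

The Hill model for binned local AUROC on the stability scale
`s = offset − ΔG_net` is

```
A(s) = floor + (ceiling − floor) · s^n / (K^n + s^n)
```

with the threshold crossing solved in closed form,
`s* = K·((t − floor)/(ceiling − t))^(1/n)`.

## Worked example

Component energies and net ΔG records for a small bulged stem-loop:

```python
from lsc.structure_io import annotate_from_dotbracket
from lsc.energy_model import default_params, structure_energy
from lsc.lsc_stats import net_energy_records

params = default_params()
st = annotate_from_dotbracket("GGGAGGAAAACCCCC", "(((.((....)))))", "demo")
res = structure_energy(st, params)
for label, c in res.components.items():
    print(f"{label:3s} {c.value:+6.2f}  {dict(c.terms)}")
print(f"total {res.total:+.2f} kcal/mol")
for r in net_energy_records(st, params):
    print(f"{r.loop_label} ({r.loop_kind}): loop {r.loop_dg:+.2f}, "
          f"stems {r.stem_dgs} -> net {r.net_dg:+.2f}")
```

```
S1   -6.60  {'stacking': -6.6}
B1   +0.50  {'initiation': 3.8, 'stacking': -3.3}
S2   -3.30  {'stacking': -3.3}
H1   +4.50  {'initiation': 5.6, 'mismatch': -1.1}
total -4.90 kcal/mol
B1 (bulge): loop +0.50, stems (-6.6, -3.3) -> net -4.45
H1 (hairpin): loop +4.50, stems (-3.3,) -> net +1.20
```

The stem values are pure stacking sums (the helix-end AU/GU penalties that
the Turner rules charge explicitly are attributed to stems; none apply
here), the single-nucleotide bulge keeps its cross-bulge stack, and the sum
of the four components is exactly the structure's nearest-neighbor energy.
The bulge sits at a comfortably negative net ΔG while the hairpin loop on
this toy helix is under-compensated (net +1.20 kcal/mol) — the kind of
substructure the fidelity analysis flags as unlikely to fold consistently.

## Analysis pipeline

The numbered drivers under `analysis/` run the whole study on synthetic
inputs and write their tables under `results/`:

```
python analysis/01_simulate_database.py     # planted-compensation records
python analysis/02_database_stats.py        # binned fits, rotation control
python analysis/03_refold_underfolded.py    # constrained-refolding repair
python analysis/04_design_libraries.py      # three variant libraries
python analysis/05_simulate_reactivity.py   # two-state DMS simulation
python analysis/06_fidelity_analysis.py     # AUROC, regressions, Hill fits
```

On the defaults (seed 1), `02` recovers the planted median-fit slope
(−1.009 for hairpins, R² 0.998) and shows the net-ΔG variance far below the
rotation control (F = 0.25, p ≈ 0); `06` reports a positive local
stem-reactivity slope (+0.028, R² 0.26 for hairpins) with the distal slope
CI straddling zero, and Hill crossings near −0.9 kcal/mol for the simulated
two-state model.

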
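# Methods

## Substructure decomposition

Secondary structures are decomposed by the bpRNA conventions: a *stem* is a
maximal run of stacked base pairs; every remaining position belongs to
exactly one loop — hairpin (no enclosed helix), bulge (unpaired on one
strand between two helices), internal loop (unpaired on both strands),
multiloop (two or more enclosed helices), or an exterior segment.
Coordinates are 1-based inclusive throughout.  Pseudoknotted pairs (bracket
pages beyond `()`) are kept in the pairing map but excluded from the
decomposition, which is defined on the nested page only; records whose span
touches a pseudoknotted position carry a flag.  An internal loop is one
record with two strand parts (net ΔG is defined per loop, not per strand).
Substructures touching `N` are flagged non-computable rather than dropped,
so counts survive into reports.

The `.st` dialect written and parsed here mirrors the bpRNA layout (header
lines, sequence, dot-bracket, per-position type string, one annotation line
per substructure strand); `.ste` files append one free-energy field per
line, kcal/mol to two decimals, with `NA` for non-computable components.
The parser re-derives the decomposition from the dot-bracket and
cross-checks every annotation line against it, so inconsistent files are
rejected rather than trusted.  A fully-paired multiloop (no unpaired
segment) emits a single placeholder line so its energy survives the round
trip.

## Component free energies

Energies follow the Turner 2004 nearest-neighbor rules at 37 °C, evaluated
per substructure so that the sum of components reproduces a whole-structure
evaluation exactly:

* **Stems** — sum of stack terms over consecutive pairs.
* **Hairpins** — length initiation (tables to 30 nt, then
  `lxc·ln(size/30)`), terminal mismatch for loops over 3 nt, and the
  special tri/tetra/hexaloop sequence energies, which replace the generic
  terms.  Loops under 3 nt are a hard error (sterically impossible).
* **Bulges** — initiation; single-nucleotide bulges keep the cross-bulge
  stack (quasi-continuous helix).
* **Internal loops** — dedicated 1×1/2×1/2×2 tables, the 2×3 and 1×n
  mismatch variants, otherwise initiation(n1+n2) + capped asymmetry
  (NINIO) + terminal mismatches on both closing pairs.
* **Multiloops** — the standard linear model (offset + per-branch +
  per-unpaired).  Multiloops are never assigned a net ΔG; they only enter
  whole-structure totals.

Dangling ends and coaxial stacking are excluded everywhere: the analysis
sums stem and loop terms per substructure, and excluding single-strand
stacking keeps the attribution of every energy term unambiguous.  The
reference evaluator used in tests is therefore run with dangles disabled.

**Helix-end penalties.** The Turner rules charge the terminal AU/GU penalty
explicitly in some loop contexts (triloops, bulges ≥ 2 nt, multiloop and
exterior branches) and fold it into mismatch tables elsewhere.  The
explicit terms are charged to the **stem** component by default, keeping
"stem ΔG" the self-contained stabilizing quantity of the analysis; a config
switch (`EnergyConfig.end_penalty_on="loop"`) moves them to the adjacent
loop for sensitivity analysis (exterior branches stay with the stem, since
exterior segments carry no energy).  Mismatch-embedded penalties always
stay loop-side.  Both attributions leave the component sum unchanged.

**Numerics.** Tables are stored in the parameter file's printed units
(dacal/mol) and summed in those units, with C-style truncation of the
`lxc·ln(size/30)` extrapolation term, so totals match integer-dacal
reference implementations to the printed precision rather than merely to a
tolerance.  Temperatures other than 310.15 K rescale every term from the
file's enthalpies as `ΔG(T) = ΔH − (ΔH − ΔG37)·T/310.15`; requesting a
non-default temperature from a file without enthalpies is an error.

**Parameter provenance.** `load_params("turner2004")` parses the
`rna_turner2004.par` file distributed with the installed ViennaRNA package
(the full set, including the 2×2 internal-loop tables, is several hundred
kilobytes, so it is read from the environment rather than duplicated).  The
parser is independent and accepts any file in the same dialect; lookups
return file values verbatim.

## Net ΔG and database statistics

Net ΔG for a loop is its free energy plus the adjacent stem free energy —
the single closing stem for hairpins, the arithmetic mean of the two
flanking stems for bulges and internal loops.  Averaging (rather than
summing) the two stems keeps hairpin and junction scales comparable but
ignores stem asymmetry; this is a known simplification.

* **Binning** — loop-ΔG bins of 0.25 kcal/mol with edges anchored at 0;
  bins with fewer than 20 records are excluded from fits (logged).
  Quantiles use linear interpolation.
* **Fits** — per-bin medians and 5 % quantiles of stem ΔG are regressed on
  bin centers with count-weighted least squares (a bin summary's sampling
  variance scales as 1/n).  Slope confidence intervals come from a
  stratified within-bin bootstrap (percentile, 500 resamples, seeded): the
  parametric t-interval measurably undercovered (≈93 % at nominal 95 % in
  null simulations) because tail bins are small, high-leverage, and
  non-Gaussian, while the bootstrap interval covers at ≈97 %.
* **Rotation control** — within each structure, loops of a kind with more
  than three instances swap stem sets by a cyclic shift of 2 in annotation
  order; the shift of 2 (not 1) avoids handing a bulge/internal loop a stem
  it shares with its neighbor, and any residual shared-stem case is dropped
  and counted.  The control preserves the loop-energy and stem-summary
  multisets per structure, destroying only the pairing between them.
* **Variance comparison** — per-bin net-ΔG frequency differences
  (original − control, both normalized, summing to 0) and a two-sided F
  test on the variances (sidedness configurable; the spec's direction of
  interest — original variance smaller — is available as `alternative="less"`).
* **Group summaries** — median, SD, Gaussian KDE (Scott's rule, bandwidth
  reported) per family or taxon tag, with pairwise two-sided Mann-Whitney U
  tests (chosen because the compared distributions are non-Gaussian;
  groups under 20 records are dropped).

## Constrained refolding

Database structures projected from consensus alignments can leave long
stretches spuriously unpaired.  `flag_underfolded` reports maximal unpaired
runs of at least 20 nt (default; no canonical value exists, so the
threshold is configurable and logged).  `refold` passes trusted pairs as
hard constraints (`(`/`)` at forced partners, everything else left free) to
a folding backend behind a two-method contract — `fold(sequence,
constraint)` and `version()` — and then *verifies* that every forced pair
survived, raising a contract violation otherwise.  Constraint pairs must be
nested; pseudoknotted constraints are unsupported.  A ViennaRNA MFE backend
and a deterministic mock (for adversarial contract tests) ship with the
package.

## Library design

Each library probes one loop type on a triply-bulged hairpin scaffold:
5' flank, constant stems S1/S2 (7 bp) separated by constant 2-nt bulges,
then the variable substructure, then a 3' flank.  The hairpin library
varies the terminal stem (4–12 bp) and its loop (3–11 nt); the bulge and
internal-loop libraries vary the studied loop (1–9 nt per strand) and both
flanking stems, with a constant 4-nt apical loop.  The internal-loop
scaffold therefore has two constant bulges plus the studied internal loop.

Constraints: all loop residues are A/C (DMS-informative); variable stems
sample length, GC fraction (grid 0–1 in steps of 0.25) and G:U count
(0–2); constant stems have fixed GC content (default 0.5; no canonical
value exists), G:C/C:G closing pairs, no G:U pairs, and are accepted only
within ±0.25 kcal/mol of the modal stacking energy of their candidate pool,
so their free energy is near-constant while their sequence varies — which
also supplies the sequence diversity that makes the pairwise distance
constraint satisfiable.  Pairwise distance (positional mismatches over the
shared prefix plus the absolute length difference, a defined convention for
unequal lengths) must be at least 20; rejection sampling caps at 10⁴
attempts per variant and fails loudly with the achieved count.

Filters: sequences outside ±20 % of the set's mean length are removed, as
are sequences containing more than four consecutive C (unreliable DMS
signal); the C-repeat exclusion runs before any fidelity statistic and the
removed names are always reported.

## Reactivity analysis

Only A/C residues carry DMS signal; G/U and uncovered positions are
missing, never imputed.  AUROC treats designed-unpaired residues as
positives with reactivity as the score, computed from average ranks
(Mann-Whitney convention, ties credited ½), which equals brute-force
concordant-pair counting exactly.  Scopes: global (all residues), local
(the randomized region), distal (the constant control region).

Region means are arithmetic means over informative residues per
(region × stem/loop), reported with `log10(mean + 1e-4)` alongside (log of
the mean, not mean of logs; both the base and the pseudo-count are
configurable).  Per-position profiles average each stem pair's informative
residues per molecule, average same-index values of the two stems of a
junction before pooling, and report mean ± 1.96·SEM per net-ΔG bin for
positions 1–6 from the loop; (bin, position) cells with fewer than 70
contributing nucleotides are omitted.  The default position bins are
[−20,−15), [−15,−10), [−10,−5), [−5,0), [0,10] kcal/mol.

Binned local AUROC (0.2 kcal/mol bins) is fit to the Hill equation on the
stability scale `s = offset − ΔG_net`, with the offset at the largest
populated bin edge so all fitted abscissae are non-negative; floor,
ceiling, midpoint K and coefficient n are all free, bounded least squares
(floor/ceiling in [0, 1.5], K > 0, n in [0.05, 50]).  Flat data (range
< 0.02), non-convergence, or an inverted fit yield a degenerate-fit flag
with diagnostics instead of numbers.  The threshold crossing is closed
form and mapped back to the net-ΔG scale.

## Synthetic data: what it does and does not emulate

`simulate_net_energy_records` plants the compensation the statistics are
meant to detect: loop ΔG ~ lognormal(µ=1.25, σ=0.35) (positive, right-
skewed, mode a few kcal/mol, like real loop penalties), stem summary
= −β·loop − c + N(0, noise) + family offset, defaults β=1, c=3 kcal/mol,
noise 0.5 kcal/mol.  Junction stems split the summary symmetrically with a
0.5 kcal/mol spread.  β=0 gives the independent null.

`simulate_reactivity_profiles` draws per-residue reactivities from a
two-state mixture: folded fraction `p = 1/(1+exp(ΔG_net/RT))` with
RT = 0.6163 kcal/mol (310.15 K); designed-paired A/C residues in the local
region are paired with probability p and unpaired otherwise (per-residue
Bernoulli, emulating an ensemble of molecules); the distal region is
always folded; designed-unpaired residues always draw unpaired.  Paired
reactivity ~ Exponential(mean 0.01), unpaired ~ Gamma(shape 2, mean 0.10)
— typical DMS mutation-fraction scales.  The overlap of these
distributions caps fully-folded AUROC at 1 − (1 + mean_u/(shape·mean_p))⁻² ≈ 0.972,
so simulated AUROC saturates slightly below 1 even at −20 kcal/mol; the
expected AUROC and the threshold crossing are available in closed/numeric
form for end-to-end checks.  An optional closing-pair fraying boost exists
(default off).

Not emulated: sequencing-depth noise, per-read correlations, signal decay
along the read, non-canonical pairs, tertiary contacts, and any real
database's family composition.  Passing tests on this generator shows the
pipeline recovers planted structure at realistic scales and noise — not
that real data satisfy the two-state model.

## Problem sizes

Validation runs use 120 random structures (≤ 80 nt) for the energy oracle,
1,000 random profiles (≤ 50 residues) for the AUROC oracle, 5,000 records
for slope recovery, 100 replicates of 1,000 records for null CI coverage,
1,000 structures (plus 20 independence replicates) for the rotation
control, and a 2,000-variant simulated hairpin library for the Hill
recovery; the analysis drivers default to 4,000 structures and 600
variants per library.  These sizes give sampling error well inside the
assertion tolerances while keeping any single run under a minute or two.

## Known limitations

* Stem averaging for junctions ignores stem asymmetry and blurs the
  boundary between neighboring substructures that share a stem.
* The energy model is nested-only: pseudoknots are flagged, not scored;
  ligand binding, non-canonical pairs, and tertiary interactions are
  outside the Turner parameterization entirely.
* The `.ste` dialect is this package's defined layout (the appended-field
  convention is documented above), not a community standard.
* The under-folded threshold (20 nt) and the unequal-length distance
  convention are defined defaults, not canonical values.
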
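# Methods

## Scope and model

`mirneq` predicts the extent of miRNA–mRNA duplex formation at specified
initial concentrations.  The interaction is modeled as a two-step reaction —
open the target site on the folded mRNA, then form the intermolecular duplex
— followed by a two-species mass-action equilibrium.  Three assumptions frame
everything: (i) miRNA–miRNA and mRNA–mRNA interactions do not occur; (ii) the
mature miRNA is presented unstructured (its self-folding energy is zero by
default, reflecting its association with the silencing complex; a precomputed
value can be supplied and is subtracted from ΔΔG as an unfolding cost); and
(iii) one miRNA species meets one mRNA species in isolation — no competition
or multi-site cooperativity.  Binding, not its downstream outcome
(degradation versus translational repression), is what the model predicts;
"mRNA reduction" means the bound fraction [ST]/[T₀].

## Energy rule

All stages share one `EnergyParameterSet` instance — mixing energy rules
between the duplex and folding stages would make their difference
meaningless.  The shipped default is a Turner-style 37 °C set, normative for
this package's own computations (no bit-compatibility claim with any external
folding suite):

- 21 unique stack energies (Watson–Crick and G:U wobble pairs) mirrored to
  all 36 ordered pair-of-pair combinations under nearest-neighbor rotational
  symmetry;
- hairpin (≥ 3 nt), bulge (≥ 1 nt), and internal-loop length penalties
  tabulated to 30 nt, extrapolated beyond as value(30) + c·ln(n/30) with
  c = 1.0785 kcal/mol ≈ 1.75·R·T;
- intermolecular duplex initiation +4.09 kcal/mol; terminal A:U/G:U penalty
  +0.45 kcal/mol (duplex ends only);
- linear multiloop cost a + b·branches + c·unpaired = 3.4 + 0.4·branches + 0
  (folding only);
- R = 0.001987 kcal·mol⁻¹·K⁻¹, T = 310.15 K.

The model deliberately omits dangles, coaxial stacking, sequence-dependent
tetraloop bonuses, and enthalpy/entropy decomposition (so changing the
temperature rescales only RT-dependent quantities, not tabulated energies).
Parameters load from a three-column TSV (`kind`, `key`, `value_kcal_mol`);
`write_parameters` round-trips the dialect.

## Duplex search

`duplex_mfe` minimizes over all antiparallel, non-crossing intermolecular
pairings by dynamic programming, with bulge/internal loops between
consecutive pairs capped at 15 unpaired nt (generous for ~22-nt miRNAs) and a
validity requirement of at least one stacked (adjacent) pair of pairs.  The
scanner slides a window of miRNA length + 15 nt in 1-nt steps, giving the
mRNA side room for loops; retained alignments must reach the −8.5 kcal/mol
cutoff (inclusive) and lie within 5 kcal/mol of the best site on that mRNA
(both configurable).  Overlapping alignments collapse to the lowest-energy
one, ties broken toward the smaller start coordinate; the seed filter then
keeps sites whose miRNA positions 2–7 are Watson–Crick paired (human) or
carry at most one G:U (fly).  Energetically poor canonical pairs are not
special-cased: G:U is scored by the table wherever the optimization selects
it, and only the seed filter constrains it.

## Folding and accessibility

`fold_mfe` is a Zuker-style MFE dynamic program over pseudoknot-free
structures: minimum hairpin loop 3 nt, interior loops capped at 30 unpaired
nt (the standard restriction), lonely pairs allowed, multiloops linear.  The
open chain is the reference state at 0 kcal/mol; a structure is only reported
if its energy is negative.  Constraints force an interval unpaired by
removing its bases from the pairing candidates, so the constrained optimum
can never beat the unconstrained one and ΔG_open ≥ 0 holds by construction.
Co-optimal structures are resolved by a fixed traceback order (hairpin, then
interior loops by increasing 5′ gap, then multiloop splits), making identical
inputs give identical structures; only the energies feed the downstream math.

The folding-region policy: transcripts ≤ 6000 nt fold whole; longer ones fold
only their annotated 3′UTR; 3′UTRs > 6000 nt split into 4000-nt sections
overlapping by 200 nt (the overlap quantifies "slightly overlapping"; both
values are configurable).  A site spanning two sections is assigned to the
section containing it entirely, else to the one containing its 5′ end.  The
engine is pure Python and is routinely exercised on inputs up to a few
hundred nt; an external folding backend can be substituted for very long
transcripts provided the same energy rule is used throughout.

## Equilibrium

K = exp(−ΔΔG/RT) against a 1 mol/L standard state; exponents beyond ±700 are
clamped with a warning (the solver's stable forms remain finite, and the
clamped K underflows [ST] to exactly zero in the weak limit).  The
conservation + mass-action system reduces to a quadratic per species; each
root is evaluated in cancellation-free form — `(-q + sqrt(q² + e))/2`
rewritten as `e / (2(q + sqrt(q² + e)))` whenever `q > 0`, and the [ST]
discriminant expanded as `(s0−t0)² + (2(s0+t0) + 1/K)/K` so no large squares
cancel.  Conservation is then reconciled from the best-resolved quantity:
if [ST] is smallest it anchors [S] and [T] by subtraction; otherwise [S] and
[T] keep their own stable values and [ST] is derived from the smaller of the
two.  This keeps all three concentrations at full relative machine precision
across K ∈ [e⁻⁷⁰⁰, e⁷⁰⁰] and concentrations spanning 10⁻¹² – 10⁻⁴ M, which
the test suite verifies against a 150-digit reference (50 digits are not
enough: the textbook discriminant subtraction spans up to ~80 orders of
magnitude on that grid).

The net free-energy change uses the ideal-dilute-solution Gibbs energy
G = Σᵢ [i]·(g_i⁰ + RT(ln[i] − 1)).  The −1 (molecule-count) term matters:
without it the functional's minimizer sits at [ST]/([S][T]) = K·e rather than
K, because the reaction reduces the total molecule count by one.  With it,
the mass-action root is the exact minimizer of G along the conservation
line, ΔG_net = G(equilibrium) − G(initial) is strictly negative whenever a
duplex forms, and zero otherwise.  ΔG_net is evaluated in a regrouped form in
which every term carries a factor of [ST] (with `log1p` for the dilution
logarithms when the bound fraction is below machine epsilon), so its sign is
exact even when binding is vanishingly weak.  It is reported per liter of
solution and is informational; classification uses concentrations only.

## Concentrations per cell

C = N / ((1 − f_nuc)·V_cell·10⁻¹⁵ L/µm³·N_A) with f_nuc = 0.25 by default.
Under strict SI conversion, 1000 copies in a 1000 µm³ cell is 2.214 nM and
1 µM corresponds to ≈ 4.5×10⁵ copies.  A `paper_convention` flag scales
results by 1000 to reproduce a published set of example prefixes that are
consistently 1000× above the SI values (the significands agree; only the
prefix differs).  Organelle-excluded volume is not modeled; real effective
concentrations may be several-fold higher.

## Synthetic fixtures

The generator emulates exactly what the tests need and nothing more: an mRNA
is a poly-A background (incapable of self-pairing) with an insert at a known
offset.  Insert kinds: `perfect` (reverse complement of the miRNA), `seed_gu`
(one wobble opposite a seed position), `seed_only` (seed complement embedded
in guaranteed-non-pairing filler, too weak for the energy cutoff), and
`scrambled` (Altschul–Erickson-style dinucleotide shuffle of the complement,
deterministically re-shuffled until the scanner reports no site — decoys are
true negatives by construction).  The `hairpin_occluded` context plants the
miRNA sequence downstream of the site behind a tetraloop so the two zip into
a long helix burying the site.  miRNAs are sampled with ≥ 35% GC, no AAAA
runs (which would pair with the background), and at least one G/U in the
seed so a wobble variant always exists; all sampling derives from the spec's
single seed, making generation a pure function of the spec.

Defaults — 22-nt miRNAs, 80-nt mRNAs, site at offset 30, 1 µM : 1 µM, the
30% reduction rule — represent a strong accessible site under typical
benchmark conditions; perfect 22-mer duplexes land near −20 to −40 kcal/mol.
What passing fixture tests shows: the pipeline recovers planted
thermodynamic signal exactly and rejects composition-matched noise.  What it
does not show: performance on real 3′UTRs, whose base composition, partial
sites, and structural context are far richer than a poly-A background — the
fixtures validate the machinery, not biological recall.

## Numerical and design choices

- Coordinates are 0-based half-open internally, 1-based inclusive in every
  report.  U and T are interchangeable on input and normalized to U.
- Report TSVs print energies to two decimals and concentrations to six
  significant digits in scientific notation; batch row order is
  (mirna_id, mrna_id, site_start), making runs byte-reproducible.
- The no-site sentinel row carries remaining_fraction = 1 and
  functional = false: an absent candidate site is interpreted as no
  interaction.
- `best_site` picks the row with the greatest bound fraction; ties break by
  lower ΔΔG, then smaller start coordinate.
- When only one initial concentration is given, the other defaults to the
  same value (total mRNA concentrations are rarely reported).
- Problem sizes in the shipped tests: exhaustive-enumeration cross-checks run
  on ≤ 25-nt folds and ≤ 12-nt duplex pairs (300 and 500 random instances);
  fixture recovery uses 50 planted sites and 50 decoys on 80-nt mRNAs.

## Known limitations

Single site, single species pair: no cooperativity between proximate sites,
no competition among co-expressed miRNAs, no RISC kinetics.  MFE only — no
partition function, so accessibility reflects a single optimal structure
rather than the thermal ensemble.  The simplified loop model (no dangles or
coaxial stacks) shifts absolute energies relative to full Turner rules;
internal consistency between stages, which is what the equilibrium needs, is
preserved by sharing the parameter set.  The pure-Python folding engine is
cubic in sequence length and intended for windows up to a few hundred nt.
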
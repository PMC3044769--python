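# mirneq — quantitative miRNA–mRNA interaction prediction

Most target-prediction tools answer a yes/no question: *can* this miRNA bind
this mRNA?  `mirneq` answers the quantitative one: *how much* of the mRNA is
actually bound at the concentrations the two species reach in a cell.  It is
aimed at researchers studying post-transcriptional regulation who want
concentration-aware predictions — the same site can be saturated in a cell
expressing a miRNA at 10,000 copies and untouched at 100 copies.

## The model

Binding is a two-step hybridization reaction evaluated under one consistent
nearest-neighbor energy rule:

1. **Site discovery.** Candidate sites are the windows on the mRNA where the
   intermolecular duplex reaches a minimum free energy ΔG_hybrid ≤ −8.5
   kcal/mol (dynamic programming over all antiparallel, non-crossing
   pairings), and where the miRNA seed (nt 2–7 from the 5′ end) is
   Watson–Crick paired — strictly in human mode, with one G:U wobble tolerated
   in fly mode.
2. **Accessibility.** The mRNA is folded twice: unconstrained (MFE ΔG_T) and
   with the site forced single-stranded (ΔG°_T).  The opening energy
   ΔG_open = ΔG°_T − ΔG_T ≥ 0 is the cost of exposing the site.  mRNAs ≤ 6000
   nt are folded whole; longer ones only over their 3′UTR, split into
   overlapping ~4000-nt sections when necessary.
3. **Equilibrium.** The net change ΔΔG = ΔG_hybrid + ΔG_open sets
   K = exp(−ΔΔG/RT), and the mass-action system

       [S] + [ST] = [S₀],   [T] + [ST] = [T₀],   [ST]/([S][T]) = K

   is solved in closed, cancellation-free form for the unbound miRNA [S],
   unbound mRNA [T], and duplex [ST].  The reported **mRNA reduction** is the
   bound fraction [ST]/[T₀]; an interaction is called *functional* when it
   reaches the reduction threshold (30% by default, 20% matching the minimum
   used in reporter confirmation experiments).  The net ensemble free-energy
   change ΔG_net ≤ 0 is also reported (zero exactly when no duplex forms).

A copy-number converter (C = N / (V_cyto·N_A), nucleus taking 25% of the cell
volume) links the molar inputs to per-cell expression counts.

The package does not predict what happens after binding (degradation versus
translational repression), does not model multi-site cooperativity or
competition between species, and uses energy minimization throughout (no
partition functions).

## Worked example

```sh
python examples/predict_interaction.py
```

```
miRNA  (22 nt): UGGUGUUAACCUUACUAUACUC
mRNA   (80 nt): AAAAAAAAAAAAAAAAAAAAAAAAAAAAAAGAGUAUAGUAAGGUUAACACCAAAAA...
planted site (0-based): (30, 52)

site 31-52 (1-based inclusive)
  dg_hybrid =   -35.20 kcal/mol   duplex formation energy
  dg_open   =     0.00 kcal/mol   cost of exposing the site
  ddg       =   -35.20 kcal/mol   net two-step change
  bound fraction    = 1.0000  ([ST]/[T0] at equilibrium)
  remaining mRNA    = 0.0000
  net dG            = -2.607e-05 kcal/L (always <= 0)
  functional (>=30% reduction): True
```

A perfect 22-nt complement in an unstructured context binds essentially every
mRNA molecule at 1 µM : 1 µM.  Run `examples/site_accessibility.py` to see the
same site buried in a hairpin (ΔG_open = 32.05 kcal/mol) drop to a bound
fraction of 0.000166, and `examples/equilibrium_curve.py` for the
concentration dependence — total concentration moves the equilibrium more
than the miRNA:mRNA ratio does.

The other examples cover seed-filter modes (`scan_sites.py`) and copy-number
conversion (`copy_number_to_molarity.py`).

## Command line

The `mirneq` entry point wraps the same library functions:

```sh
mirneq predict --mirna mirnas.fa --mrna mrnas.fa --out report.tsv
mirneq scan --mirna mirnas.fa --mrna mrnas.fa --seed-mode fly
mirneq fold --mrna mrnas.fa --site-start 31 --site-end 52
mirneq equilibrium --in energies.tsv --out states.tsv   # batch solver
mirneq conc --copies 1000 --cell-volume 1000            # -> 2.214e-09 M
```

`predict` writes one TSV row per site (energies to two decimals,
concentrations in scientific notation); a pair with no surviving candidate
site yields a sentinel row with the full mRNA remaining.

## Layout

- `src/mirneq/energy_params.py` — the nearest-neighbor parameter set (TSV-backed)
- `src/mirneq/duplex_scan.py` — duplex MFE search and seed filtering
- `src/mirneq/folding.py` — constrained MFE folding and opening energies
- `src/mirneq/interaction_energy.py` — the two-step ΔΔG
- `src/mirneq/equilibrium.py` — mass-action solver and ΔG_net
- `src/mirneq/cellconc.py` — copies-per-cell ↔ molarity
- `src/mirneq/pipeline.py` — orchestration, classification, reports
- `src/mirneq/fixtures.py` — synthetic sequences with planted ground truth
- `docs/methods.md` — modeling assumptions, parameters, and numerical choices
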
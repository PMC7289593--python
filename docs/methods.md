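# Methods

## Model and conventions

All free energies are Gibbs free-energy changes of redox reactions in
dilute aqueous systems, evaluated as ΔG′ = ΔG°′ + RT ln Q with
R = 8.314 × 10⁻³ kJ K⁻¹ mol⁻¹ and T in kelvin (default 298.15 K). The
package treats activities as equal to concentrations (M for aqueous
solutes, atm partial pressure for gases); no ionic-strength or
speciation corrections are applied, and ΔG°′ values are inputs — they
are never derived from formation energies, and no enthalpy-based
temperature correction is available.

Three conventions define the quotient Q:

1. **pH-7 standard state.** ΔG°′ is defined at pH 7, so the proton
   enters Q as (a_H⁺/10⁻⁷)^ν. At pH 7 proton stoichiometry contributes
   nothing; away from pH 7 each net proton produced multiplies Q by
   10^(7−pH). This is the only reading under which the bundled coupled
   reactions reproduce their reference in-situ free energies, and it is
   verified by the test suite.
2. **Unit activities for water and solids.** Enforced by the condition
   set itself, regardless of any supplied value.
3. **No phase coercion.** The engine uses whatever activity value the
   condition set supplies for a species. This matters for CH₄ in the
   environmental condition set, which is specified as a molar
   concentration (3.000 × 10⁻⁵ M) even though the reaction notation
   writes CH₄ as a gas; reproducing the reference free-energy column
   requires using the molar value as given, so the engine does.

ΔG°′ is stored per mole of a declared *reference species*; the
per-reaction value is ΔG°′ × |ν_ref|. Results are reported per
reaction, per reference species, per mole of electron acceptor, and per
mole of electrons (ΔG°′/n), with E°′ = −ΔG°′/(nF), F = 96.5 kJ/V.

## Thresholds, ceilings, windows

For a consumer `a EA + b H₂ → c C + d D`, solving
ΔG′(a_H₂) = ΔG′_target in closed form gives

    ln a_H₂ = [ln Q₋H₂ + (ΔG°′_rxn − ΔG′_target)/RT] / b,

where Q₋H₂ is the quotient with the H₂ term removed. The target is the
minimum biological energy quantum, by default −10 kJ/mol (±1), scaled
from the requested basis (per mol H₂, per reaction, or per mol
acceptor) to the per-reaction value. For methane oxidation written as
an H₂ producer (ΔG°′ = +135.4 kJ/mol CH₄, 4 H₂ per CH₄) the analogous
ceiling is

    a_H₂ = [(a_CH₄/a_HCO₃⁻) · exp((ΔG′_target − ΔG°′)/RT)]^¼.

Both are returned in atm and, via Henry's law (M = atm × 101325 ×
K_H/1000, K_H in mol m⁻³ Pa⁻¹), in aqueous M. A syntrophy window is
feasible when the consumer floor does not exceed the producer ceiling;
a zero-width window counts as feasible.

The closed forms are cross-checked in the tests against an independent
bisection oracle on log₁₀(a_H₂) (200 iterations; bracket [−30, 2] for
realistic cases, widened to [−250, 120] for the randomized suite) to a
relative tolerance of 10⁻⁹ over 1,000 seeded random scenarios.

## Bundled scenarios

The scenario bundle contains:

* seven H₂-linked reactions (methane oxidation to bicarbonate,
  acetogenesis, methanogenesis, sulfate reduction, ferric iron
  reduction with amorphous Fe(OH)₃, nitrate reduction to nitrite, and
  PCE→TCE dechlorination);
* eight methane-coupled reactions (the same acceptors plus 2-CP, MCB,
  TCE and 1,2-DCA dechlorinations);
* six per-H₂ consumer half-reactions used to rebuild the coupled set by
  H₂ cancellation;
* three condition sets: `standard` (all activities 1),
  `table3_env`/`fig2_env` (published environmental concentrations, the
  latter being the 12-species subset used for the ΔG′-vs-[H₂] curves).

ΔG°′ for each reaction is stored on the most precisely printed basis:
per mole of CH₄ for the methane-coupled set, and for the H₂ reactions a
reference species chosen so that the per-H₂, per-acceptor and
per-electron tabulations all reproduce after rounding (e.g.
acetogenesis is stored as −104.2 kJ per mole of acetate, consistent
with the printed −52.1 kJ per mole of HCO₃⁻ and −26.1 kJ per mole of
H₂). The half-reactions for TCE, MCB, 2-CP and DCA are not tabulated
anywhere per mole of H₂; their values are derived by difference,
ΔG°′_half = (ΔG°′_coupled − 135.4)/4, and carry the extra precision
needed for the coupling identity to close exactly.

The 1,2-DCA coupled reaction is balanced with 3 H₂O on the reactant
side (4 + 16 + 6 H = 1 + 16 + 9 H); a variant with 2 H₂O appears in
print but is hydrogen-unbalanced, and since water has unit activity the
free energy is unaffected.

## Documented discrepancies

`reproduce_table` computes every row and flags, rather than adjusts,
rows that do not match their printed counterparts:

* **Ferric iron coupled row.** Computed ΔG′ = −144.18 kJ/mol CH₄ vs
  printed −144.1 — agreement to 0.08 kJ, but the 1-d.p. prints differ
  (−144.2 vs −144.1). The row's ΔG°′ (+46.2) is also inconsistent with
  the per-H₂ iron value (−44.6): H₂ cancellation would give
  135.4 + 4 × (−44.6) = −43.0. Flagged.
* **Nitrate coupled row.** Computed ΔG′ = −522.0 kJ/mol CH₄ vs printed
  −501.4; no quotient convention tried reconciles the two, and the
  row's ΔG°′ (−510.7) likewise disagrees with per-H₂ additivity
  (135.4 + 4 × (−158.1) = −497.0). Flagged.
* **Tabulated threshold-concentration column.** The printed theoretical
  H₂ thresholds (e.g. 162.3 nM for methanogenesis, 15.4 nM for sulfate
  reduction) are not recovered from the stated closed form at standard
  activities with ΔG′ = −10 kJ/mol H₂ and the Henry conversion used
  here (we obtain ≈52 nM and ≈9.9 nM). The same applies to the
  29.7 μM / 3,888 Pa AOM breaking point (we obtain ≈1.4 × 10⁻⁶ atm
  with [CH₄] = 2.14 atm, [HCO₃⁻] = 20.2 mM). These figures originate
  in earlier literature whose exact conventions are not stated; the
  package exposes its closed form, verified against the bisection
  oracle, and does not reverse-engineer the printed numbers.

## Synthetic scenario generator

`syntherm.synthetic` emulates the generic consumer shape
`a EA + b H₂ (+ h H⁺) → c C + d D`: b ∈ {1..4}, integer coefficients up
to `max_stoich` (default 4), species charges in {−2..2} balanced
exactly by the proton term, ΔG°′ drawn uniformly per mole of H₂
(default −180 to −20 kJ, spanning acetogenesis to organohalide
respiration), n = 2b electrons, and a configurable gas fraction for
product phases. Activities are log-uniform over a configurable decade
range (default 10⁻⁹–10⁰ M). All randomness derives from
`numpy.random.default_rng` seeded with (seed, stream) pairs in a fixed
generation order, so a seed reproduces byte-identical scenarios across
platforms.

What the generator does *not* emulate: element balance of C/H/O (only
charge is balanced), thermodynamic self-consistency of ΔG°′ across
generated reactions, correlated activities (real porewaters covary),
temperature or pH variation, and activity-coefficient effects. Passing
property tests therefore demonstrate algebraic correctness of the
energetics over a wide input space, not geochemical realism of any
individual synthetic reaction.

## Numerical choices

* Stoichiometric coefficients and electron counts are exact
  `fractions.Fraction`s; scaling and coupling are exact, and a
  cancellation cutoff (|ν| < 10⁻¹²) applies only after combination with
  non-rational float weights.
* Quotients are accumulated in log space, so ΔG′ evaluation cannot
  overflow even at the extreme H₂ activities probed during bisection.
* A fully cancelled reaction is representable; its free energies are 0
  and it is excluded from energy ladders. Ladder ties break by reaction
  id, lexicographically.
* Printed-value comparisons in the tests round computed values with
  round-to-nearest at the reference precision (kJ to 1 d.p., volts to
  2 d.p.); thresholds are quoted to 3 s.f.
* Default problem sizes: 1,000 random scenarios for the oracle
  equivalence suite, 100 for the invariant suite, 121-point log grids
  for curves; the full test suite runs in a few seconds.

## Known limitations

Beyond the non-goals above (no speciation, no kinetics, no ΔG°′
derivation): the Henry's-law conversion assumes the bare solubility
constants are in mol m⁻³ Pa⁻¹ — supported by the fact that
7.8 × 10⁻⁶ × 101325 ≈ 7.9 × 10⁻⁴ M atm⁻¹ matches the known solubility
of H₂ — and the electron-count validator only knows the H₂ (2 e⁻) and
CH₄→HCO₃⁻ (8 e⁻) donor rules; other donors are accepted as declared.
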
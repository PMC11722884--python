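# Methods

## The model

The water footprint (WF) of a diet is an accounting identity, not a fitted
model. Each food category *i* of a dietary pattern carries a per-kg WF
vector (green, blue, grey) on a production-weight basis, and a weekly
consumed mass. The weekly WF of the pattern is

```
WF_week = Σ_i (m_i / 1000) · wf_i        [L/week, componentwise]
```

where `m_i` is the production-weight mass in g/week and `wf_i` the per-kg
vector in L/kg. Derived views are the per-capita/day WF (`WF_week / 7`),
the green/blue/grey component shares (`component / total`), and the
fraction of the total contributed by any partition of the categories
(animal / plant / other, or guideline food groups). The total WF is always
`green + blue + grey`, derived, never stored — which makes conservation
(additivity under concatenation, exact scaling) a structural property
rather than a numerical accident.

Three conversions connect guideline recommendations (stated in edible
grams per serving) to the production-weight masses the accounting needs:

* **edible → production**: `m_production = m_edible / f_edible`, with
  `f_edible ∈ (0, 1]` the edible fraction of production weight (fruit peel
  and stone, egg shell, fish waste, potato peel…).
* **cooked → dry legumes**: WF databases price dry pulses; a cooked
  serving is divided by 2.5 (default, configurable).
* **seafood**: wild-caught fish carries 0 L/kg, so only the farmed share
  of consumed mass (default 50%) is charged against the aquaculture WF.
  The discount applies to *mass*, never to the per-kg value.

Composite and group foods:

* **jam** is 35% fruit + 40% sugar by mass: `wf_jam = 0.35·wf_fruit +
  0.40·wf_sugar`.
* **food groups** are averaged over member foods three ways: simple
  componentwise mean; consumption-share weighted mean; or
  *serving-weighted* — mean per-serving WF divided by mean serving mass.
  The serving-weighted rule is the one consistent with dairy
  cup-equivalents (a cup equivalent is 244 g of milk but only 43 g of
  cheese): it keeps the result in L/kg and reduces to the simple mean when
  all serving masses are equal. It is isolated behind `GroupWeighting` so
  it can be swapped.

All conversion constants (2.5, 0.5, 0.35, 0.40) live in a single
`Conversions` namespace with those defaults.

## Pattern construction

Patterns come from guideline-style specs: per category a serving size
(g edible), a weekly frequency (or a per-day min/max range), member foods,
a weighting mode, and an optional edible-fraction override. Guidelines
that state serving ranges rather than energy targets (the Spanish ones)
are resolved by building a minimum and a maximum pattern, averaging the
two category-by-category, and then rescaling every entry's servings by a
single factor so the pattern meets the target energy (2000 kcal/day by
default), computed from a kcal/100 g-edible composition table. Uniform
rescaling preserves serving ratios exactly and applies to all entries,
indulgence foods included. Fractional servings are legitimate (occasional
red meat appears at 0.4 servings/week).

Classification into animal / plant / other is by explicit taxonomy with no
silent default: animal covers meat, poultry, eggs, seafood and dairy;
other covers discretionary items (sugar, jam, alcohol, calorie-limit
allowances); plant is everything else, *including* butter and the whole
fats group, which ride with oils on the plant side of the contribution
analysis.

## The packaged fixtures and rounding reconciliation

The Italian, US and Spanish 2000 kcal/day guideline patterns ship as CSV
fixtures carrying the published per-category values (serving size,
servings/week, g/week, per-kg WF, weekly WF). Published tables are rounded
to integers cell by cell, which leaves them internally inconsistent in
three ways the loader has to take a position on:

1. **Component cells vs row totals.** A row's green+blue+grey weekly cells
   can sum to a value 1–20 L away from its printed total (the worst case
   is a per-kg component that is itself a misprint — the butter row's
   green value is a digit transposition, detectable because the corrected
   digits sum exactly to the printed total). The loader rescales the three
   component cells proportionally so they sum to the row-total cell: the
   row total is the less-rounded anchor, and summing row totals reproduces
   the published grand totals within 3 L for all three patterns, while
   summing raw component cells does not (it misses by up to 12 L).
2. **Per-kg columns vs weekly columns.** For group rows averaged with
   different member serving sizes (US and Spanish dairy, US protein
   foods), the published per-kg column is the *simple* member mean while
   the weekly WF is *serving-weighted*; mass × printed-per-kg can miss the
   weekly cell by thousands of litres. Pattern entries therefore carry an
   effective per-kg value (weekly WF / weekly mass), which makes
   mass × WF/kg reproduce every published weekly cell exactly; the printed
   per-kg columns remain available as the fixture's food-database view.
   Rows where the two disagree are flagged in the fixture's notes, as are
   two rows carried as published against their own arithmetic (the Spanish
   egg and sugar rows).
3. **Serving-size rounding.** The Spanish pattern was energy-rescaled
   before printing, so a few serving-size cells round to values slightly
   inconsistent with the mass columns (olive oil, nuts); those serving
   sizes are back-computed from the mass columns and noted. Entry
   validation allows 0.01 g of slack on the edible ≤ production invariant
   for the same reason.

Edible fractions in the fixtures are back-computed per row as
edible-mass / production-mass, so users can override them.

## Synthetic data

The generator emulates the structural properties the pipeline assumes,
not any real food database. Per-kg WF totals are log-normal
(`log-mean 7.3, log-sd 1.0`: median ≈ 1500 L/kg, right tail reaching the
~15,000 L/kg of red meat and olive oil, floor near vegetables' ~300 L/kg).
The green/blue/grey split is Dirichlet with concentrations (7.7, 1.2,
1.1), giving a mean green share of 0.77 — inside the 75–80% band the
national patterns show. Edible fractions are uniform on (0.6, 1.0]; energy
densities uniform on 20–900 kcal/100 g; protein on 0.5–30 g/100 g; serving
sizes 5–250 g and frequencies 0.4–24 servings/week, the ranges the
guideline patterns actually span. Every draw is keyed to a single integer
seed and is bit-reproducible.

What the generator does not emulate: correlations between WF and energy
density, seasonal or regional variation, and the guideline-specific
structure of real patterns (it draws categories independently). Passing
tests on synthetic data therefore demonstrate the *accounting* is correct
(conservation, partition, rescaling, swap deltas), not that any particular
national diet's numbers are right — that is what the fixtures are for.

## Scenarios

Substitution deltas use the savings convention: positive = water saved.
`delta_equal_mass` charges both sides at the same consumed mass (passing
seafood through the aquaculture-mass rule); `delta_equal_protein` removes
the mass of food A that matches the protein of the added mass of food B
(`m_remove = m_add · protein_B / protein_A`); `apply_swap` edits a pattern
and returns a delta that matches full recomputation to 1e-6 (verified over
1000 random swaps). Four substitution savings quoted for these patterns in
the literature (3121, 316, 1965, 570 L/week) are not unambiguously
derivable from the published per-category values; `examples/
swap_reconstructions.py` prints the closest reconstructions and their
residuals instead of asserting them. The olive-oil comparison (+2421
L/week, Spanish EVO vs Italian vegetable oil) is exact and is asserted.

## Numerical choices

* Full precision everywhere internally; integer rounding
  (half-away-from-zero, matching the published tables) only at report
  rendering. Reports are never computed from re-parsed rounded cells.
* Tolerances: published weekly totals ±3 L and per-capita/day ±1 L
  (accumulated printed-cell rounding); per-row weekly WF ±1 L; published
  percentages ±1 point; energy rescaling recovers its target to 1e-6;
  structural identities to 1e-9 absolute or 1e-12 relative.
* Degenerate inputs fail loudly: zero-energy patterns cannot be rescaled,
  component shares of a zero total are an error, unmapped categories and
  partition gaps raise rather than defaulting.

## Limitations

* Food waste is not modelled; all masses are as-recommended consumption.
* Per-food WF values are inputs, taken as given from the upstream global
  WF databases; the package does not re-derive them.
* Single swaps and scripted sequences only — no optimisation over diets.
* Figures are numbers-only (shares and contributions); no plotting.
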
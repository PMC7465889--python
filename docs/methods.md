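# Methods

## Problem and model

`fvnlpoints` estimates the FVNL (fruit, vegetable, nut, legume) points that
nutrient-profile models assign to a packaged product, using only the order
of its ingredient list. The estimator is a deterministic rule system, not a
statistical fit: its justification is positional arithmetic. If an
ingredient is listed *k*-th, it can account for at most 1/*k* of product
weight, so an FVNL component in second place can reach at most 50% and a
third-place component at most 33% — below the >40% threshold the
non-concentrated scales require for 1 point, which is why the
non-concentrated path demands FVNL among the first **two** ingredients,
while the concentrated path (whose scale starts at ≥25%) examines the first
**three**.

Assumptions inherited from labelling law and from the models themselves:

* ingredients are listed in strictly descending order of weight;
* a bracketed group lists the sub-ingredients of the preceding name, again
  in descending order;
* "and/or" alternatives occupy a single slot in the weight ordering;
* the five attainable rungs per scale are L0/L1/L2/L5/L8, named for the
  FSANZ/HSR point values; other models re-map the same rungs
  (Nutri-Score foods 0/1/2/5/5; Ofcom 0/1/2/5/5).

## Point scales

| rung | FSANZ NPSC / HSR | Nutri-Score food | Nutri-Score beverage | Ofcom |
|------|------------------|------------------|----------------------|-------|
| L0   | 0                | 0                | 0                    | 0     |
| L1   | 1                | 1                | 2                    | 1     |
| L2   | 2                | 2                | 4                    | 2     |
| L5   | 5                | 5                | 10                   | 5     |
| L8   | 8                | 5                | 10                   | 5     |

The HSR scale nominally runs 1–8 in 1-point steps, but that granularity is
unattainable without QUIDs, so the coarse five-rung scale is used. The
beverage column's intermediate values follow the published percentage
correspondence (>40% → 2, >60% → 4, >80% → 10): the L1 rung corresponds to
the >40% band and L2 to the >60% band, a documented interpolation since the
source material states only that the maxima differ. Ofcom's scale does not
distinguish concentrated products, so the engine routes Ofcom scoring
through the non-concentrated path exclusively.

## Decision tree

1. **No ingredient list** → 0 points, unless the product name contains a
   configured override keyword (`salad`, `fruit tray`, `vegetable tray`,
   `fruit platter`, `vegetable platter`, `crudite`), in which case the
   override rung (default L8) applies. The keyword list is config; the
   published guidance gives examples but no closed rule.
2. **Multiple components** (kits) → each component is scored under the
   non-concentrated criteria; component points are averaged and snapped to
   the model's attainable set, **ties snapping downward** (the conservative
   direction; the source does not specify tie behaviour).
3. **Option selection** — a product in an FVNL-based category
   (J fruit/juices, K legumes, O nuts/seeds, P potatoes, V vegetables)
   whose FVNL components among the first three ingredients are all or
   mainly concentrated takes Option 1. "Mainly" is implemented as a strict
   majority count of the effective-FVNL ingredients in the first three
   slots; whether the source meant majority by count or by estimated weight
   is ambiguous, so the choice is logged in the trace. Concentrated FVNL in
   any other category (soup with tomato paste, granola bars with dried
   fruit, soft drinks with juice concentrate) stays on Option 2.
4. **Positional rungs** — Option 1: no concentrated FVNL in the first three
   → L0; third → L1. Option 2: no FVNL in the first two → L0; second only
   → L1. Composite ingredients count as FVNL when one of their first two
   sub-ingredients is FVNL (recursively).
5. **Upper rungs (L2/L5/L8)** — every ingredient is assigned a
   weight-contribution class (below); all non-FVNL minimal → L8; any
   substantial → L2; otherwise L5.

## Weight-contribution classes

For each non-FVNL ingredient, evaluated in order:

1. **Precedes the first FVNL ingredient** → substantial. By descending
   weight it outweighs every FVNL component (this is what holds a
   water-led, concentrate-second juice at L2 rather than L5).
2. **Minimal-weight class** (salt, preservatives, colours, vitamins,
   minerals, flavours, antioxidants, acids, gums, cultures…) → minimal.
   Exception: in the snack-like categories **O and S**, salt is a seasoning
   on the food itself rather than a preservative and is demoted to
   non-substantial — this is what separates salted nuts (5) from canned
   beets in salted water (8).
3. **After the first salt/preservative** → minimal: anything listed after a
   trace-level additive is itself at trace level.
4. **Water** → category-conditional: minimal in V and P (canning water is
   drained before consumption), non-substantial in J, K and O (blocks the
   top rung but allows 5 — canned legumes in water score 5, fruit packed in
   water 5, only a pure product 8), substantial elsewhere (soup, combination
   dishes: water is the product's bulk).
5. **Dense class** (added sugars and sweeteners including honey; butter,
   cheese, dairy, eggs, meats and fish; starches, flours and cereal-based
   ingredients) → substantial, with one exception: in the generous
   categories (J, K, O, P, V) a *starch* sitting directly before the
   additive tail — every later ingredient minimal — is treated as a
   dusting/coating agent and demoted to minimal. This resolves the tension
   between "starches imply a 2" and the 8-point exemplar of almonds dusted
   with wheat starch: position semantics ("smaller amounts sit near the end
   of the list") say a trailing starch wedged against the additives is a
   coating, while a starch followed by bulk ingredients (gnocchi flour,
   soup-mix barley) is a true base and keeps its 2-point force.
6. **Anything else** (oils, vinegar, wine, unknown names) →
   non-substantial. Oils are deliberately *not* minimal even though one
   criteria sentence lists "oil" among possibly-minimal ingredients: the
   5-point exemplar "Thompson raisins, sunflower oil" shows oil blocking
   the top rung, and that exemplar wins. Unknown ingredients default to
   non-FVNL/non-substantial — consistent with the observation that products
   whose extra ingredients avoid the dense list typically score ≥ 5 — and
   are flagged `unknown` in the trace.

## Lexicon

Classification is data-driven (`data/default_lexicon.yml`): ~230 entries
covering every ingredient named in the published worked examples plus
common fruits, vegetables, nuts, legumes, additives, sugars and dense
ingredients. Matching is longest-match on stemmed word boundaries
(`tomatoes` ↔ `tomato`), with no fuzzy matching, for reproducibility over
recall. Pure concentration markers (`concentrated`, `paste`, `dried`,
`dehydrated`) are modifiers: they flag concentration anywhere in a name but
never decide what the ingredient *is*. `neutral` patterns (e.g.
`vegetable oil`, `palm oil`, `vinegar`) carry no class but shadow shorter
FVNL patterns, so "vegetable oil" never matches "vegetable". Users can
extend or replace the lexicon; validation rejects unknown class tags,
conflicting duplicates, and entries that are simultaneously minimal and
substantial.

Model eligibility is encoded per entry: `tuber`, `seed_fsanz_only` and
`spice_fsanz_only` count under FSANZ NPSC and HSR only; `eligible_oil`
(rapeseed/canola, walnut, olive oils) under the Nutri-Score only; the four
core FVNL classes count everywhere.

## TRA categories

Products are conditioned on Health Canada's Table of Reference Amounts
major categories, letters A–X. Published category tables show 22 rows
(A–V); the two remaining codes are taken here as the product groups such
audits exclude up front (meal replacements/nutritional supplements and
foods for children under 4) and are accepted as valid input codes.

## Batch statistics

Category summaries report n, mean, sample SD (ddof = 1; 0 for singleton
categories), min, quartiles and max. Quartiles use the inclusive
linear-interpolation convention (pandas' default `quantile`); no convention
is stated in the published tables, so one is fixed and documented here.
Input tables are UTF-8 CSV/TSV with the delimiter sniffed from the header
line (explicit override available); rows failing validation are collected
in a report, never silently dropped.

## Synthetic fixtures

`fixtures.generate_products(n, seed)` samples ~50 templates transcribed
from the published criteria exemplars and per-category product examples,
spanning every rung, both options, composites, and/or groups, the beverage
scale, no-list products, name overrides and two-component kits. Slots are
filled only from the default lexicon, so recovery failures implicate rules
rather than vocabulary, and each template's truth rung was assigned by hand
against the criteria prose when the template was written — independent of
the engine. The bank emulates rule structure, **not** the real food
supply: it contains no OCR noise, no vocabulary outside the lexicon, no
realistic category proportions and no ambiguous marketing names, so 100%
truth recovery demonstrates rule fidelity, not field accuracy on raw
scraped labels. The published national-database distributions are not
reproducible here because that database is proprietary; the package
reproduces the printed worked examples exactly and the structural
properties of the method instead.

## Known limitations

* The dense/minimal vocabulary is finite; unknown ingredients lean
  generous (non-substantial). For high-stakes audits, extend the lexicon
  for the product space at hand and review `unknown` trace flags.
* "Mainly concentrated", beverage-scale interpolation, averaging
  tie-breaks, the coating rule and the salt-seasoning categories are
  documented interpretations of under-specified guidance; all are
  config-adjustable.
* The engine estimates FVNL points only — not NPSC baseline/modifying
  points, HSR stars, Nutri-Score grades, or percentage estimates when
  QUIDs are present.
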
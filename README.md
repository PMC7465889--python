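# fvnlpoints

Position-based estimation of **fruit, vegetable, nut and legume (FVNL)
points** for packaged foods and beverages whose labels carry no quantitative
ingredient declarations (QUIDs).

Several nutrient-profile (NP) models credit the FVNL content of a product:
the FSANZ Nutrient Profiling Scoring Criterion (NPSC), the Health Star
Rating (HSR) system, the Nutri-Score (which additionally credits rapeseed,
walnut and olive oils, and uses separate food and beverage scales) and the
UK Ofcom model. All of them define FVNL points as a function of the
*percentage* of the product that is FVNL — a quantity that simply is not
printed on most Canadian or US labels, where fewer than 3% of products carry
QUIDs. What those labels do guarantee is that ingredients are listed in
descending order of proportion by weight, so the **position** of FVNL
components is an exploitable signal.

`fvnlpoints` implements a reproducible, rule-based estimator built on that
signal, for researchers auditing packaged-food databases and for
policymakers examining how FVNL points distribute across food categories.

## The scoring rules in brief

Only five rungs of each scale are attainable without QUIDs. Writing the
attainable point set as {0, 1, 2, 5, 8} (FSANZ NPSC and HSR):

* **Concentrated path ("Option 1")** — for fruit/vegetable-category
  products (TRA categories J, K, O, P, V) whose FVNL components among the
  first three ingredients are all or mainly concentrated (juice
  concentrates, pastes, dried fruit). A concentrated FVNL must be one of
  the first **three** ingredients: third → 1 point; first or second → 2, 5
  or 8 points depending on how much the non-FVNL ingredients contribute.
* **Non-concentrated path ("Option 2")** — everything else. An FVNL must be
  one of the first **two** ingredients: second → 1 point; first → 2, 5 or 8
  points by the same contribution logic.
* **2 vs 5 vs 8** — a non-FVNL ingredient "contributes substantially"
  (capping the product at 2) when it is an added sugar or sweetener
  (including honey) or a dense ingredient such as butter, cheese, starches
  or cereal-based ingredients, or water outside the category exceptions;
  the product reaches 8 only when every non-FVNL ingredient is a
  minimal-weight additive (salt as a preservative, colour, vitamins,
  minerals, flavour extracts, antioxidants, food additives). Otherwise 5.
* **Composite ingredients** — "peanut butter (peanuts, vegetable oil,
  salt)" counts as FVNL if one of its first two sub-ingredients is FVNL,
  applied recursively.
* **No ingredient list** — 0 points unless the product name makes its FVNL
  nature evident (garden salad, fruit or vegetable tray prepared in-store).
* **Multi-part products** — each component is scored under Option 2 and the
  component points are averaged, snapped to the model's attainable set.

Model differences live in the *lexicon*, not the tree: tubers, seeds,
spices and capers are FVNL under FSANZ NPSC/HSR only; rapeseed, walnut and
olive oils under the Nutri-Score only. The Nutri-Score food scale caps at 5
(beverages: 0/2/4/10); Ofcom uses Option 2 only. See `docs/methods.md` for
the full rule inventory and every documented interpretation.

## Worked example

```python
from fvnlpoints import FvnlScorer, ProductRecord, Model

scorer = FvnlScorer()
rec = ProductRecord(
    id="x1", name="cherry cup", tra_category="J",
    ingredient_texts=["Cherries, water, sugar"],
)
res = scorer.score_product(rec, Model.FSANZ_NPSC)
print(res.points, res.level, res.option_used)   # 2 CriteriaLevel.L2 option2
```

or from the shell:

```text
$ fvnl score-one --ingredients "Cherries, water, sugar" --category J --model fsanz
points: 2 (option=option2, level=L2)
  - model=FSANZ_NPSC category=J beverage=False
  - FVNL ingredients among the first three are not mainly concentrated: Option 2
  - FVNL is the first ingredient: examining remaining ingredients
  - a non-FVNL ingredient contributes substantially: 2-point rung
  - level L2 -> 2 points on the FSANZ_NPSC scale
```

Cherries lead the list, so the product clears the 1-point positional
criterion, but the added sugar marks a substantial non-FVNL contribution,
capping it at 2 points. Every decision the engine takes is recorded in the
trace.

Batch workflow:

```bash
fvnl fixtures --n 500 --seed 42 --out fixtures.csv --truth truth.csv
fvnl score --in fixtures.csv --models fsanz,hsr,nutriscore \
           --out scored.csv --trace traces.jsonl
fvnl summarize --in scored.csv --model fsanz --out summary.csv
```

`summary.csv` reports n, mean, SD, min, quartiles and max points per TRA
category plus a TOTAL row — the shape of a food-supply FVNL audit.

## Layout

* `src/fvnlpoints/parser.py` — ingredient-list grammar (order, brackets,
  and/or groups)
* `src/fvnlpoints/lexicon.py` + `data/default_lexicon.yml` — model-specific
  ingredient classification; the lexicon is user-extensible data
* `src/fvnlpoints/scorer.py` — the decision tree and criteria rungs
* `src/fvnlpoints/batch.py` — CSV/TSV ingest, database scoring, category
  summaries
* `src/fvnlpoints/fixtures.py` — synthetic products with known truth
* `src/fvnlpoints/cli.py` — the `fvnl` command
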
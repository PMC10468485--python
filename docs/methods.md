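# Methods

## The classification rule

A packaged item is flagged as UPF-like when its label shows

* at least one **cosmetic additive** in the ingredient list, or
* at least one **critical nutrient in excess** under the PAHO nutrient
  profile model (NPM), evaluated only where the model applies (NOVA
  groups 3–4).

The two criteria are computed independently and combined as a plain
disjunction; `criteria_fired` records which side(s) triggered.

### Ingredient parsing and additive matching

Ingredient text is folded (lowercase, NFKD diacritic stripping, whitespace
collapse), split on commas/semicolons, and parenthesized or bracketed
sub-lists — compound ingredients — are flattened into additional tokens, so
additives declared inside them are scanned.  Additives that a compound
ingredient *contains but does not declare* are unrecoverable from the label
and out of reach of any label-based method.

Matching is word-boundary-aware substring search of every lexicon pattern
(canonical name, synonyms, INS code) in every token.  Within a token, a
pattern that is a proper substring of another matching pattern is suppressed
("partially hydrogenated fat" beats "hydrogenated"; "corante caramelo"
beats the generic "corante"), while disjoint patterns all match (one token
naming two colors yields two matches).  Each lexicon entry contributes at
most one match per product.  Word-boundary anchoring is a deliberate
tightening of plain substring search: it prevents accidental hits such as a
short additive name inside an unrelated longer word, and the test suite's
brute-force oracle applies the identical rule.

Multifunction additives resolve to `category_overrides[subgroup]` when the
lexicon defines an override for the product's subgroup, else to the entry's
`default_function` — the data-level analogue of assigning the function most
commonly authorized for that food category.  Cosmetic status is then a
per-entry function→bool map, pre-filled from the NOVA cosmetic-class list
(flavors, flavor enhancers, colors, emulsifiers, emulsifying salts,
sweeteners, thickeners, anti-foaming, bulking, carbonating, foaming,
gelling, glazing).  Keeping the taxonomy in data lets jurisdictions differ
without code changes.  The shipped starter lexicon (62 entries, Portuguese
and English names, every cosmetic class plus preservatives, antioxidants and
acidulants) is illustrative, not a reproduction of the Anvisa database.

**Sweetener policy.**  Sweeteners are simultaneously a cosmetic class and an
NPM criterion.  Default policy counts them only on the NPM side
(`sweetener_excluded=True`) so one additive never inflates both criteria;
the flag can be flipped for sensitivity analyses.

### Nutrient-profile model

Energy-relative thresholds with ≥ semantics (a value exactly at a threshold
is flagged), defaults in `NPMConfig` / `npm_paho_default.yaml`:

| criterion       | rule                               | default |
|-----------------|------------------------------------|---------|
| free sugars     | sugar energy / total energy        | ≥ 0.10 (4 kcal/g) |
| total fat       | fat energy / total energy          | ≥ 0.30 (9 kcal/g) |
| saturated fat   | fat energy / total energy          | ≥ 0.10 |
| trans fat       | fat energy / total energy, **or** a trans-source keyword ("hydrogenated …", Portuguese equivalents) in the ingredients | ≥ 0.01 |
| sodium          | mg sodium per kcal                 | ≥ 1.0 |
| sweeteners      | presence                           | any |

Fractions are basis-free, so per-100 g and per-100 mL records are treated
identically.  **Missing is never zero**: an undeclared nutrient yields a
missing flag, and `any_excess` treats missing as false.  Zero-energy
products: a positive declared quantity makes the fraction diverge and is
flagged (for sodium this is the configurable `zero_energy_sodium_rule`,
default conservative).

**Added/free sugars.**  Sugar information is mostly voluntary on the labels
this method targets (~10.8% declared).  The estimation chain is: declared
added sugars → declared total sugars as an upper proxy (policy
`use_declared_total_as_added`, default on; the provenance field records
`declared`) → per-subgroup reference value from a pluggable
`SugarReferenceTable` (`imputed`) → `missing`.  The shipped reference CSV is
an illustrative fixture; published per-subgroup estimates from a
food-composition table can be dropped in without code changes.  Free sugars
default to added sugars; a pluggable policy can add juice-derived terms.

**Applicability gate.**  With reference labels, the NPM applies iff NOVA ∈
{3, 4}.  In screening mode (no labels) the default is to apply it to every
record with a panel (`missing_label_mode="apply_all"`), with an
`additive_only` alternative — the gate is then a modelling choice, made
explicit rather than silent.

## Agreement statistics

For a 2×2 table (reference positive = NOVA 4 vs the flag):
P_o = (a+d)/n, P_e = [(a+b)(a+c) + (c+d)(b+d)]/n², κ = (P_o−P_e)/(1−P_e);
P_e = 1 is handled as κ = 1 for perfect agreement else 0.  Landis–Koch
bands are made contiguous with half-open intervals — (−∞,0) poor, [0,.20]
slight, (.20,.40] fair, (.40,.60] moderate, (.60,.80] substantial, (.80,1]
almost perfect — which resolves the lexical gaps of the verbal scale (e.g.
0.20–0.21) deterministically.

Reconstruction from printed marginals inverts
a = n·prev·sens, b = n·prev·(1−sens), then d = n·P_o − a, c = n·(1−prev) − d
(or, from an overall flag rate, c = n·rate − a, d = n·(1−prev) − c).  Cells
stay **real-valued**: rounding them to integers would add error on top of
the rounding already present in three-significant-figure inputs.  Any
implied negative cell raises an infeasible-marginals error naming the cell.
Reconstruction validates printed statistics; it does not claim to recover
the original table exactly.

## Synthetic catalogs

The generator works **flag-level first**: for each item it draws which
criteria the item will satisfy, then materializes a label realizing exactly
those draws.  This makes ground truth exact by construction — the end-to-end
test requires the pipeline to reproduce the hidden truth table item by item,
with no statistical slack.

* Subgroups are drawn by weight from a single seeded `numpy` Generator
  stream, consumed in fixed per-item order (bit-reproducible per seed).
* For NOVA 3–4 subgroups, (nutrient-excess, cosmetic) pairs are drawn from
  the joint Bernoulli distribution with the configured marginals and 2×2
  odds ratio (Plackett quadratic, root inside the Fréchet bounds, marginals
  reproduced to 1e−9).  For groups 1–2 only the cosmetic flag is drawn.
* A drawn excess is realized through one channel — sodium, total fat,
  saturated fat, a trans-source keyword, a sweetener name, or (only when the
  item declares sugars) a high declared-sugar value — chosen uniformly among
  the channels available to that item.  Quantities are placed with wide
  margins on the intended side of every threshold, so panel rounding cannot
  flip a flag; non-chosen nutrients sit well below their thresholds.
* A drawn cosmetic flag materializes at least one cosmetic, non-sweetener
  additive name from the lexicon (classes sampled per the subgroup's
  conditional inclusion probabilities); non-cosmetic classes (preservatives,
  antioxidants, …) may appear on any item.  Undrawn items never contain
  cosmetic additive names.
* Synthetic runs use **no sugar-imputation reference**: undeclared sugars
  stay missing, keeping truth exact (a shared per-subgroup reference value
  could not realize per-item excess draws consistently).

The shipped `synth_default.yaml` encodes group shares 71.9/13.7/2.4/12.0%,
per-group rates (97.1%/82.1% with odds ratio 3.40 for UPF — implying a
98.8% union; 90.9%/3.7% under independence for processed foods; 0.4% and a
pasta-heavy ~5.1% cosmetic rate for groups 2 and 1) and the 10.8%
sugar-declaration rate.  The processed-foods source row prints a combined
rate (89.1%) *below* its nutrient-excess marginal (90.9%), which no joint
distribution can realize; the generator therefore honours the two marginals
and lets the union fall where probability puts it (≥ 90.9%).

What the generator does **not** emulate: realistic brand/ingredient prose,
correlations between nutrient quantities beyond the two-flag joint,
mislabelled or noisy panels, and additives hidden inside undeclared compound
formulations.  Passing tests therefore certify the pipeline's logic and its
statistical behaviour under the modelled structure, not label-reading
robustness on real-world messiness.

## Problem sizes and numerics

Default suite and driver scales — 400–600 items for identity tests, 1,500
for rate recovery (3-binomial-SE bands), 5,000 for the UPF combined-rate
run, 3,000 for the narrative drivers — keep every stage sub-second to a few
seconds while leaving Monte-Carlo error well inside the tested bands.
Floating-point policy: catalog CSVs serialize at 12 significant digits
(lossless round trips at label precision); results CSVs render 4 decimals;
comparisons in kappa use exact arithmetic on float cells with a 1e−9 guard
only for the degenerate P_e = 1 case.

## Known limitations

* The starter lexicon is a functional sample; coverage of real Brazilian
  labels requires extending it (it is plain JSON).
* Added-sugar imputation is a table lookup; the published regression-based
  estimation it stands in for is out of scope.
* No kappa variance/CI, weighted kappa, or multi-rater statistics.
* NOVA groups are inputs, never outputs: the package screens for UPF-like
  labels, it does not assign NOVA classifications.
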
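# paneval

Multi-criteria evaluation of indicator panels — rectangular tables of
alternatives (e.g. years) × indicators, where each indicator is either a
benefit ("larger is better") or a cost ("smaller is better") measure.

The pipeline chains six stages:

1. **Entropy weights** (`paneval.entropy`) — objective indicator weights from
   the Shannon entropy of each direction-folded, min-max normalized column.
2. **Weighted TOPSIS** (`paneval.topsis`) — cost columns are co-trended
   (reciprocal by default, difference-from-reference selectable), every
   column is scaled to unit Euclidean norm and weighted; alternatives are
   scored by relative closeness `C = D⁻/(D⁺ + D⁻)` to the ideal profile.
3. **Weighted rank-sum ratio** (`paneval.rsr`) — within-column midranks
   (ties averaged) aggregated as `WRSR = (1/n)·Σⱼ Wⱼ·Rᵢⱼ`.
4. **Fuzzy combination** (`paneval.fuzzy`) — convex blends `W₁·C + W₂·WRSR`
   under several weight ratios (default 0.1:0.9, 0.5:0.5, 0.9:0.1), ranked
   per scheme and summarized by the modal rank.
5. **Concordance** (`paneval.concordance`) — Spearman rank correlation
   between method rankings (exact no-tie shortcut, midrank product-moment
   with ties, t-approximation p-values).
6. **Sensitivity** (`paneval.sensitivity`) — one weight at a time is
   perturbed so its renormalized value scales by a unitary variation rate β
   (`W′_k = β·W_k`), and the TOPSIS closeness curves are recomputed over a
   β grid (default 14 values, 0.01–4.5).

A bundled 15×6 example panel (Chinese maternal-health indicators,
2004–2018: mortality per 100,000 plus five coverage rates in percent) is
available as `paneval.fixture_china_mch("raw" | "cotrended")` and as CSV +
YAML files under `src/paneval/data/`. A seeded synthetic-panel generator
(`paneval.synthetic`) produces structurally similar panels — monotone
trends, noise, exact ties, benefit/cost mixtures — for testing.

## Command line

```sh
# full evaluation: weights, TOPSIS, WRSR, fuzzy, concordance tables + summary.json
paneval evaluate --panel panel.csv --schema schema.yaml --out results/

# weight-perturbation sweep (one indicator or all)
paneval sensitivity --panel panel.csv --schema schema.yaml --out results/ --k 0
paneval sensitivity --panel panel.csv --schema schema.yaml --out results/ --k all --betas 0.5,1,2

# generate a synthetic panel in the same input format
paneval synth --spec spec.yaml --seed 7 --out-panel p.csv --out-schema s.yaml
```

The panel file is a plain CSV (header of indicator labels, first column of
alternative labels). The schema file maps each indicator to its direction
and, for cost indicators, an optional co-trend method/reference:

```yaml
X1: {direction: cost, cost_reference: 100000, cotrend_method: reciprocal}
X2: {direction: benefit}
```

Every table is written twice: rounded half-even to `--digits` (default 4)
and at full precision (`*_full.csv`). Runs are deterministic — identical
inputs give byte-identical outputs. Exit codes: 0 success, 2 validation
error, 3 numerical/domain error.

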
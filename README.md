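# tpptriage

Triage of drug, biological and dietary-supplement R&D pipeline candidates
against target product profiles (TPPs).

A TPP states the characteristics a new medical product should have, with a
*minimum* and a *preferred* criterion for each parameter. Given a candidate
registry for a condition — here modelled on the pre-eclampsia prevention and
treatment pipeline — this package:

1. **screens** the registry with six exclusion rules (already marketed for
   the indication; recommended or in routine use; recommended for a subgroup
   only; inactive after negative trial outcomes; targets a single symptom;
   inferior to current treatments), recording a single-counted reason code
   per excluded candidate;
2. **reconciles** two independent reviewers' per-criterion match levels
   (met preferred / met minimum / partially met / not met / unknown), with a
   third reviewer adjudicating disagreements;
3. **scores** each retained clinical candidate-indication pair as a
   weighted sum over nine critical TPP criteria — setting, efficacy,
   companion diagnostic, clinical monitoring, safety, mode of
   administration, treatment adherence, stability (cold chain) and WHO
   Essential Medicines List status — with efficacy and safety up-weighted:

   `total = Σ_c w_c · s(level_c)`,  `r = total / max attainable`

4. **ranks** each pair high / medium / low potential by comparing `r`
   against per-phase cutoffs (defaults: high ≥ 0.60, medium ≥ 0.40); and
5. **reports** traffic-light matrices (dark green / light green / yellow /
   red / grey), screening flowcharts and pipeline-landscape breakdowns by
   activity, phase, product type and archetype.

A seeded synthetic-data module generates registries and reviewer
assessments with planted ground truth (exclusion triggers, match profiles
and ranks), so every stage is testable end-to-end without external data.

Intended users: analysts prioritising R&D portfolios against TPPs, and
anyone reproducing or extending pipeline-landscape analyses of maternal
medicines.

## Worked example

```python
import tpptriage as t
from tpptriage.data import preclinical_registry, clinical_phase_lists

tax = t.categorize_preclinical(preclinical_registry())
print(tax.denominator, dict(tax.indication_membership))
print({k: v for k, v in tax.subclass_counts.items() if v >= 5})
print(t.unique_candidate_count(clinical_phase_lists().values()))
```

prints

```
40 {'prevention_only': 11, 'treatment_only': 24, 'both': 5}
{'amino acid-peptide': 7, 'polyphenol': 7, 'DNA/siRNA/mRNA': 5}
32
```

— of the 40 unique preclinical candidates, 11 target prevention only, 24
treatment only and 5 both; the most common subclasses are amino
acid/peptides (7), polyphenols (7) and DNA/siRNA/mRNA medicines (5); and
the six clinical phase lists collapse to 32 unique candidates once the four
dual-indication entries are deduplicated.

The full pipeline on synthetic data, from the shell:

```sh
tpptriage simulate --out sim --seed 7 --n 200 --disagreement 0.1
tpptriage rank --registry sim/registry.csv --assessments sim/assessments.csv --out out
# -> ranked 77 candidate-indication pairs: {'high': 12, 'low': 41, 'medium': 24}
tpptriage report --registry sim/registry.csv --assessments sim/assessments.csv --out rep
```

`out/ranked.csv` holds one row per retained clinical candidate-indication
pair with its nine reconciled levels, weighted score, completeness fraction
(share of criteria with informative levels) and rank; `rep/matrix.html` is
the traffic-light matrix with legend.

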
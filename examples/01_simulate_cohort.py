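"""Generate a synthetic EMR cohort and inspect its comorbidity burden.

Builds a 1510-patient cohort of older lung-cancer patients with the
reference disease marginals, runs it through eligibility filtering, and
prints the comorbidity-count distribution — the share of patients with
zero, one, or several chronic conditions alongside their cancer.
"""

from comopat import (
    CohortConfig,
    build_transactions,
    comorbidity_distribution,
    filter_cohort,
    generate_cohort,
)
from comopat.synthetic import catalog_for

config = CohortConfig(rng_seed=42, missing_field_rate=0.02, duplicate_key_rate=0.01)
records = generate_cohort(config)
catalog = catalog_for(config)
kept, report = filter_cohort(records, catalog)

print(f"records emitted: {len(records)}, kept after eligibility: {report.n_kept}")
print(f"excluded: {report.missing_field} missing a mandatory field, "
      f"{report.duplicate_key} duplicate primary keys")

tdb = build_transactions(kept, catalog)
dist = comorbidity_distribution(tdb)
print("\ncomorbidity count distribution:")
for row in dist.histogram.itertuples(index=False):
    print(f"  {row.n_comorbidities:>2} comorbidities: {row.count:>4} patients "
          f"({100 * row.proportion:.1f}%)")
share = 1 - dist.histogram.loc[0, "proportion"]
print(f"\n{100 * share:.1f}% of patients carry at least one comorbidity — the "
      "burden the downstream pattern mining characterises.")
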
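"""Do independent estimate producers agree more over time?

Loads the bundled panel of published male adult-mortality (45q15) estimates
for the 27 Brazilian states from three producers (DDM-R, IHME, IBGE) in the
1980/1991 and 2000/2010 intercensal periods, computes the per-state RMSE
dispersion across producers, aggregates it nationally, and classifies each
state as converging, diverging or stable.
"""
from ddmkit import (
    convergence_change,
    convergence_table,
    load_brazil_male_45q15_panel,
    national_summary,
)

panel = load_brazil_male_45q15_panel(drop_extra_sources=True)
table = convergence_table(panel, metric="q45_15")
nat = national_summary(table, "mean_of_states")
print("national RMSE of male 45q15 across producers:")
for _, row in nat.iterrows():
    print(f"  {row['period']}: {row['rmse']:.4f}")

change = convergence_change(table)
counts = change["verdict"].value_counts()
print("\nstate verdicts:", dict(counts))
print("\nfive largest movers:")
print(
    change.reindex(change["delta_rmse"].abs().sort_values(ascending=False).index)
    .head(5)
    .to_string(index=False)
)
# A falling RMSE means the producers' estimates are closing in on each other;
# states where it rises are where the choice of agency still matters most.
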
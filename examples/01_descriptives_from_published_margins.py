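"""Pooled descriptive summaries from the published per-year counts.

Builds the pooled column of the study's frequency table from the per-year
counts of the 2008/2013/2018 Nigeria DHS child sample, then estimates the
tetrachoric correlation between diarrhoea and ARI from the pooled 2x2
table.  The tetrachoric rho is the correlation of a latent bivariate
normal underlying the two binary indicators — a child-level (not
ecological) co-morbidity measure.
"""

from comorbmap import ndhs_ari_diarrhoea_table, ndhs_pooled_counts, tetrachoric
from comorbmap.descriptives import percentage

pooled = ndhs_pooled_counts()
print(pooled[["2008", "2013", "2018", "pooled"]])
print()
print(f"pooled children:        {pooled.loc['total_children', 'pooled']:,}")
print(f"ARI cases:              {pooled.loc['ari', 'pooled']:,}")
print(f"diarrhoea cases:        {pooled.loc['diarrhoea', 'pooled']:,}")
print(f"stunted:                {pooled.loc['stunting', 'pooled']:,}")
print(f"ARI and diarrhoea:      {pooled.loc['ari_and_diarrhoea', 'pooled']:,}")
print(f"all three illnesses:    {pooled.loc['all_illnesses', 'pooled']:,}")
print(f"rural share:            {percentage(pooled, 'residence_rural'):.0f}%")
print(f"no-education share:     {percentage(pooled, 'education_none'):.0f}%")

table = ndhs_ari_diarrhoea_table()
res = tetrachoric(table)
print()
print(f"ARI x diarrhoea 2x2 cells (n11, n10, n01, n00): {table.cells}")
print(f"tetrachoric rho = {res.rho:.4f} (se {res.se:.4f})")
print("rho > 0: children with diarrhoea are markedly more likely to also "
      "have ARI than independence would imply.")
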
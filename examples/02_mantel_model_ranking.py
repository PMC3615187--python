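"""Which environmental gradient best explains lipid dissimilarity?

Builds the Euclidean dissimilarity matrix of core-lipid compositions
across the 25 packaged springs, one environmental distance matrix per
measured variable, and ranks the single-predictor models by small-sample
AICc with Mantel permutation tests.
"""

from tetralink import (
    env_distance,
    mantel,
    parse_geochem,
    parse_lipid_table,
    profile_distance,
    rank_models,
    substitute_bd,
)
from tetralink.geochem import VARIABLES
from tetralink.pipeline import fixture_path

core = parse_lipid_table(fixture_path("core_lipids.tsv"), "core")
records = substitute_bd(
    parse_geochem(fixture_path("spring_geochemistry.tsv")), "auto"
)
lipid_ids = {p.spring_id for p in core}
records = [r for r in records if r.spring_id in lipid_ids]

response = profile_distance(core)
predictors = {v: env_distance(records, [v]) for v in VARIABLES}

ranking = rank_models(response, predictors, n_perm=999, seed=0)
print(ranking.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

ph_rank = mantel(response, predictors["ph"], n_perm=999, seed=0, method="spearman")
print(
    f"\nBest model: {ranking.best} (dAICc = 0 by construction).\n"
    f"Rank-Mantel r2 for pH = {ph_rank.r2:.2f} (p = {ph_rank.p:.3f}): "
    "pH distance alone\nexplains about a third of the rank variation in "
    "lipid dissimilarity; every\nother gradient has essentially no support."
)
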
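"""Screen a synthetic compound compendium against the planted module pair.

Generates a 10-compound compendium in which one compound (cpd_000) is a
planted vasodilator — in its treatment samples the positive-module genes
are shifted up and the negative-module genes down — then scores every
compound with the weighted KS enrichment statistic and ranks by
TES = ES_PFGM − ES_NFGM with a 1000-draw module-resampling null.
"""

from tfgmr import (
    SyntheticCompendiumSpec,
    build_ranked_list,
    differential_scores,
    generate_profiles,
    rank_compounds,
    true_modules,
)

spec = SyntheticCompendiumSpec(seed=17)  # 200 genes, 10 compounds, modules 20/20
pair = true_modules(spec)
profiles = {
    cid: build_ranked_list(differential_scores(matrix))
    for cid, matrix in generate_profiles(spec).items()
}
scores = rank_compounds(profiles, pair, B=1000, seed=17)

print(f"{'compound':<10} {'ES_PFGM':>8} {'ES_NFGM':>8} {'TES':>7} {'p':>9}")
for s in scores:
    print(f"{s.compound_id:<10} {s.es_pfgm:8.3f} {s.es_nfgm:8.3f} "
          f"{s.tes:7.3f} {s.p_value:9.4g}")

top = scores[0]
print(f"\nTop-ranked: {top.compound_id} (planted direction: "
      f"{spec.direction_of(top.compound_id)}).")
print("A large positive TES means the compound induces the positive module and")
print("represses the negative one — the expression signature of a vasodilator;")
print("p is the fraction of size-matched random gene-set pairs scoring at least")
print("as high on the same ranked list (add-one permutation estimate).")
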
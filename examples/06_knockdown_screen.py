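"""Screen in-silico knockdowns for state-destabilizing regulators.

Unperturbed ensemble models labelled by the distance/null assignment train a
ridge state mapper; every single-TF knockdown (and pairs among the strongest
destabilizers) is re-simulated and classified, with a chi-squared test against
the unperturbed state counts and a pathway annotation of the network TFs.
"""

import coregrn as cg
from coregrn.netopt import score_candidate
from coregrn.pathway_annot import annotate_network_tfs
from coregrn.perturb_analysis import kd_screen, rank_destabilizers, train_state_mapper
from coregrn.target_db import build_merged_db
from coregrn.tf_activity import significant_genes

system = cg.make_planted_system(seed=17)
expr = cg.emit_expression(system)
db = build_merged_db(system.binding, system.curated_db, 0.1, restrict_to_genes=expr.genes)
act = cg.infer_activity(expr, db, system.tfs)

scored = score_candidate(system.network, act, n_models=800, n_null=200, seed=17)
print(f"unperturbed proportions: {scored.proportions}")

mapper = train_state_mapper(scored.ensemble, scored.assignment)
results = kd_screen(system.network, scored.ensemble, mapper, n_top=3)
table = rank_destabilizers(results)
print("\ntop case-state destabilizers (knockdown enlarges the control state):")
print(table.head(3).to_string(index=False))
print("\ntop control-state destabilizers:")
print(table.tail(3).to_string(index=False))
pairs = [r for r in results if len(r.genes) == 2]
sig = [r for r in pairs if r.p_value < 0.05]
print(f"\ndouble knockdowns: {len(pairs)}, significant by chi-squared: {len(sig)}")

degs = significant_genes(cg.differential_genes(expr))
pathways = {  # toy pathway sets: module A/B regulons
    "module_A_program": {g for tf in system.module_a for g in system.tf_targets[tf]} | set(system.module_a),
    "module_B_program": {g for tf in system.module_b for g in system.tf_targets[tf]} | set(system.module_b),
}
ann = annotate_network_tfs(system.tfs, db, degs, pathways)
tf = system.module_b[0]
print(f"pathway annotation for {tf}: {ann.annotations[tf][0]} (p = {ann.annotations[tf][1]:.2e})")
# the case-module TF maps to the case-module expression program
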
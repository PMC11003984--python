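"""Build the planted synthetic world every other example runs on.

The generator plants a bistable 20-TF core (two mutually inhibiting,
internally activating modules), emits a two-state expression matrix
(11 control + 9 case samples), a noisy TF-gene binding table, a curated
target database with dropout and spurious entries, and three ranked TF lists.
"""

import coregrn as cg

system = cg.make_planted_system(seed=17)
expr = cg.emit_expression(system)
binding = cg.emit_binding_table(system)
lists = cg.emit_ranked_tf_lists(system)

print(f"planted core: {system.network.n_nodes} TFs, {system.network.n_edges} edges")
print(f"module A (control-state drivers): {', '.join(system.module_a[:4])} ...")
print(f"module B (case-state drivers):    {', '.join(system.module_b[:4])} ...")
print(f"expression matrix: {len(expr.genes)} genes x {len(expr.samples)} samples")
print(f"binding table: {len(binding.table)} (TF, gene) pairs")
print(f"curated database: {len(system.curated_db)} TFs")
print(f"ranked lists: {len(lists)} methods x {len(lists[0])} TFs each")
# Expected: 60 planted edges; the expression matrix separates the two sample
# groups by 2 noise-SDs on every signal gene, so downstream stages can recover
# the core.
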
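"""Running-sum set enrichment of complex I modules.

Ranks all proteins by log2 fold change and asks whether each curated
complex I module (N, Q, P) is concentrated at one end of the ranking.
The enrichment score is the signed maximum of a weighted running sum;
significance comes from random same-size sets, with BH correction
across modules.
"""

from etpath import differential, enrichment, make_omics_table
from etpath.simulate import proteome_design

design, module_sets = proteome_design(seed=42)
table, _ = make_omics_table(design)
delta = differential(table.to_log2(), "patient", "control")

results = enrichment(delta["log2fc"], module_sets, n_perm=1000, seed=42)
print(f"{'module':<8}{'size':>5}{'ES':>9}{'p':>10}{'q':>10}")
for r in results:
    print(f"{r.set_id:<8}{r.size:>5}{r.es:>9.3f}{r.p:>10.4g}{r.q:>10.4g}")
print()
print("A negative enrichment score means the module's members pile up at")
print("the depleted end of the ranking. Only the N-module does so")
print("significantly - the planted, selective instability of the")
print("NADH-oxidizing module - while Q and P behave like random sets.")
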
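"""Differential abundance testing with FDR control on a synthetic proteome.

Generates a label-free-quantification-like table (400 proteins, patient
and control triplicates) in which the complex I N-module subunits are
planted 3- to 10-fold down, then runs the standard pipeline: validity
filter, log2 transform, per-protein t-tests, Benjamini-Hochberg
correction, and a per-module summary.
"""

from etpath import differential, filter_valid, make_omics_table, module_map
from etpath.simulate import proteome_design

design, module_sets = proteome_design(seed=42)
table, truth = make_omics_table(design)

table = filter_valid(table).to_log2()
delta = differential(table, "patient", "control")

n_t = int(delta.significant_t.sum())
n_bh = int(delta.significant_bh.sum())
print(f"{len(delta)} proteins tested: {n_t} significant by t-test, {n_bh} after BH")
print()
print("most depleted proteins (log2 patient/control):")
print(delta.nsmallest(5, "log2fc")[["log2fc", "p", "q"]].round(4))
print()
print("per-module summary:")
print(module_map(delta, module_sets)[["n_detected", "mean_log2fc", "median_log2fc"]].round(3))
print()
print("Only the N-module mean drops (the planted defect); Q- and P-module")
print("abundances stay flat, mirroring a selective loss of the NADH-oxidizing")
print("module while the rest of complex I remains.")
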
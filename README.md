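# etpath

Structure-based electron-tunneling pathway analysis between redox
cofactors, in-silico point mutagenesis by side-chain truncation, and the
matching differential omics statistics — built for studying how missense
mutations in respiratory-chain complex I (CI) subunits disrupt the
enzyme, and usable for any donor/acceptor pair and any grouped
abundance table.

## Who this is for

Mitochondrial disease and electron-transfer researchers who want a
transparent, testable answer to two questions:

1. **Structural arm** — given a structure with two iron–sulfur clusters
   (or FMN), which residues carry the electronic coupling between them,
   and how much does a substitution to a smaller residue (e.g. the
   pathogenic Val→Ala in NDUFS1, between clusters N4 and N5) slow the
   electron-transfer rate?
2. **Omics arm** — in patient-versus-control metabolome/proteome tables,
   which features change, is the GSH/GSSG redox ratio shifted, and are
   the CI modules (N/Q/P) affected as coherent sets?

## The model

**Tunneling pathways.** The electronic coupling between donor D and
acceptor A is modeled as a product of per-step decay factors over a
chain of steps (the empirical pathway model):

    T_DA = ∏ ε_i ,   ε_cov = 0.6
                     ε_hb(r) = 0.36 · exp[−1.7 (r − 2.8)]   (capped at 0.36)
                     ε_sp(r) = 0.6 · exp[−1.7 (r − 1.4)]    (capped at 0.6)

with r in Å and 1.7 Å⁻¹ the through-space decay constant. The dominant
pathway maximizes ∏ε, found exactly as a shortest path under additive
weights −ln ε on an atom graph in which each cofactor is contracted to a
super-node. The nonadiabatic electron-transfer rate scales as
k ∝ |T_DA|², so for a mutation that leaves driving force and
reorganization energy untouched,

    k_WT / k_mut = (T_WT / T_mut)² .

Mutations are modeled as pure side-chain truncations (Val→Ala, Val→Gly,
Asp→Gly, …): the residue is renamed and the atoms absent from the
target's canonical set are deleted, with no rebuilding — so a mutation
can only remove coupling routes, and the predicted ratio is always ≥ 1.

**Omics statistics.** Features ×samples intensity tables are filtered to
features fully observed in at least one group, log2-transformed, missing
values imputed from a down-shifted normal (mean − 1.8 SD, width 0.3 SD per
sample), tested per feature with two-sample t-tests, and corrected with
Benjamini–Hochberg (significance p ≤ 0.05, q ≤ 0.05). Per-sample
log2(GSH/GSSG) ratios are compared by one-way ANOVA with Tukey HSD.
Feature sets (curated CI N/Q/P module lists ship with the package) are
scored with a weighted Kolmogorov–Smirnov running sum against a
random-set permutation null.

A synthetic-data module generates both kinds of input with known ground
truth: toy PDB structures in which two 4Fe–4S clusters are bridged by a
single residue's side chain (with an analytically computable pathway
coupling), and log-normal abundance tables with planted fold changes,
replicate noise, and abundance-dependent dropout.

## Worked example

```python
import tempfile
from etpath import (BridgeDesign, MutationSpec, analyze_pair,
                    make_bridge_structure, read_structure)

pdb_text, truth = make_bridge_structure(BridgeDesign(jitter=0.0))
with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
    fh.write(pdb_text)
s = read_structure(fh.name)

report = analyze_pair(
    s, truth.cofactors, "N4", "N5",
    mutations=[MutationSpec.parse("A:10:VAL>ALA"),
               MutationSpec.parse("A:10:VAL>GLY")],
)
print(f"T_wt = {report.wt_path.coupling:.6g}")
for p in report.predictions:
    print(f"{p.mutation}: T_mut = {p.T_mut:.6g}  ratio = {p.rate_ratio:.1f}")
```

prints

```
T_wt = 0.000562644
A:10:VAL>ALA: T_mut = 6.72186e-05  ratio = 70.1
A:10:VAL>GLY: T_mut = 4.44566e-05  ratio = 160.2
```

The wild-type electron crosses a ~3 Å space gap into the valine's CG1,
runs along two covalent bonds (CG1–CB–CG2), and jumps into the second
cluster. Truncating the valine to alanine deletes both methyl branches
and forces a single longer jump through the CB atom: the coupling drops
8-fold and the predicted rate 70-fold. Truncation to glycine is worse
still. Each number is reproduced against the generator's analytic
product of decay factors to 1e-9 relative in the test suite.

The omics arm, on a synthetic proteome with the N-module planted 3–10×
down (`examples/differential_abundance.py`), prints a per-module
summary — N-module mean log2FC −2.5, Q and P ≈ 0 — and the enrichment
example flags only the N-module (ES −1.0, q ≈ 0.005).

More narrative scripts live in `examples/` (one per capability), and a
thin CLI wraps the same functions:

```sh
etpath simulate-structure --out bridge
etpath path --structure bridge.pdb --cofactor N4=A:501 --cofactor N5=A:502 \
            --mutate "A:10:VAL>ALA" --out run
etpath delta --table prot.csv --groups "patient:p1,p2,p3 control:c1,c2,c3"
```

For real structures, supply the cofactor label map yourself (e.g.
`N4=B:603`): inspect the HETATM records (`SF4`/`FES`/`F3S`/`FMN`
residues) of your file and match clusters to labels using the
structure's literature; the mapping is a curated input, not something
the package infers.

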
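# modelsup

Compare, superpose and visualise **overlapping predicted structural models of
one protein sequence**, and reconcile two domain classifications
(SCOP/CATH-style) into tiered consensus superfamily pairs.

Structure-prediction resources routinely publish several models for the same
protein, each covering a (possibly different) region of the sequence.  Seeing
where those models agree — and, more importantly, where they disagree — takes
more than loading them side by side: divergent segments (unfolded tails,
differently-placed helices) wreck a naive least-squares superposition, and
per-model rainbow colouring hides which residues are actually equivalent.
`modelsup` is a toolkit for researchers and resource curators who need to
inspect such model ensembles, and for anyone comparing two domain
classifications of the same structure set.

## What it does

Given two or more single-chain PDB models whose residue numbers index the
source sequence:

1. **Align by residue number.** Residues are equivalent iff they carry the
   same sequence position — no sequence or structure alignment, because the
   models describe the same sequence by construction.
2. **Score per-position consistency.** For every model pair, the shared
   positions are brought into a robust rigid fit (window-consensus
   initialisation + iteratively reweighted least squares) and each position i
   gets the SSAP-style kernel score
   `S(i) = 1 / (1 + (δ_i/σ)²)` on its residual deviation δ_i (σ = 2 Å by
   default).  The per-column score is the minimum over model pairs: a
   position is conserved only if *every* pair agrees there.
3. **Trim divergent regions.** Positions scoring below a threshold (0.5) are
   excluded iteratively — with a floor of max(3, 30%) of columns — so tails
   and rearranged segments do not disrupt the superposition of the regions
   the models agree on.
4. **Superpose jointly.** Reference-free iterative fitting of all models to
   their evolving mean structure on the included columns (Kabsch/SVD rigid
   fits); the frame is anchored to the first model for reproducible output.
5. **Colour with a shared, conservation-weighted rainbow.** Every sequence
   position gets one colour, used in *all* models (blue at the N-terminus
   through to red at the C-terminus); the gradient advances with cumulative
   consistency weight, so divergent stretches consume little of the spectrum
   and conserved regions get most of the colour range.
6. **Draw alignment lines.** Each alignment column with ≥ 2 members becomes a
   minimal spanning tree over the equivalent residues' superposed CA
   coordinates — the fewest, shortest black lines that connect all
   equivalents, emitted into a PyMOL object named `alignment` that can be
   toggled from the object panel.
7. **Render or export.** A multi-MODEL PDB, a byte-stable `.pml` script, a
   TSV report, and an optional orthographic PNG snapshot.

For two domain-classification tables, `modelsup` computes all residue-level
domain overlaps, aggregates them per superfamily pair, finds **consensus
pairs** (mutually each other's most similar partner) and grades them:

* **Bronze** — mutual best partners (similarity = shared residues).
* **Silver** — bronze, plus ≥ 80% of each side's classifiable domains map to
  the other, and mapped domains overlap over an average of ≥ 80% of their
  residues (both sides).
* **Gold** — silver, plus a *minimum* of ≥ 80% residue overlap (both sides).

All 80% thresholds are inclusive and configurable.

## Worked example

Generate a synthetic ensemble — three models of a 40-residue protein that
agree on a 30-residue helical core (0.2 Å coordinate noise) but place the
last 10 residues 8 Å apart in different directions — and superpose it:

```bash
modelsup fixtures  --out-dir demo --seed 7
modelsup superpose demo/model1.pdb demo/model2.pdb demo/model3.pdb \
        --out-dir demo/out --png
head -8 demo/out/report.tsv
```

```
# rmsd_included	0.2546
# rmsd_all_shared	3.9388
# refine_iterations	2
# trim_iterations	2
# pairwise_rmsd	model1	model2	0.3916
# pairwise_rmsd	model1	model3	0.4530
# pairwise_rmsd	model2	model3	0.4741
seq_pos	icode	n_members	score	included	t
```

The ensemble RMSD over the columns kept for fitting is 0.25 Å — the three
models agree closely on the core — while the RMSD over *all* shared columns
is 3.94 Å, the footprint of the divergent tail.  The per-column table shows
why: core positions score ≈ 0.8–0.95 and are included, tail positions score
≈ 0.02 and are excluded,

```
31	-	3	0.019	0	0.993
32	-	3	0.018	0	0.994
...
```

and the tail's gradient parameter `t` is squeezed into 0.99–1.00: the ten
divergent residues receive a sliver of red while the conserved core spans
nearly the whole blue-to-red spectrum.  `demo/out/superposition.pml` loads
the superposed models into PyMOL with exactly these colours and an
`alignment` button for the per-column MST lines; `superposition.png` is a
stand-alone snapshot.

For classifications:

```bash
modelsup classmap demo/classification_a.tsv demo/classification_b.tsv \
        --out demo/tiers.tsv
```

writes one row per overlapping superfamily pair with its tier, shared
residue count and the domain-mapping / residue-overlap fractions both ways.

## Library use

```python
from modelsup import read_model
from modelsup.cli import run_superposition

models = [read_model(p) for p in ("m1.pdb", "m2.pdb", "m3.pdb")]
out = run_superposition(models)
print(out.result.rmsd_included, sorted(out.trim_result.excluded))
```

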
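# vennkit

Exclusive-region Venn analysis and drawing for named sets, built for
gene-list comparison in genomics and transcriptomics workflows (which
genes are shared by which RNA-seq samples or annotated genomes, and which
are unique to each).

## The model

Given `n` named sets `A_1 … A_n` (`1 ≤ n ≤ 31`), every element `x` of the
union receives an integer label

```
a_x = Σ_{i=1..n} b_i ,   b_i = 2^(i−1) if x ∈ A_i else 0
```

so that two elements share a label exactly when they belong to the same
*exclusive* intersection region — the elements in precisely that
combination of sets and no other. An `n`-set diagram resolves
`2^n − 1` such regions. Classification is a single pass over a hash table
of elements, linear in the total element count and independent of `2^n`,
which is what makes 31-set data processing practical.

Three diagram families are drawn, all as standalone SVG:

* **Classic** (1–5 sets): circles up to three sets, Venn's four-ellipse
  construction, and the symmetric five-ellipse construction (congruent
  ellipses rotated in 72° steps).
* **Edwards** (2–6 sets): two half-planes, a central circle, and
  serpentine "cogwheel" bands of doubling tooth count for sets four to
  six.
* **Nested** (5–8 sets): the first four sets form an outer Classic
  diagram and a miniature Classic diagram of the remaining sets is inlaid
  into every outer region (plus one standalone copy outside), so all
  `2^n − 1` counts — up to 255 for eight sets — stay legible.

Diagrams are limited to 8 sets (graph mode); from 9 to 31 sets the
partition is still computed and exported as text (data-processing mode).

## Worked example

Generate three synthetic gene lists with naturalistic overlap, export the
partition, and draw the diagram:

```sh
vennkit fixtures --n-sets 3 --elements 40 --seed 11 --out-dir sets
vennkit export sets/S1.txt sets/S2.txt sets/S3.txt --vertical counts.tsv
cat counts.tsv
```

```
combination	count	elements
S1	9	g1_12_e79e4a g1_15_e79e4a ...
S2	9	g2_11_e79e4a g2_13_e79e4a ...
S1&S2	3	g3_34_e79e4a g3_37_e79e4a g3_38_e79e4a
S3	8	g4_0_e79e4a g4_18_e79e4a ...
S1&S3	5	g5_10_e79e4a g5_1_e79e4a ...
S2&S3	3	g6_20_e79e4a g6_2_e79e4a g6_35_e79e4a
S1&S2&S3	3	g7_28_e79e4a g7_4_e79e4a g7_9_e79e4a
```

One row per combination of sets: 9 genes occur only in `S1`, 3 are shared
by exactly `S1` and `S2` (and not `S3`), 3 by all three, and so on; the
counts always sum to the size of the union (40 here). The vertical export
of an `n ≤ 8`-set input always has `2^n` lines (header + one row per
combination), e.g. 64 lines for six sets.

```sh
vennkit diagram sets/S1.txt sets/S2.txt sets/S3.txt --svg venn.svg
vennkit region sets/S1.txt sets/S2.txt sets/S3.txt "S1&S2&S3"
```

The SVG contains one semi-transparent shape per set and one count per
region; each count carries the stable id `region-<label>` and a tooltip
naming its combination, and the `region` subcommand prints the same
exclusive element list (`g7_28_e79e4a …`) for downstream use. Input files
are plain text with identifiers separated by any whitespace; matrix
(binary incidence, for network construction) and horizontal
(`S1&S2: g3_34… g3_37…`) exports are also available.

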
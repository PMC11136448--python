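# gatescribe

Cell-type annotation for flow and mass cytometry built around a
human-readable **marker table** — a pseudo-gating strategy that lists, per
cell type, whether each informative protein marker is positive (`+`),
medium (`m`), negative (`-`) or unconstrained (`*`). The table can be
written by an immunologist or **mined automatically from an annotated
reference dataset**, so the same interpretable object supports both
semisupervised (table-driven) and supervised (reference-driven) workflows.

## Who this is for

Cytometrists and computational immunologists who want automated cell
annotation that remains auditable in the vocabulary of manual gating:
every assignment traces back to a table row like `Mono: CD3-,CD19-,CD14+`
rather than to an opaque classifier.

## The model

**Level calling.** Each marker's (compensated, variance-stabilized)
intensity distribution is modeled with a univariate Gaussian mixture

&nbsp;&nbsp;&nbsp;&nbsp;p(x) = Σᵢ φᵢ 𝒩(x | μᵢ, σᵢ),&nbsp;&nbsp;i = 1…G,&nbsp;&nbsp;G ∈ {2, 3},

fitted by EM with either equal (**E**, one shared σ) or variable (**V**,
per-component σᵢ) variance. Cells are assigned to the
maximum-a-posteriori component; components ordered by mean map to the
symbols `-` (`m`) `+`. G = 3 is used only for markers whose table entry
declares a medium level. Optionally, **ranked set sampling** (set size
m = 2) builds the fitting sample from the order-statistic stratum opposite
the marker's skewness, sharpening bimodality in heavily skewed channels.

**Annotation.** The table is compiled into a priority-ordered dictionary
of concrete signatures (wildcards and `|`/`^` operator groups expanded;
ties resolved toward entries with more `+`/`m` markers). A simple random
sample of cells (default 10%) is signature-matched against the dictionary;
the remaining and unmatched cells are labeled by k-NN majority vote
(k = 10) in the Euclidean space of the table's markers. With the **reject
option**, mutual nearest neighbors between matched and unmatched cells
first separate classification errors from genuinely novel populations:
unmatched cells with no MNN into the matched set keep the label
`unknown`.

**Training.** Given reference labels, every pair of cell types is
discriminated by a shallow classification tree on the ordinal-encoded
signatures; the top-importance marker enters both types' entries at their
modal level. The greedy guard keeps the mined table minimal.

## Worked example

```bash
gatescribe simulate --output demo --n-cells 4000 --seed 5
gatescribe train    --input demo/expression.csv --labels demo/labels.csv \
                    --output demo/mined_table.csv --seed 5
gatescribe annotate --input demo/expression.csv --marker-table demo/mined_table.csv \
                    --output demo/annotation.csv --seed 5
gatescribe evaluate --input demo/annotation.csv --labels demo/labels.csv \
                    --output demo/metrics.csv
```

The simulated dataset draws four populations (T cells, B cells,
monocytes, NK cells at 40/30/20/10%) from a ground-truth gating design
over six markers, with the two components of each marker six standard
deviations apart. The final command prints

```
accuracy: 99.6%
median F1: 0.995
```

meaning 99.6% of the 4000 cells received their generating label after the
table was mined back from the data, and the median per-population F1 is
0.995; `demo/metrics.csv` holds the per-label precision/recall/F1
breakdown. The mined table itself (`demo/mined_table.csv`) is the
interpretable artifact: one row per cell type, e.g. `Tcell: CD3+,CD19-`.

The same steps are available as library calls
(`gatescribe.extract_marker_table`, `gatescribe.annotate`,
`gatescribe.per_label_prf`) on in-memory matrices.

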
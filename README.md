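# isips

Infer the assembly intermediates (subcomplexes) of a multiprotein complex
from protein–protein interaction (PPI) tables.

Multiprotein complexes rarely assemble in one step: subunits form
intermediate subcomplexes first. Which subunits go together early is hard
to observe directly, but it leaves a footprint in the interactome —
subunits of the same subcomplex tend to share more protein partners with
each other than with the rest of the complex. `isips` exploits that
footprint. Given the subunit list of one complex and MITAB interaction
exports (iRefIndex/BioGRID/IntAct style, optionally augmented with a
scored-prediction table such as PrePPI), it builds the complex-centric PPI
network, clusters the subunits bottom-up by shared *external* interactors,
and emits the inferred subcomplex hierarchy with branch supports and
per-subcomplex interactor reports. It is aimed at molecular biologists
planning assembly experiments and at anyone benchmarking complex-assembly
predictions.

## The score at the core

For two subunits or subcomplexes *x*, *y*, let *X*, *Y* be the sets of
proteins interacting with them and *SUₓ*, *SUᵧ* the complex subunits among
those. The pseudo-Jaccard similarity

    j(x, y) = (N(X ∩ Y) − N(SUₓ ∩ SUᵧ)) / (N(X ∪ Y) − N(SUₓ ∪ SUᵧ))

is the Jaccard index of the interactor sets after removing intra-complex
partners from both numerator and denominator: only partners *external* to
the complex count as evidence of co-assembly. Clustering uses the distance
d = 1 − j, merging the closest pair of clusters at each round and
recomputing distances from the merged cluster's full neighborhood (no
linkage-update formula). Five alternative association scores (Dice,
Minimum Sensitivity, Ochiai, Overlap, Kulczynski) are available for
comparison. Each internal branch of the resulting dendrogram is annotated
with the rate of well-designed triples: the fraction of triples {x, y, y′}
with x in one of the two clades the branch joins and y, y′ in the other
such that j(y, y′) ≥ max(j(x, y), j(x, y′)).

## Worked example

The package ships a generator for a small frozen example: 5 subunits
(A–E) and 12 external proteins.

```sh
python -c "from isips.synthgen import fig2_fixture; fig2_fixture('db')"
isips run --input db/inputlist.txt --db-dir db --out results
```

prints

```
network: 17 proteins, 24 interactions
merges: 4 (method=pseudo_jaccard)
tree: ((A,B):0.571429,(D,(C,E):0.750000):0.833333):0.916667
artifacts written to results
```

Reading the tree line: A and B merge first at distance 0.571429 = 4/7 —
they share 6 interactors out of 10, of which 3 shared and 3 total are
fellow subunits, so j = (6−3)/(10−3) = 3/7. C and E join next (d = 0.75),
then D joins them, and the root (d ≈ 0.917) completes the complex. The
single-pair view shows the underlying counts:

```
$ isips score --input db/inputlist.txt --db-dir db A B
j(A,B) = 0.428571	d = 0.571429	[N_int=6 N_uni=10 N_su_int=3 N_su_uni=3]
```

`results/` contains the three interaction tiers (complete, partially
redundant, non-redundant with PubMed counts), the network edge list and
summary, the per-step distance matrices, the tree in linear format and in
newick (merge-distance and support variants), an SVG dendrogram drawn
horizontally (root left; the vertical ordering of leaves is layout, not
chronology), and the per-subcomplex interactor lists.

`isips synth` generates synthetic MITAB inputs with planted subcomplex
structure for benchmarking; see `isips --help`.

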
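# biogap

Protected-area (PA) gap analysis across four dimensions of biodiversity —
species, phylogenetic diversity, weighted endemism and phylogenetic
endemism — with explicit correction for spatially biased collection effort.
The package targets conservation biogeographers who have occurrence
records, PA and biome polygons, environmental rasters and (partial)
phylogenies, and want to know how much of each biodiversity dimension the
reserve network misses, how that changed as the network grew, and how far
sampling artefacts distort the answer. Because national occurrence
databases are rarely shareable, a synthetic-data module generates whole
landscapes with known ground truth, so every estimator in the pipeline is
testable end to end.

## The quantities at the core

Distribution data are aggregated on a hexagonal grid (cell diameter 55 km,
the ground analogue of 0.5°). For species *s* occupying `R_s` hexagons, the
**weighted endemism** is `WE_s = 1/R_s`, and a cell's WE is the sum over
the species present in it — so each species contributes exactly 1 summed
over the grid. **Phylogenetic weighted endemism** generalises this to tree
branches: a branch of length `L` whose descendant clade occupies `R`
hexagons contributes `L/R` to each of them (branch lengths are all set to
1, since lengths are not comparable across source trees). **Phylogenetic
diversity** of a species set is the total branch length of the minimal
rooted subtree spanning it.

Raw WE conflates narrow ranges with poor sampling, so a corrected index is
computed per species:

```
WE* = (A·B) / (A·B + (1−A)(1−C))
```

where `A = WE` (clamped into (ε, 1−ε), ε = 1e-5), `B = A ×` the species'
normalised sampling effort (mean count of records within 50 km of its
occurrences, normalised by the best-sampled species), and `C` grows
linearly with the species' record count from 1e-5 at a single record to
0.999 at 150+, where the records-per-species distribution saturates.

Supertrees are assembled by **matrix representation with parsimony**: every
clade of every source tree becomes a binary character (members 1, other
taxa of that tree 0, absent taxa `?`), and a **parsimony ratchet**
(alternating NNI hill-climbing under reweighted and original characters)
searches for the most parsimonious merged tree.

Species-level range estimates come from an ensemble of distribution models
(Bioclim envelope, Domain/Gower, Mahalanobis, logistic GLM) fitted on the
first four correlation-PCA axes of 21 environmental layers, binarised at
the lowest training-point suitability (zero training omission) and kept
only when the pseudo-absence AUC exceeds 0.7.

## Worked example

The numbered scripts under `analysis/` run the study on a synthetic world
(all accept `--seed`). For example:

```
$ python analysis/06_gap_report.py --seed 1
share of biodiversity outside the PA network:
  species         51.25%  (41/80)
  lineage length  12.03%
  WE sum          44.66%
  PWE sum         44.42%
per-epoch accumulation slopes (degrees, species):
  1903-1950:  59.41
  1951-1980:  33.81
  1981-1990:  -0.00
  1991-2000:  -0.00
  2001-2016:  33.44
report -> results/report.json
```

Reading: 41 of the 80 simulated species have no record inside any PA;
lineage length is far better covered (12% outside) because deep branches
are protected as soon as any descendant is; the endemism sums split almost
evenly. The slope sequence shows protection accruing in the epochs in
which this world's PAs happened to be designated, on axes normalised to
percent-of-final value versus percent of the 1903–2016 span. The other
scripts cover simulation (`01`), per-PA sampling effort and density
classes (`02`), raw vs corrected endemism (`03`), MRP supertree recovery
(`04`) and the SDM ensemble (`05`); each prints what it found and writes
its tables under `results/`.

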
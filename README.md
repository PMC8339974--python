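# amesread

Local read-across and global machine-learning models for *Salmonella*
mutagenicity (Ames test) prediction.

The bacterial reverse-mutation (Ames) assay is the standard first step of
genotoxicity assessment. `amesread` is for computational toxicologists who
need *in silico* mutagenicity calls with an explicit applicability domain:
it implements a lazar-style **local read-across classifier** — for each
query structure, find experimentally characterized neighbors, then take a
similarity-weighted majority vote — alongside five **global baseline
learners** (random forest, two logistic-regression variants, a small
neural-network ensemble, an RBF SVM), a 10-fold crossvalidation harness
with the standard confusion-matrix metric panel, dataset-compilation rules
for heterogeneous Ames sources, and a structural-group summarizer for
pyrrolizidine alkaloids (PAs).

## The model

Structures are represented either by **atom-environment fingerprints**
(MolPrint2D-style: per heavy atom, the counted atom types at topological
distances 1 and 2, collected into a set) or by numeric descriptor vectors
(CDK/PaDEL-style matrices read from CSV). Similarity between compounds
*a*, *b* is

* Tanimoto/Jaccard over feature sets:  sim = |A ∩ B| / |A ∪ B|
* cosine over descriptor vectors:      sim = A·B / (|A||B|)

Neighbors above a similarity threshold vote with their experimental
outcomes, weighted by similarity:

    p_c = Σ sim_n,c / Σ sim_n

and the class with the higher probability is the prediction. Thresholds
are tiered: first 0.5 (fingerprints) or 0.9 (descriptors) for
**high-confidence** predictions; on failure 0.2 / 0.7 with a **low
confidence** applicability-domain warning; if both tiers fail the engine
abstains. Database entries with the query's own canonical structure are
excluded from its neighbors, so predicting a training compound behaves
like leave-one-out.

Training data are compiled from per-source tables by canonical-SMILES
merge: same-structure/same-outcome replicates collapse to one measurement,
conflicting outcomes are kept as two measurements and flagged
contradictory, and strain-wise tables are reduced to a binary call
(mutagenic iff ≥ 1 positive in the TA97–TA1538 *S. typhimurium* strains,
with or without S9 activation).

## Worked example

The package ships a deterministic generator of congeneric chemical series
whose labels are driven by an aromatic-nitro toxicophore — a synthetic
stand-in for a curated Ames database that makes every stage runnable
without downloads:

```python
from amesread.synthetic import FixtureSpec, generate
from amesread.fingerprints import fingerprints_for
from amesread.lazar import LazarModel
from amesread.validation import crossvalidate_lazar, build_report

dataset, descriptors = generate(FixtureSpec(seed=42))   # 20 series x 10 congeners
fps = fingerprints_for({k: k for k in dataset.keys()})

model = LazarModel.from_dataset(dataset, fps, kernel="tanimoto")
query = dataset.keys()[0]
pred = model.predict(fps[query], query_key=query)
print(pred.predicted, pred.p_mutagenic, pred.confidence, len(pred.neighbors))

rows = crossvalidate_lazar(dataset, fingerprints=fps, k=10, seed=1)
for label, conf in (("lazar-HC", "high"), ("lazar-all", None)):
    r = build_report(rows, label, confidence=conf)
    print(label, r.panel, r.n_predictions, r.n_total)
```

prints (abridged):

```
mutagenic 1.0 high 4
lazar-HC: acc=98.0% tpr=98.8% tnr=97.2% predictions=153/200
lazar-all: acc=98.5% tpr=99.0% tnr=98.0% predictions=200/200
```

The query (a nitro-bearing xylene congener) is predicted mutagenic with
certainty because all four neighbors above the 0.5 tier carry the same
alert; `lazar-HC` scores only the 153 high-confidence predictions while
`lazar-all` includes the low tier — on clean congeneric data both recover
the toxicophore rule almost perfectly, and accuracy degrades as label
noise is added (see `scripts/acceptance.py`).

The same workflows are available from the shell:

```bash
amesread fixture --seed 42 --out-dir fix/
amesread crossvalidate --model lazar-mp2d --train fix/training.csv --out-dir cv/
amesread crossvalidate --model rf --train fix/training.csv --descriptors fix/descriptors.csv --out-dir cv/
amesread pa-classify --input pas.csv --out assignments.csv
```

Every run writes a manifest (resolved configuration, seed, input digests)
next to its outputs.

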
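# mthvr

Ancestry inference from mitochondrial hypervariable-region (HVR1/HVR2)
profiles: profile parsing and validation, binary feature encoding with three
missing-data strategies, exact PCA with cross-validated dimension selection,
four classifiers (RBF soft-margin SVM, LDA, QDA, Hamming 1-nearest-neighbor),
micro/macro accuracy evaluation, region-informativeness scans, and a
structured synthetic-data generator.

Profiles are rCRS-relative polymorphism lists (`16298C` substitution,
`16124.1C` insertion, `16189-` deletion) plus explicit typed ranges, stored
as TSV:

```
sample_id	label	country	ranges	polymorphisms
S1	Caucasian	US	73-340;16024-16365	16298C 16311C
```

Untyped positions are missing data; three strategies handle them at
prediction time: reference imputation (`rcrs`), per-position training rates
(`probability`), and restriction to the training/test common region
(`common_region`, refit per distinct test region signature).

## CLI

```
mthvr simulate --n-samples 400 --coverage forensic_like --seed 1 \
    --out profiles.tsv --truth truth.tsv
mthvr summarize profiles.tsv --coverage
mthvr cv profiles.tsv --classifier svm --k 10 --svm-c 10 --gamma 0.1
mthvr holdout --train train.tsv --test test.tsv --strategy common-region \
    --classifier svm --k 10 --svm-c 10 --gamma 0.1
mthvr scan profiles.tsv --mode window --classifier 1nn --out scan.tsv
mthvr train profiles.tsv --classifier lda --k 5 --model-out model.pkl
mthvr predict new_profiles.tsv --model model.pkl
```

Omit `--k`/`--svm-c`/`--gamma` to select them by nested 5-fold
cross-validation on the training partition (slower).

## Library sketch

```python
from mthvr.synthetic_data import SyntheticConfig, generate_dataset
from mthvr.evaluation import PipelineSpec, cross_validate

dataset, truth = generate_dataset(SyntheticConfig(n_samples=500, seed=1))
result = cross_validate(dataset, PipelineSpec(classifier="svm", k=10,
                                              C=10.0, gamma=0.1), seed=0)
print(result.micro, result.macro, result.per_class())
```

Modules: `profile_io` (tables, trimming, coverage), `feature_encoding`
(feature spaces, encodings, strategies), `pca`, `classifiers`, `evaluation`
(CV, holdout, scans, metrics), `synthetic_data`.

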
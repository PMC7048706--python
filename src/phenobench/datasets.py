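"""Published benchmark accuracy tables shipped with the package.

Three traits × methods accuracy tables from published genomic phenotype
prediction benchmarks, transcribed at their printed precision:

* ``load_yeast_table`` — cvR² for 46 growth traits of a laboratory × wine
  yeast cross (tenfold CV), methods: Bloom (sequential QTL mapping), lasso,
  ridge, BLUP, GBM, RF, SVM.
* ``load_wheat_table`` — cvR² for 4 agronomic traits of 254 wheat breeding
  lines (fivefold CV, 10 resampling runs), methods: lasso, ridge, BLUP, GBM,
  RF, SVM.
* ``load_rice_table`` — test-set R² for 12 agronomic traits of the 3000 Rice
  Genomes Core SNP subset (70/30 train/test), same six methods.

These tables are the inputs for the rank-based method comparison in
:mod:`phenobench.rankstats`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("phenobench.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def load_yeast_table() -> pd.DataFrame:
    """46 yeast growth traits × 7 methods, cvR² (tenfold CV)."""
    return _load("yeast_cvr2.tsv")


def load_wheat_table() -> pd.DataFrame:
    """4 wheat traits × 6 methods, cvR² averaged over 10 fivefold-CV runs."""
    return _load("wheat_cvr2.tsv")


def load_rice_table() -> pd.DataFrame:
    """12 rice traits × 6 methods, R² on a 70/30 train/test split."""
    return _load("rice_r2.tsv")
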
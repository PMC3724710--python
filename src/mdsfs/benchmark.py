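"""Published benchmark results on the DD, TG and EDD protein fold datasets.

The original MD-SFS study evaluated attribute selection on three protein
fold recognition benchmarks — Ding & Dubchak's dataset (DD, 27 SCOP folds),
Taguchi & Gromiha's dataset (TG, 30 folds) and the extended DD set (EDD) —
with three classifiers (LDA + nearest centroid, linear SVM, naive Bayes)
under 10-fold cross-validation.  Those datasets are not bundled here, but
the published accuracy tables are themselves the inputs of two analyses the
package reproduces exactly:

* the one-sided paired t-test comparing backward brute-5 selections (from
  all 30 attributes) against the classic HPZXV benchmark subset, and
* occurrence counting of attribute symbols over the 18 brute-5 subsets
  selected from the full attribute universe (both schemes, all datasets and
  classifiers).

Accuracies are in percent.
"""

from __future__ import annotations

DATASETS = ("DD", "TG", "EDD")
CLASSIFIERS = ("LDA", "SVM", "NB")

#: 10-fold CV fold recognition (%) of the classic five-attribute benchmark
#: subset HPZXV, per dataset and classifier.
HPZXV_ACCURACY: dict[str, dict[str, float]] = {
    "DD": {"LDA": 23.1, "SVM": 29.5, "NB": 32.8},
    "TG": {"LDA": 20.5, "SVM": 23.5, "NB": 28.8},
    "EDD": {"LDA": 27.5, "SVM": 31.7, "NB": 38.4},
}

#: Backward-elimination brute-5 selections from all 30 attributes:
#: (subset symbols, accuracy %), per dataset and classifier.
BACKWARD_BRUTE5_ALL: dict[str, dict[str, tuple[str, float]]] = {
    "DD": {"LDA": ("BPEVO", 39.7), "SVM": ("BPDFM", 35.2), "NB": ("IUKaP", 44.0)},
    "TG": {"LDA": ("FJBaf", 28.3), "SVM": ("JTFQB", 31.0), "NB": ("JbXMK", 39.5)},
    "EDD": {"LDA": ("TJXbV", 36.3), "SVM": ("JTFOH", 38.2), "NB": ("IXMEb", 46.6)},
}

#: Forward-selection brute-5 selections from all 30 attributes.
FORWARD_BRUTE5_ALL: dict[str, dict[str, tuple[str, float]]] = {
    "DD": {"LDA": ("BDEFa", 35.3), "SVM": ("JBPKG", 34.0), "NB": ("BUDOG", 44.1)},
    "TG": {"LDA": ("FJTaB", 30.1), "SVM": ("JTFWD", 31.6), "NB": ("JTMWO", 39.2)},
    "EDD": {"LDA": ("ITXJc", 36.2), "SVM": ("ITMJB", 39.1), "NB": ("JTMWF", 46.8)},
}


def brute5_all_subsets() -> list[str]:
    """The 18 brute-5 subsets selected from all 30 attributes.

    Both schemes, all three datasets and classifiers; the corpus over which
    attribute occurrences are counted.
    """
    out = []
    for scheme in (BACKWARD_BRUTE5_ALL, FORWARD_BRUTE5_ALL):
        for ds in DATASETS:
            for clf in CLASSIFIERS:
                out.append(scheme[ds][clf][0])
    return out


def ttest_vectors(classifier: str) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Paired accuracy vectors (x, y) for the published t-test of one classifier.

    x = backward brute-5 selections from all 30 attributes (DD, TG, EDD);
    y = the HPZXV benchmark subset on the same datasets.
    """
    x = tuple(BACKWARD_BRUTE5_ALL[ds][classifier][1] for ds in DATASETS)
    y = tuple(HPZXV_ACCURACY[ds][classifier] for ds in DATASETS)
    return x, y
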
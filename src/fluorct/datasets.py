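"""Bundled worked-example data used in documentation and validation.

``example_fold_change_table`` is the published relative-expression report
of a blastocoel-fluid qPCR study of one apoptosis-related target gene
normalised to an endogenous control across 18 expressing embryos: the
fold-change ratio of each sample versus the highest-expressing sample
(Expressed Sample 4) and the printed log10 of that ratio.  The spread —
about fourteen orders of magnitude between the highest- and
lowest-expressing samples — is the dynamic range that a single fixed
fluorescence threshold cannot span.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["example_fold_change_table"]

_EXAMPLE_ROWS = [
    ("Expressed Sample 1", 7.06e-06, -5.15),
    ("Expressed Sample 2", 0.16, -0.80),
    ("Expressed Sample 3", 1.70e-04, -3.75),
    ("Expressed Sample 4", 1.00, 0.00),
    ("Expressed Sample 5", 6.51e-06, -5.19),
    ("Expressed Sample 6", 1.40e-03, -2.85),
    ("Expressed Sample 7", 9.76e-07, -6.01),
    ("Expressed Sample 8", 0.087, -1.06),
    ("Expressed Sample 9", 1.88e-13, -12.73),
    ("Expressed Sample 10", 1.36e-05, -4.87),
    ("Expressed Sample 11", 1.22e-06, -5.91),
    ("Expressed Sample 12", 1.41e-06, -5.85),
    ("Expressed Sample 13", 1.42e-06, -5.85),
    ("Expressed Sample 14", 1.07e-14, -13.97),
    ("Expressed Sample 15", 3.12e-07, -6.51),
    ("Expressed Sample 16", 5.18e-05, -4.29),
    ("Expressed Sample 17", 1.14e-06, -5.94),
    ("Expressed Sample 18", 1.01e-06, -5.99),
]


def example_fold_change_table() -> pd.DataFrame:
    """The printed example report: sample, fold_change_ratio, log10_fold_change.

    Ratios are as printed (3 significant figures, 2 for the sub-unity
    decimals) and the log column is as printed (2 decimals); the two
    columns are related by log10 up to that rounding.
    """
    return pd.DataFrame(
        _EXAMPLE_ROWS, columns=["sample", "fold_change_ratio", "log10_fold_change"]
    )
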
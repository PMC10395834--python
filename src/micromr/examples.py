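"""Worked-example data: a published diet → gut-microbe → colorectal-tumor
mediation table.

Twenty two-step MR pathways linking dietary habits, microbial mediators and
colorectal-tumor phenotypes (CRC: colorectal cancer; CC/CR: malignant colon /
rectal tumors; BCR/BC/BR: benign colorectal / colon / rectal tumors), as
printed in a published summary-statistics MR analysis: total effect ``b1``,
exposure→mediator effect ``b2``, mediator→outcome effect ``b3``, indirect
effect ``b``, mediation probability ``p`` and mediated proportion (%).

The printed ``b`` and proportion columns were derived from unrounded
coefficients, so re-deriving them from the two-decimal ``b2``/``b3`` shown
here reproduces them exactly only where rounding happens to commute (the
bread and calcium rows among others); the sign pattern and the 10-of-20
direction-consistency count are exact.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["mediation_example_table"]

_MEDIATION_TSV = """\
pathway\tb1\tb2\tb3\tb\tp\tproportion
Alcohol drinker status: Current-Eubacterium ventriosum-CC\t11.03\t-19.24\t-0.25\t4.75\t0.00\t43.04
Bread intake-Bacteroides ovatus-BCR\t0.54\t0.63\t0.11\t0.07\t0.04\t12.64
Cereal type: Biscuit cereal-Erysipelotrichaceae-CRC\t-2.99\t2.44\t-0.17\t-0.42\t0.94\t13.97
Ferritin-Streptococcus thermophilus-CRC\t0.27\t-0.42\t-0.22\t0.09\t0.02\t34.22
Ferritin-Sutterellaceae unclassified-BR\t0.35\t0.72\t-0.24\t-0.18\t0.97\t-49.67
Lamb/mutton intake-Eubacterium siraeum-CR\t-2.19\t-0.62\t-0.33\t0.21\t0.07\t-9.51
Liver intake-Eubacterium ventriosum-CC\t0.84\t8.90\t-0.25\t-2.20\t0.97\t-261.5
Milk type: Never/rarely have milk-Bifidobacterium adolescentis-BCR\t5.39\t51.02\t0.46\t23.45\t0.01\t435.4
Milk type: Never/rarely have milk-Streptococcus-CC\t9.33\t26.29\t-0.17\t-4.46\t0.99\t-47.79
Supplements: Calcium-Bacteroides ovatus-BR\t4.05\t2.99\t0.16\t0.48\t0.05\t11.85
Supplements: Calcium-Bacteroides ovatus-BCR\t2.86\t2.99\t0.11\t0.33\t0.05\t11.40
Supplements: Calcium-Bacteroides ovatus-BC\t4.69\t2.99\t0.11\t0.34\t0.06\t7.23
Supplements: Glucosamine-Sutterellaceae unclassified-BR\t2.66\t3.42\t-0.24\t-0.83\t0.99\t-31.11
Supplements: Zinc-Bifidobacterium adolescentis-BCR\t3.86\t-8.69\t0.46\t-3.99\t0.99\t-103.5
Single crust pastry intake-Coprococcus sp_ART55_1-CR\t5.57\t6.66\t-0.29\t-1.93\t0.94\t-34.57
Special diet: Gluten-free-Erysipelotrichaceae-CR\t-6.55\t-4.71\t-0.22\t1.05\t0.05\t-16.02
Special diet: Gluten-free-Streptococcus-CC\t5.39\t6.27\t-0.17\t-1.06\t0.96\t-19.74
Supplements: Multivitamins +/- minerals-Bacteroides ovatus-BC\t2.62\t2.03\t0.11\t0.23\t0.04\t8.82
Supplements: Multivitamins +/- minerals-Bacteroides ovatus-BCR\t3.16\t2.03\t0.11\t0.22\t0.03\t7.03
Supplements: Vitamin C-Coprococcus sp_ART55_1-CR\t31.68\t32.35\t-0.29\t-9.36\t0.95\t-29.54
"""


def mediation_example_table() -> pd.DataFrame:
    """The 20-pathway worked-example mediation table as a DataFrame."""
    return pd.read_csv(io.StringIO(_MEDIATION_TSV), sep="\t")
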
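"""Small published data bundled for worked examples.

``sap_alpha_diversity`` is the printed per-individual alpha-diversity
table for the one polymorphic planthopper population (SAP): 10
Wolbachia-infected (w+) and 9 uninfected (w-) female adults, rarefied to
39872 reads.  It is the input to the infected-vs-uninfected Welch
t-test battery.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["sap_alpha_diversity"]

_SAP_ALPHA = """\
sample_id\tinfected\tsobs\tshannon\tsimpson\tace\tchao\tcoverage
w+1\tTrue\t693\t1.594\t0.5328\t816.372\t766.533\t0.996
w+2\tTrue\t356\t0.707\t0.832\t434.097\t409.182\t0.998
w+3\tTrue\t76\t0.378\t0.829\t206.037\t126.647\t0.999
w+4\tTrue\t161\t0.210\t0.949\t234.636\t206.217\t0.998
w+5\tTrue\t139\t0.406\t0.850\t188.332\t178.200\t0.999
w+6\tTrue\t132\t0.206\t0.943\t314.430\t235.542\t0.998
w+7\tTrue\t107\t0.561\t0.771\t199.706\t152.000\t0.999
w+8\tTrue\t95\t0.475\t0.787\t209.990\t159.688\t0.999
w+9\tTrue\t96\t0.337\t0.877\t148.918\t133.625\t0.999
w+10\tTrue\t93\t0.965\t0.466\t149.309\t143.167\t0.999
w-1\tFalse\t247\t1.232\t0.459\t342.134\t312.632\t0.998
w-2\tFalse\t402\t1.490\t0.412\t431.463\t443.143\t0.998
w-3\tFalse\t399\t3.987\t0.040\t461.191\t457.400\t0.998
w-4\tFalse\t636\t5.063\t0.013\t689.927\t684.838\t0.998
w-5\tFalse\t528\t3.990\t0.052\t628.688\t643.000\t0.997
w-6\tFalse\t516\t3.962\t0.052\t630.807\t621.726\t0.997
w-7\tFalse\t640\t4.590\t0.027\t709.431\t722.787\t0.997
w-8\tFalse\t534\t3.915\t0.052\t632.849\t651.018\t0.997
w-9\tFalse\t497\t3.817\t0.065\t599.893\t629.255\t0.997
"""


def sap_alpha_diversity() -> pd.DataFrame:
    """Published alpha-diversity indexes for 10 infected and 9 uninfected
    females from the SAP population (index = individual, ``infected``
    boolean column, then Sobs/Shannon/Simpson/Ace/Chao/Coverage)."""
    df = pd.read_csv(StringIO(_SAP_ALPHA), sep="\t", index_col=0)
    df["infected"] = df["infected"].astype(bool)
    return df
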
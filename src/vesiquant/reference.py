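"""Published reference abundances of prohormone-processing components.

Mean total NSAF (x1e3) with standard deviations for the chromogranins,
prohormone convertases PC1/3 and PC2 with their endogenous regulators
proSAAS and 7B2, carboxypeptidase E, and related enzymes of dense-core
secretory vesicles, as reported for the human pheochromocytoma granule
proteome.  Used as a worked example for abundance-ratio computation
(PC2:PC1/3 ~ 3, CPE:PC1/3 ~ 6, PC2:7B2 ~ 3, proSAAS:PC1/3 ~ 3.5).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def prohormone_abundances() -> pd.DataFrame:
    """The packaged abundance table, indexed by protein label.

    Columns: ``mean_nsaf_x1000``, ``sd_x1000``.
    """
    ref = resources.files("vesiquant").joinpath("data/prohormone_nsaf.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="protein")
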
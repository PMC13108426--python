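"""urbanscape: landscape genomics of urban vs. rural wildlife populations.

End-to-end toolkit for reduced-representation SNP data sampled from
colonies along an urbanisation gradient: variant QC, population structure
(PCA, sparse-NMF admixture, Weir-Cockerham FST), isolation by distance
(multiple regression on distance matrices), circuit-theory landscape
connectivity with MLPE mixed-model hypothesis comparison, RDA-based
genotype-environment association, candidate-SNP annotation, protein
network topology and GO enrichment.  A synthetic-data generator with a
ground-truth record supports parameter-recovery testing of every stage.
"""

from importlib import resources

import pandas as pd

__version__ = "0.1.0"


def load_study_colonies() -> pd.DataFrame:
    """Colony table of the ten Israeli fruit-bat roosts (five urban in the
    Greater Tel Aviv area, five rural around Beit Guvrin), with WGS84
    coordinates and percent urban cover within 5 km of each roost."""
    with resources.files("urbanscape.data").joinpath("colonies_israel.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
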
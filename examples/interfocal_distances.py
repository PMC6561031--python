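"""CFP/YFP interfocal distances: integrated versus excised element.

Generates colabel snapshots (element marked by LacI-CFP, nearby chromosomal
locus by TetR-YFP), pairs the foci per cell, and summarizes 2D interfocal
distances in the single-chromosome (0.8-1.8 um) window.
"""
import pandas as pd

from icetrack import preset, generate_colabel_snapshot, pair_foci_table
from icetrack.geometry import interfocal_summary
from icetrack.spots import apply_thresholds

cfg = preset("wildtype")
for population, label in (("non_tc", "integrated element"),
                          ("tc", "excised element")):
    cells, foci, _ = generate_colabel_snapshot(cfg, 800,
                                               population=population, seed=5)
    pairs = pair_foci_table(cells, apply_thresholds(foci))
    classes = pd.Series(population, index=cells["cell_id"])
    summary, _ = interfocal_summary(pairs, classes)
    row = summary[summary["ploidy_class"] == "oneX"].iloc[0]
    print(f"{label:20s}  n={row['n']:4d}  mean {row['mean_nm']:.0f} nm  "
          f"sd {row['sd_nm']:.0f} nm")
# Integrated: operator arrays sit ~12 kb apart on the chromosome -> ~200 nm.
# Excised: the element physically disengages from its locus -> ~385 nm, about
# twice as far, the signature of excision in tc cells.
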
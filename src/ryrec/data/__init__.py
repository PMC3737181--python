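"""Packaged reference tables for the *rosy* transgene assay.

``table1_marker_map.tsv`` transcribes the 25 polymorphisms distinguishing the
*ry606N* and *ry609N* transgenes.  The printed source table is internally
inconsistent for five rows (−527, −468, −332, −323, −320): the variant state
is shown in the *ry609N* column while the comments and the construction
narrative place those changes — including the *ry606* null mutation itself —
on the *ry606N* transgene.  The fixture follows the construction narrative,
the only assignment under which selection for *ry+* recombinants is coherent.

``table2_counts.tsv`` holds the per-location screen sizes and CO/NCO counts;
``fig4_intervals.tsv`` holds the standard-map flanking-gene intervals used
for regional cM/Mb comparisons.
"""

from importlib import resources

import pandas as pd

from ..markers import MarkerMap, load_marker_map
from ..stats import RateRow, load_intervals, load_location_counts


def _path(name: str):
    return resources.files(__package__).joinpath(name)


def marker_map_path():
    return _path("table1_marker_map.tsv")


def counts_path():
    return _path("table2_counts.tsv")


def intervals_path():
    return _path("fig4_intervals.tsv")


def example_sim_config_path():
    return _path("example_sim.yaml")


def marker_map() -> MarkerMap:
    """The packaged 25-site transgene marker map."""
    with resources.as_file(marker_map_path()) as p:
        return load_marker_map(p)


def location_counts() -> list[RateRow]:
    """Per-location progeny totals and CO/NCO counts."""
    with resources.as_file(counts_path()) as p:
        return load_location_counts(p)


def regional_intervals() -> pd.DataFrame:
    """Standard-map intervals flanking each insertion site."""
    with resources.as_file(intervals_path()) as p:
        return load_intervals(p)
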
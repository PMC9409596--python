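"""Shared builders for test data."""

import pandas as pd

from fdsweep import TraitTable


def random_mean_traits(rng, n_species=8, n_cont=3, n_cat=1):
    """A random species-mean TraitTable, complete on every trait."""
    rows = []
    for i in range(n_species):
        sp = f"s{i}"
        for j in range(n_cont):
            rows.append((sp, f"T{j}", float(rng.normal(10, 3)), "continuous"))
        for j in range(n_cat):
            rows.append((sp, f"C{j}", f"L{int(rng.integers(3))}", "categorical"))
    return TraitTable(
        pd.DataFrame(rows, columns=["species", "trait", "value", "kind"])
    )
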
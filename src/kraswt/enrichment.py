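"""One-tailed hypergeometric gene-set over-representation.

Run separately per signature direction.  The universe defaults to the
genes that passed the differential-expression prefilter (the tested-gene
background); sets are intersected with the universe before testing and
sets with fewer than ``min_set_size`` in-universe members are reported as
untested to avoid degenerate tails.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import GeneSetCollection
from .stats import bh_adjust, hypergeom_tail

DEFAULT_MIN_SET_SIZE = 5


def enrich(query: Sequence[str], sets: GeneSetCollection,
           universe: Sequence[str],
           min_set_size: int = DEFAULT_MIN_SET_SIZE) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set.

    p = P(X >= k) for X ~ Hypergeom(N = |universe|, K = |set in universe|,
    n = |query|); BH across all tested sets.  Returns rows sorted by
    adjusted p; untested (too-small) sets carry NaN p-values.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    if not q:
        raise ValueError("empty query")
    stray = q - uni
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:5]}")
    N, n = len(uni), len(q)
    rows = []
    for name in sets.names():
        members = set(sets.members(name)) & uni
        K = len(members)
        overlap = sorted(members & q)
        k = len(overlap)
        tested = K >= min_set_size
        p = hypergeom_tail(k, K, n, N) if tested else np.nan
        rows.append({"set_name": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N,
                     "p_raw": p, "tested": tested,
                     "overlap_genes": ",".join(overlap)})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    tested_idx = df.index[df["tested"]]
    if len(tested_idx):
        df.loc[tested_idx, "p_adj"] = bh_adjust(
            df.loc[tested_idx, "p_raw"].to_numpy())
    return df.sort_values(["p_adj", "set_name"], kind="mergesort",
                          na_position="last").reset_index(drop=True)
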
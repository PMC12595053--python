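"""Published entropy/weight reference table and the weight round-trip check.

A CSV of per-variable entropies and weights for the four crop x phase blocks
(coffee and cacao under El Niño and La Niña, six climate variables each)
ships with the package.  ``recompute_weights`` re-derives every weight from
the entropies alone through the EWM formulas (d_i = 1 - E_i,
w_i = d_i / sum d_i) and reports the deviation from the published value —
a fast desk check that the weighting arithmetic is implemented exactly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from ensotel.ewm import weights_from_entropy

_DATA_PACKAGE = "ensotel.data"
_TABLE_NAME = "table1_entropies.csv"


def load_reference_entropies(path=None) -> pd.DataFrame:
    """The bundled crop x phase x variable entropy/weight table."""
    if path is not None:
        df = pd.read_csv(path)
    else:
        with resources.files(_DATA_PACKAGE).joinpath(_TABLE_NAME).open() as fh:
            df = pd.read_csv(fh)
    required = {"crop", "phase", "variable", "entropy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns {sorted(missing)}")
    return df


def recompute_weights(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute each block's weights from its entropies.

    Adds ``weight_recomputed`` and, where a published ``weight`` column
    exists, ``abs_dev`` = |recomputed - published| after rounding the
    recomputed weight to 4 decimals (the table's printed precision).
    """
    if df is None:
        df = load_reference_entropies()
    out = []
    for (crop, phase), block in df.groupby(["crop", "phase"], sort=False):
        block = block.copy()
        _, w = weights_from_entropy(block["entropy"].to_numpy())
        block["weight_recomputed"] = w
        if "weight" in block.columns:
            block["abs_dev"] = (block["weight_recomputed"].round(4)
                                - block["weight"]).abs()
        out.append(block)
    return pd.concat(out, ignore_index=True)


def max_weight_deviation(path: Path | None = None) -> float:
    """Largest |recomputed - published| weight over all blocks."""
    df = recompute_weights(load_reference_entropies(path))
    if "abs_dev" not in df.columns:
        raise ValueError("reference table has no published 'weight' column")
    return float(df["abs_dev"].max())
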
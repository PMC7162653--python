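"""Published connection counts from a paired-recording study of cortical clones.

Counts of connected / tested directed pairs between excitatory neurons in
mouse somatosensory cortex, split by lineage relation (related = both cells
labeled within one clone; unrelated = exactly one labeled) and by pre/post
layer.  Vertical types cross layers; lateral types stay within a layer.
These tables let the analyses and worked examples run without any download.
"""

from __future__ import annotations

import pandas as pd

# (relation, pre_layer, post_layer): (connected, tested)
_COUNTS = {
    # vertical, related
    ("related", "L2/3", "L4"): (0, 98),
    ("related", "L4", "L2/3"): (12, 91),
    ("related", "L5", "L2/3"): (2, 75),
    ("related", "L2/3", "L5"): (6, 76),
    ("related", "L4", "L5"): (7, 62),
    ("related", "L5", "L4"): (1, 62),
    # vertical, unrelated
    ("unrelated", "L2/3", "L4"): (0, 141),
    ("unrelated", "L4", "L2/3"): (12, 149),
    ("unrelated", "L5", "L2/3"): (3, 118),
    ("unrelated", "L2/3", "L5"): (2, 123),
    ("unrelated", "L4", "L5"): (2, 89),
    ("unrelated", "L5", "L4"): (0, 91),
    # lateral, related
    ("related", "L2/3", "L2/3"): (2, 105),
    ("related", "L4", "L4"): (11, 100),
    ("related", "L5", "L5"): (1, 43),
    # lateral, unrelated
    ("unrelated", "L2/3", "L2/3"): (20, 342),
    ("unrelated", "L4", "L4"): (17, 148),
    ("unrelated", "L5", "L5"): (14, 136),
}

#: pooled counts over connection classes: (connected, tested)
POOLED = {
    ("related", "all"): (42, 712),
    ("unrelated", "all"): (70, 1337),
    ("related", "vertical"): (28, 464),
    ("unrelated", "vertical"): (19, 711),
    ("related", "lateral"): (14, 248),
    ("unrelated", "lateral"): (51, 626),
}

#: earlier retroviral-labeling study used as a comparison prediction:
#: sister-cell and control connection rates, clone size 6
PRIOR_STUDY = {"related": (65, 179), "unrelated": (9, 143), "clone_size": 6}


def connection_counts() -> pd.DataFrame:
    """Per-connection-type counts as a tidy frame.

    Columns: relation, pre_layer, post_layer, k (connected), n (tested),
    connection_class ("vertical" if pre != post else "lateral").
    """
    rows = [
        {
            "relation": rel,
            "pre_layer": pre,
            "post_layer": post,
            "k": k,
            "n": n,
            "connection_class": "lateral" if pre == post else "vertical",
        }
        for (rel, pre, post), (k, n) in _COUNTS.items()
    ]
    return pd.DataFrame(rows)


def input_fraction_inputs() -> pd.DataFrame:
    """Related/unrelated count pairs for each input-fraction estimate.

    One row per connection type with k_r/m_r (related connected/tested) and
    k_u/m_u (unrelated), the inputs of the cylinder input-fraction model.
    """
    table = connection_counts()
    wide = table.pivot_table(
        index=["pre_layer", "post_layer", "connection_class"],
        columns="relation",
        values=["k", "n"],
        aggfunc="first",
    )
    out = pd.DataFrame(
        {
            "k_r": wide[("k", "related")],
            "m_r": wide[("n", "related")],
            "k_u": wide[("k", "unrelated")],
            "m_u": wide[("n", "unrelated")],
        }
    ).reset_index()
    return out.dropna().astype({"k_r": int, "m_r": int, "k_u": int, "m_u": int})
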
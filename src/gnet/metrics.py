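"""Novelty difference metrics.

Two stimuli are compared matrix by matrix: each of the nine grid positions
contributes one difference point per matrix (layout, shapes, colors) when the
codes at that position mismatch. Codes are categorical, so a mismatch always
counts 1 regardless of the numeric distance between codes. The total stimulus
difference is the sum over the three matrices (0..27; at most 26 when both
stimuli fill five of nine cells).

From the pairwise difference, three novelty indices are defined per novel
stimulus:

* **DTF** — difference to the corresponding familiar (the base it was
  generated from, or the randomly paired familiar for fully novel stimuli);
* **DTAF** — mean difference to all five familiars;
* **DTAN** — mean difference to all other novels in the pool (99 at the
  default configuration). A same-category-only variant is available via
  ``dtan_same_category_only`` but is not the default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .stimgen import NOVEL_CATEGORIES, Stimulus, StimulusPool

__all__ = [
    "matrix_difference",
    "stimulus_difference",
    "compute_indices",
    "index_correlations",
]


def matrix_difference(a, b) -> int:
    """Count positions where two categorical code vectors differ.

    >>> matrix_difference([1, 0, 0, 1, 1, 1, 0, 0, 1], [0, 1, 0, 1, 1, 1, 0, 1, 0])
    4
    >>> matrix_difference([3, 0, 0, 2, 2, 2, 3, 0, 0], [1, 0, 0, 2, 2, 2, 1, 0, 0])
    2
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"vector length mismatch: {a.shape} vs {b.shape}")
    return int(np.sum(a != b))


def stimulus_difference(s1: Stimulus, s2: Stimulus) -> int:
    """Total difference: layout + shapes + colors positional mismatches."""
    if len(s1.layout) != len(s2.layout):
        raise ValueError("stimuli have different grid sizes")
    return (
        matrix_difference(s1.layout, s2.layout)
        + matrix_difference(s1.shapes, s2.shapes)
        + matrix_difference(s1.colors, s2.colors)
    )


def _pairwise_differences(rows: list[Stimulus], cols: list[Stimulus]) -> np.ndarray:
    """Vectorized stimulus differences between two stimulus lists."""
    A = np.stack([s.as_stack() for s in rows])        # (n, 3*cells)
    B = np.stack([s.as_stack() for s in cols])
    n_cells = len(rows[0].layout)
    neq = A[:, None, :] != B[None, :, :]              # (n, m, 3*cells)
    # Per-matrix mismatches sum to the same total as the flat comparison.
    del n_cells
    return neq.sum(axis=2)


def compute_indices(pool: StimulusPool, *, dtan_same_category_only: bool = False) -> pd.DataFrame:
    """Compute DTF, DTAF and DTAN for every novel in the pool.

    Returns a DataFrame with one row per novel: ``stimulus_id``, ``category``,
    ``base_familiar_id``, ``dtf``, ``dtaf``, ``dtan``.
    """
    novels = pool.novels
    familiars = pool.familiars
    fam_index = {f.id: k for k, f in enumerate(familiars)}

    to_fam = _pairwise_differences(novels, familiars)    # (n_novels, n_fam)
    among = _pairwise_differences(novels, novels)        # (n_novels, n_novels)

    rows = []
    n = len(novels)
    categories = np.array([s.category.value for s in novels])
    for i, s in enumerate(novels):
        if s.base_familiar_id is None or s.base_familiar_id not in fam_index:
            raise ValueError(f"novel {s.id} lacks a base familiar pairing")
        dtf = int(to_fam[i, fam_index[s.base_familiar_id]])
        dtaf = float(to_fam[i].mean())
        if dtan_same_category_only:
            mask = (categories == s.category.value)
        else:
            mask = np.ones(n, dtype=bool)
        mask[i] = False
        dtan = float(among[i, mask].mean())
        rows.append(
            {
                "stimulus_id": s.id,
                "category": s.category.value,
                "base_familiar_id": s.base_familiar_id,
                "dtf": dtf,
                "dtaf": dtaf,
                "dtan": dtan,
            }
        )
    df = pd.DataFrame(rows)
    order = [c.value for c in NOVEL_CATEGORIES]
    df["category"] = pd.Categorical(df["category"], categories=order, ordered=True)
    return df


def index_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among the three indices, across stimuli.

    Returns a DataFrame with rows ``dtf-dtaf``, ``dtf-dtan``, ``dtaf-dtan``
    and columns ``r``, ``n``, ``p`` (two-sided).
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 stimuli to correlate indices")
    out = []
    for x, y in (("dtf", "dtaf"), ("dtf", "dtan"), ("dtaf", "dtan")):
        xv = scores[x].to_numpy(dtype=float)
        yv = scores[y].to_numpy(dtype=float)
        if np.std(xv) == 0 or np.std(yv) == 0:
            raise ValueError(f"zero variance in {x if np.std(xv) == 0 else y}; correlation undefined")
        r, p = stats.pearsonr(xv, yv)
        out.append({"pair": f"{x}-{y}", "r": float(r), "n": len(xv), "p": float(p)})
    return pd.DataFrame(out).set_index("pair")
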
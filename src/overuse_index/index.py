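"""The Overuse Index: Z-score standardization of system effects and categories.

The fitted health-system fixed effects :math:`\\Phi_k` (reference system
included at 0) are standardized across systems,

.. math:: OI_k = (\\Phi_k - \\bar\\Phi) / SD(\\Phi),

with the sample standard deviation (n-1).  By construction the standardized
index has mean 0 and SD 1.  Systems are then placed in 5 categories:

* 1 — more than 1 SD below the mean (``oi < -1``)
* 2 — between -1 and -0.5 SD (``-1 <= oi < -0.5``)
* 3 — within 0.5 SD of the mean (``-0.5 <= oi < 0.5``)
* 4 — between 0.5 and 1 SD (``0.5 <= oi < 1``)
* 5 — more than 1 SD above the mean (``oi >= 1``)

The interval endpoints are half-open as shown (each boundary value belongs to
the upper category).  Category 1 systems use the least
low-value care relative to peers, category 5 the most.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "standardize_index",
    "categorize",
    "OveruseIndexScaler",
    "build_index_table",
    "compare_category_assignments",
]

_CATEGORY_EDGES = np.array([-1.0, -0.5, 0.5, 1.0])


def categorize(oi) -> np.ndarray | int:
    """Overuse category 1..5 for standardized index values."""
    arr = np.asarray(oi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("categorize requires finite index values")
    cat = np.searchsorted(_CATEGORY_EDGES, arr, side="right") + 1
    if np.isscalar(oi) or arr.ndim == 0:
        return int(cat)
    return cat.astype(int)


class OveruseIndexScaler(BaseEstimator, TransformerMixin):
    """Z-score scaler for system fixed effects (sample SD, n-1).

    ``fit`` learns the mean and SD across systems; ``transform`` returns the
    standardized index.  Kept separate from :class:`sklearn.preprocessing`
    scalers because the ddof and degenerate-input contracts here are part of
    the index definition.
    """

    def fit(self, X, y=None):
        phi = np.asarray(X, dtype=float).ravel()
        if len(phi) < 2:
            raise ValueError("at least 2 systems are required to standardize")
        if not np.all(np.isfinite(phi)):
            raise ValueError("system effects must be finite")
        sd = phi.std(ddof=1)
        if sd == 0.0:
            raise ValueError("system effects are constant; the index is undefined")
        self.mean_ = float(phi.mean())
        self.scale_ = float(sd)
        self.n_systems_ = len(phi)
        return self

    def transform(self, X):
        phi = np.asarray(X, dtype=float).ravel()
        return (phi - self.mean_) / self.scale_

    def categories(self, X) -> np.ndarray:
        return categorize(self.transform(X))


def standardize_index(phi) -> np.ndarray:
    """Standardized Overuse Index for a vector of system effects."""
    return OveruseIndexScaler().fit(phi).transform(phi)


def build_index_table(system_effects: pd.Series) -> pd.DataFrame:
    """Index table: system_id, raw Phi, standardized OI, category 1-5."""
    phi = system_effects.to_numpy(dtype=float)
    oi = standardize_index(phi)
    return pd.DataFrame(
        {
            "system_id": system_effects.index,
            "raw_phi": phi,
            "oi": oi,
            "category": categorize(oi),
        }
    )


def compare_category_assignments(run_a: pd.DataFrame, run_b: pd.DataFrame):
    """Category shifts between two index runs (e.g. a sensitivity analysis).

    Returns ``(shift_counts, detail)``: counts of systems changing by 0, 1,
    2+ categories over the common systems, and a per-system table.  Systems
    present in only one run are ignored (callers may log them).
    """
    a = run_a.set_index("system_id")["category"]
    b = run_b.set_index("system_id")["category"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("the two runs share no systems")
    detail = pd.DataFrame(
        {
            "system_id": common,
            "category_a": a.loc[common].to_numpy(),
            "category_b": b.loc[common].to_numpy(),
        }
    )
    detail["abs_shift"] = np.abs(detail["category_a"] - detail["category_b"])
    binned = np.minimum(detail["abs_shift"], 2)
    counts = {
        "shift_0": int((binned == 0).sum()),
        "shift_1": int((binned == 1).sum()),
        "shift_2_plus": int((binned == 2).sum()),
        "n_common": int(len(common)),
        "n_only_a": int(len(a.index.difference(b.index))),
        "n_only_b": int(len(b.index.difference(a.index))),
    }
    return counts, detail
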
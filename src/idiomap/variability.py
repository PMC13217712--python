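"""Correlational-distance idiosyncrasy metrics.

The distance between two participants' activation vectors is
``1 - Pearson r``; a participant's *variability* is their mean distance to
a reference set:

* whole  — every other participant in the sample;
* within — other members of the participant's binary diagnostic group
  (control vs autistic, not the IQ subgroups);
* tdc    — members of the control group (self excluded when the
  participant is a control).

Higher variability means a more idiosyncratic whole-brain pattern.  The
self-distance (exactly 0) is excluded from every average.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "VariabilityError",
    "correlational_distance",
    "distance_matrix",
    "variability_scores",
    "SCHEMES",
]

SCHEMES = ("whole", "within", "tdc")


class VariabilityError(ValueError):
    """Invalid input to a variability computation."""


def correlational_distance(v1, v2) -> float:
    """1 - Pearson correlation between two activation vectors.

    Ranges over [0, 2]: 0 for perfectly correlated patterns, 2 for
    perfectly anticorrelated ones.
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise VariabilityError("vectors must be 1-D and of equal length")
    if a.size < 3:
        raise VariabilityError("vectors must have length >= 3")
    for name, v in (("first", a), ("second", b)):
        if np.allclose(v.std(), 0.0):
            raise VariabilityError(f"{name} vector has zero variance")
    r = np.corrcoef(a, b)[0, 1]
    return float(1.0 - r)


def distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric participant x participant correlational distances."""
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        ids = list(range(X.shape[0]))
    if X.shape[0] < 2:
        raise VariabilityError("need at least 2 participants")
    if np.any(np.isnan(X)):
        raise VariabilityError("activation matrix contains NaN cells")
    sds = X.std(axis=1)
    flat = np.flatnonzero(np.isclose(sds, 0.0))
    if flat.size:
        raise VariabilityError(
            f"zero-variance activation vector for participants "
            f"{[ids[i] for i in flat]}")
    D = 1.0 - np.corrcoef(X)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=pd.Index(ids, name="id"), columns=ids)


def variability_scores(distmat: pd.DataFrame,
                       phenotype: pd.DataFrame | None = None,
                       schemes=SCHEMES) -> pd.DataFrame:
    """Per-participant variability under the requested reference schemes.

    Returns a frame indexed by id with one ``variability_<scheme>`` column
    and one ``n_ref_<scheme>`` reference-set-size column per scheme.
    """
    schemes = tuple(schemes)
    for s in schemes:
        if s not in SCHEMES:
            raise VariabilityError(f"unknown scheme {s!r}")
    ids = list(distmat.index)
    D = distmat.to_numpy(dtype=float)
    n = len(ids)

    need_groups = any(s in ("within", "tdc") for s in schemes)
    if need_groups:
        if phenotype is None:
            raise VariabilityError(
                "phenotype table required for within/tdc schemes")
        pheno = phenotype.set_index("id").loc[ids]
        diag = pheno["diagnostic_group"].to_numpy()

    out = pd.DataFrame(index=pd.Index(ids, name="id"))
    self_mask = np.eye(n, dtype=bool)
    for scheme in schemes:
        if scheme == "whole":
            ref = ~self_mask
        elif scheme == "within":
            same = diag[:, None] == diag[None, :]
            ref = same & ~self_mask
        else:  # tdc
            is_tdc = diag == "TDC"
            ref = np.broadcast_to(is_tdc[None, :], (n, n)) & ~self_mask
        sizes = ref.sum(axis=1)
        if np.any(sizes < 1):
            bad = [ids[i] for i in np.flatnonzero(sizes < 1)]
            raise VariabilityError(
                f"empty reference set under scheme {scheme!r} for {bad}")
        scores = np.where(ref, D, 0.0).sum(axis=1) / sizes
        out[f"variability_{scheme}"] = scores
        out[f"n_ref_{scheme}"] = sizes
    return out
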
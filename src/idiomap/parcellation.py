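"""Label-atlas parcellation of statistic maps and motion-based exclusion.

A participant's 3-D statistic map is reduced to a 1 x K vector of
per-parcel means through an integer label image (0 = background), and the
per-participant vectors are stacked into a participant x ROI matrix
aligned with the phenotype table.  Also implements the iterative
mean-framewise-displacement exclusion rule (drop anyone above
mean + 2 SD of the retained set, recompute until stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Atlas",
    "AtlasError",
    "validate_atlas",
    "parcellate_map",
    "assemble_matrix",
    "apply_fd_exclusion",
]


class AtlasError(ValueError):
    """Invalid atlas or parcellation input."""


@dataclass(frozen=True)
class Atlas:
    """Validated integer label image with contiguous labels 1..K."""

    data: np.ndarray
    labels: np.ndarray
    voxel_counts: np.ndarray
    provenance: str = ""

    @property
    def n_labels(self) -> int:
        return int(len(self.labels))


def _as_array(image) -> np.ndarray:
    if hasattr(image, "get_fdata"):
        return np.asarray(image.get_fdata())
    return np.asarray(image)


def validate_atlas(image, relabel: bool = False,
                   provenance: str = "") -> Atlas:
    """Check a label image and return an :class:`Atlas`.

    Labels must be non-negative integers; nonzero labels must be the
    contiguous range 1..K unless ``relabel`` is set, in which case gaps
    are closed by rank-relabelling.
    """
    data = _as_array(image)
    if not np.allclose(data, np.rint(data)):
        raise AtlasError("atlas voxels must be integer-valued")
    data = np.rint(data).astype(np.int32)
    if data.min() < 0:
        raise AtlasError("atlas contains negative labels")
    labels = np.unique(data)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise AtlasError("atlas has empty foreground")
    expected = np.arange(1, labels.size + 1)
    if not np.array_equal(labels, expected):
        if relabel:
            lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
            lut[labels] = expected
            data = lut[data]
            labels = expected
        else:
            missing = sorted(set(expected.tolist()) - set(labels.tolist()))
            raise AtlasError(
                f"labels are not contiguous 1..{labels.size}; missing "
                f"{missing} (pass relabel=True to close gaps)")
    counts = np.bincount(data.ravel(), minlength=labels.size + 1)[1:]
    return Atlas(data=data, labels=labels, voxel_counts=counts,
                 provenance=provenance)


def parcellate_map(stat_map, atlas: Atlas) -> np.ndarray:
    """Per-parcel arithmetic mean of the statistic map: a 1 x K vector."""
    values = _as_array(stat_map).astype(float)
    if values.shape != atlas.data.shape:
        raise AtlasError(
            f"map grid {values.shape} does not match atlas {atlas.data.shape}")
    nan_per_label = ndimage.sum(np.isnan(values), labels=atlas.data,
                                index=atlas.labels)
    bad = atlas.labels[np.asarray(nan_per_label) > 0]
    if bad.size:
        raise AtlasError(f"NaN voxels inside parcels {bad.tolist()[:10]}")
    vec = ndimage.mean(values, labels=atlas.data, index=atlas.labels)
    return np.asarray(vec, dtype=float)


def assemble_matrix(vectors: dict[str, np.ndarray],
                    phenotype: pd.DataFrame) -> pd.DataFrame:
    """Stack per-participant vectors into a participant x ROI frame.

    Row order follows the phenotype table's ``id`` column exactly.
    """
    ids = list(phenotype["id"])
    missing = [i for i in ids if i not in vectors]
    extra = [i for i in vectors if i not in set(ids)]
    if missing or extra:
        raise AtlasError(
            f"vector/phenotype id mismatch; missing vectors for {missing}, "
            f"unexpected vectors for {extra}")
    lengths = {len(np.asarray(v)) for v in vectors.values()}
    if len(lengths) != 1:
        raise AtlasError(f"vectors have differing lengths {sorted(lengths)}")
    k = lengths.pop()
    mat = np.vstack([np.asarray(vectors[i], dtype=float) for i in ids])
    return pd.DataFrame(mat, index=pd.Index(ids, name="id"),
                        columns=[f"roi_{j + 1}" for j in range(k)])


def apply_fd_exclusion(fd_values: pd.Series | dict | np.ndarray,
                       n_sd: float = 2.0):
    """Iterative head-motion exclusion.

    Repeatedly removes participants whose mean FD exceeds
    mean + ``n_sd`` * SD of the *currently retained* values, recomputing
    the threshold after each pass until no further removal occurs.
    Returns (kept ids, excluded ids, final threshold).
    """
    if isinstance(fd_values, dict):
        fd = pd.Series(fd_values, dtype=float)
    elif isinstance(fd_values, pd.Series):
        fd = fd_values.astype(float)
    else:
        arr = np.asarray(fd_values, dtype=float)
        fd = pd.Series(arr, index=pd.RangeIndex(len(arr)))
    if len(fd) < 3:
        raise AtlasError("need at least 3 FD values for the exclusion rule")

    kept = fd.copy()
    while True:
        thr = kept.mean() + n_sd * kept.std(ddof=1)
        out = kept[kept > thr]
        if out.empty:
            break
        kept = kept[kept <= thr]
        if len(kept) < 3:
            break
    excluded = fd.index.difference(kept.index)
    return list(kept.index), list(excluded), float(thr)
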
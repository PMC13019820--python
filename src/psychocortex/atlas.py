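"""Synthetic cortical parcellation with HCP-MMP1.0-like bookkeeping.

The atlas places parcels on two unit hemispheres via a deterministic
low-discrepancy spiral and labels each parcel with one of Mesulam's four
laminar-differentiation classes and one of Yeo's seven intrinsic-connectivity
networks, assigned in contiguous bands along the anterior-posterior axis.
Real surface meshes are deliberately out of scope: spin permutation and
partition contrasts only require plausible spherical geometry and a full
labelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_rng

MESULAM_CLASSES = ("idiotypic", "unimodal", "heteromodal", "paralimbic")
#: posterior-to-anterior band proportions
MESULAM_PROPORTIONS = {
    "idiotypic": 0.12,
    "unimodal": 0.36,
    "heteromodal": 0.40,
    "paralimbic": 0.12,
}

YEO_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)
YEO_PROPORTIONS = {
    "visual": 0.15,
    "somatomotor": 0.18,
    "dorsal_attention": 0.12,
    "ventral_attention": 0.12,
    "limbic": 0.10,
    "frontoparietal": 0.15,
    "default_mode": 0.18,
}

_ATLAS_COLUMNS = [
    "parcel_id",
    "name",
    "hemisphere",
    "x",
    "y",
    "z",
    "ap_axis",
    "mesulam_class",
    "yeo_network",
]


@dataclass(frozen=True)
class ParcelAtlas:
    """Parcel metadata table: spherical centroids plus partition labels.

    ``table`` has one row per parcel with columns parcel_id, name,
    hemisphere ({L, R}), x/y/z unit-sphere centroid coordinates, ap_axis
    (anterior-posterior position in [-1, 1], +1 anterior), mesulam_class
    and yeo_network.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _ATLAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"atlas table missing columns {missing}")
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("parcel centroids must lie on the unit sphere")

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def names(self) -> np.ndarray:
        return self.table["name"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def hemisphere(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def ap_axis(self) -> np.ndarray:
        return self.table["ap_axis"].to_numpy(dtype=float)

    @property
    def mesulam_class(self) -> np.ndarray:
        return self.table["mesulam_class"].to_numpy()

    @property
    def yeo_network(self) -> np.ndarray:
        return self.table["yeo_network"].to_numpy()

    def labels(self, partition: str) -> np.ndarray:
        """Return the per-parcel labels for ``partition`` in {class, network}."""
        if partition in ("class", "mesulam", "mesulam_class"):
            return self.mesulam_class
        if partition in ("network", "yeo", "yeo_network"):
            return self.yeo_network
        raise ValueError(f"unknown partition {partition!r}")

    def mask(self, partition: str, label: str) -> np.ndarray:
        return self.labels(partition) == label

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "ParcelAtlas":
        return cls(pd.read_csv(path, sep="\t"))


def _banded_labels(ap: np.ndarray, proportions: dict[str, float]) -> np.ndarray:
    """Assign labels in contiguous anterior-posterior bands.

    Bands run posterior (low ap) to anterior following the key order of
    ``proportions``; every label receives at least one parcel.
    """
    n = len(ap)
    labels = list(proportions)
    counts = np.maximum(1, np.floor(np.array([proportions[c] for c in labels]) * n)).astype(int)
    # distribute the remainder by largest fractional part
    while counts.sum() < n:
        frac = np.array([proportions[c] for c in labels]) * n - counts
        counts[np.argmax(frac)] += 1
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    order = np.argsort(ap, kind="stable")
    out = np.empty(n, dtype=object)
    start = 0
    for lab, cnt in zip(labels, counts):
        out[order[start : start + cnt]] = lab
        start += cnt
    return out.astype(str)


def make_parcellation(n_parcels: int = 360, seed: int = 0) -> ParcelAtlas:
    """Build a two-hemisphere spherical parcellation with partition labels.

    Parcels are spread over each hemispheric half-sphere (left: x < 0,
    right: x > 0, mirror-symmetric) by a golden-angle spiral, which is
    deterministic up to a seed-dependent azimuthal offset. The y axis is
    anterior-posterior; ``ap_axis`` is y rescaled so the most posterior
    parcel sits at -1 and the most anterior at +1.

    Parameters
    ----------
    n_parcels : int
        Total parcel count; must be even and at least 8. The default 360
        mirrors the HCP-MMP1.0 multimodal parcellation (180 per hemisphere).
    seed : int
        Controls only the spiral's azimuthal phase.
    """
    if n_parcels % 2 != 0 or n_parcels < 8:
        raise ValueError("n_parcels must be even and >= 8")
    rng = as_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    n_hemi = n_parcels // 2
    golden = np.pi * (3.0 - np.sqrt(5.0))

    # each hemisphere occupies its own full registration sphere (as in
    # surface-based spherical registration); right mirrors left in x
    k = np.arange(n_hemi)
    z = -1.0 + 2.0 * (k + 0.5) / n_hemi  # inferior-superior
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = (phase + k * golden) % (2.0 * np.pi)
    y = r * np.cos(theta)  # anterior-posterior
    x = -r * np.sin(theta)
    left = np.column_stack([x, y, z])
    right = left * np.array([-1.0, 1.0, 1.0])  # mirror in x

    centroids = np.vstack([left, right])
    hemi = np.array(["L"] * n_hemi + ["R"] * n_hemi)
    y_all = centroids[:, 1]
    span = np.max(np.abs(y_all))
    ap = y_all / span if span > 0 else y_all

    table = pd.DataFrame(
        {
            "parcel_id": np.arange(n_parcels),
            "name": [f"{h}_P{(i % n_hemi) + 1:03d}_ROI" for i, h in enumerate(hemi)],
            "hemisphere": hemi,
            "x": centroids[:, 0],
            "y": centroids[:, 1],
            "z": centroids[:, 2],
            "ap_axis": ap,
            "mesulam_class": _banded_labels(ap, MESULAM_PROPORTIONS),
            "yeo_network": _banded_labels(ap, YEO_PROPORTIONS),
        }
    )
    return ParcelAtlas(table)
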
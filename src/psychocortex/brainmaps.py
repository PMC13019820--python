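"""Parcel-wise brain-behavior mapping and its downstream summaries.

``map_association`` fits one robust regression per parcel (morphometry ~
predictor + covariates; age and IQ for cortical thickness, plus total
intracranial volume for surface area), collects the predictor's
standardized beta and p-value, and applies Benjamini-Hochberg FDR across
parcels within the map. Effect sizes are then contrasted across Mesulam
classes or Yeo networks with pairwise rank-sum tests (Bonferroni factor 6
or 21), and significant-parcel sets are scored for overlap with binary
meta-analytic-style masks via intersection size, coverage, and Dice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .cohort import MorphometryMatrix
from .robust import robust_fit
from .stats import fdr_bh, ranksum_test

DEFAULT_COVARIATES = {"CT": ("age", "iq"), "SA": ("age", "iq", "tiv")}


@dataclass
class EffectMap:
    """Per-parcel standardized betas with FDR-adjusted significance.

    ``table`` columns: parcel_id, name, beta_z, p, q, significant.
    """

    table: pd.DataFrame
    index_kind: str
    predictor: str

    @property
    def beta_z(self) -> np.ndarray:
        return self.table["beta_z"].to_numpy()

    @property
    def significant(self) -> np.ndarray:
        return self.table["significant"].to_numpy(dtype=bool)

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def map_association(
    morphometry: MorphometryMatrix,
    predictor: pd.Series,
    covariates=None,
    *,
    atlas: ParcelAtlas | None = None,
    extra_covariates=(),
    q_level: float = 0.05,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> EffectMap:
    """Robust parcel-wise association map with per-map FDR correction.

    ``predictor`` must be indexed by subject_id; subjects missing the
    predictor or any covariate are dropped listwise. FDR is applied across
    all parcels of this single map.
    """
    if covariates is None:
        covariates = DEFAULT_COVARIATES[morphometry.index_kind]
    covariates = list(covariates) + list(extra_covariates)

    if not predictor.index.isin(morphometry.values.index).all():
        raise ValueError("predictor subjects do not align with morphometry")
    cov = morphometry.covariates.loc[predictor.index, covariates]
    design = pd.concat([predictor.rename("_pred"), cov], axis=1).dropna()
    if len(design) < len(covariates) + 4:
        raise ValueError("too few complete subjects for the association map")
    X = design.to_numpy(float)
    Y = morphometry.values.loc[design.index].to_numpy(float)

    betas = np.empty(Y.shape[1])
    ps = np.empty(Y.shape[1])
    names = ["_pred"] + covariates
    cache: dict[bytes, tuple[float, float]] = {}
    for j in range(Y.shape[1]):
        key = Y[:, j].tobytes()
        if key in cache:
            betas[j], ps[j] = cache[key]
            continue
        res = robust_fit(Y[:, j], X, max_iter=max_iter, tol=tol, exog_names=names)
        betas[j] = res.beta_z[0]
        ps[j] = res.pvalues[1]
        cache[key] = (betas[j], ps[j])

    q, reject = fdr_bh(ps, q_level=q_level)
    atlas_names = (
        atlas.names if atlas is not None else morphometry.values.columns.to_numpy()
    )
    table = pd.DataFrame(
        {
            "parcel_id": np.arange(Y.shape[1]),
            "name": atlas_names,
            "beta_z": betas,
            "p": ps,
            "q": q,
            "significant": reject,
        }
    )
    return EffectMap(table, morphometry.index_kind, str(predictor.name))


def compare_by_partition(
    effect_map: EffectMap | np.ndarray,
    atlas: ParcelAtlas,
    partition: str,
) -> dict:
    """Median-ordered partition contrast of parcel-level effect sizes.

    Groups beta_z by Mesulam class or Yeo network, reports medians sorted
    descending, and Bonferroni-corrects all pairwise rank-sum p-values by
    the number of comparisons (6 for 4 classes, 21 for 7 networks).
    Parcels are treated as exchangeable units.
    """
    beta = (
        effect_map.beta_z if isinstance(effect_map, EffectMap) else np.asarray(effect_map)
    )
    labels = atlas.labels(partition)
    if pd.isna(labels).any():
        raise ValueError("every parcel must carry a partition label")
    uniq = sorted(set(labels))
    k = len(uniq)
    bonferroni = k * (k - 1) // 2

    medians = {lab: float(np.median(beta[labels == lab])) for lab in uniq}
    ordered = sorted(uniq, key=lambda lab: medians[lab], reverse=True)

    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = uniq[i], uniq[j]
            stat, p = ranksum_test(beta[labels == a], beta[labels == b])
            pairwise.append(
                {
                    "label_a": a,
                    "label_b": b,
                    "statistic": stat,
                    "p": p,
                    "p_bonferroni": min(1.0, p * bonferroni),
                }
            )
    return {
        "partition": partition,
        "medians": medians,
        "order": ordered,
        "n_comparisons": bonferroni,
        "pairwise": pairwise,
    }


def overlap_with_masks(significant, masks: dict, n_parcels: int | None = None) -> pd.DataFrame:
    """Overlap of a significant-parcel set with binary parcel masks.

    For each mask returns the intersection size, the proportion of the
    significant set covered, and the Dice coefficient 2|A∩B|/(|A|+|B|).
    Mask variants (baseline / preferential / unique) are simply supplied as
    separate entries.
    """
    sig = np.asarray(significant, dtype=bool)
    if n_parcels is None:
        n_parcels = sig.size
    if sig.size != n_parcels:
        raise ValueError("significant set does not match the atlas size")
    rows = []
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.size != n_parcels:
            raise ValueError(f"mask {name!r} does not match the atlas size")
        inter = int(np.sum(sig & mask))
        n_sig, n_mask = int(sig.sum()), int(mask.sum())
        rows.append(
            {
                "mask": name,
                "n_mask": n_mask,
                "n_significant": n_sig,
                "n_intersection": inter,
                "prop_significant_covered": inter / n_sig if n_sig else 0.0,
                "dice": 2.0 * inter / (n_sig + n_mask) if (n_sig + n_mask) else 0.0,
            }
        )
    return pd.DataFrame(rows)
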
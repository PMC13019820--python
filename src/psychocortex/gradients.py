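"""Structural-covariance gradients: construction, alignment, compression.

A structural-covariance matrix correlates a morphometric index (cortical
thickness or surface area, covariate-residualized) between every pair of
parcels across subjects. Its macroscale organization is extracted by
diffusion-map embedding of a sparsified normalized-angle affinity matrix:
the leading non-trivial eigenvectors ("gradients") order parcels along
axes such as anterior-posterior. Group-specific gradients are aligned to a
template by orthogonal Procrustes so loadings are directly comparable, and
"compression" — a smaller loading range, the distribution pulled toward
the center — is quantified globally by a two-sample Kolmogorov-Smirnov
test on the parcel loadings and locally by signed-rank tests per Mesulam
class or Yeo network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .atlas import ParcelAtlas
from .cohort import MorphometryMatrix
from .brainmaps import DEFAULT_COVARIATES
from .prediction import _residualize
from .stats import ks_2samp, signedrank_test

DEFAULT_SPARSITY = 0.9
DEFAULT_ALPHA = 0.5
DEFAULT_N_COMPONENTS = 10


@dataclass
class GradientSet:
    """Parcel loadings for the retained gradients of one sample.

    loadings is (n_parcels, n_components), components ordered by
    decreasing eigenvalue; variance_explained are the scaled eigenvalues
    (normalized magnitudes over retained components). ``aligned_to`` names
    the alignment template, or None for raw gradients.
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    label: str = "sample"
    aligned_to: str | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def component(self, k: int = 0) -> np.ndarray:
        return self.loadings[:, k]

    def truncate(self, k: int) -> "GradientSet":
        """Restrict to the leading ``k`` components."""
        if not 1 <= k <= self.n_components:
            raise ValueError("k outside available components")
        return GradientSet(
            loadings=self.loadings[:, :k],
            eigenvalues=self.eigenvalues[:k],
            variance_explained=self.variance_explained[:k],
            label=self.label,
            aligned_to=self.aligned_to,
            params=dict(self.params),
        )

    def to_frame(self, atlas: ParcelAtlas | None = None) -> pd.DataFrame:
        cols = {f"g{k + 1}": self.loadings[:, k] for k in range(self.n_components)}
        df = pd.DataFrame(cols)
        if atlas is not None:
            df.insert(0, "parcel_id", atlas.table["parcel_id"].to_numpy())
            df.insert(1, "name", atlas.names)
        return df


def structural_covariance(residualized: np.ndarray) -> np.ndarray:
    """Parcel x parcel Pearson correlation across subjects.

    Input rows are subjects, columns covariate-residualized parcel values.
    A zero-variance parcel keeps a unit diagonal but zero off-diagonal
    entries (flagged by a warning-free convention rather than an error).
    """
    X = np.asarray(residualized, float)
    if X.shape[0] < 30:
        raise ValueError("structural covariance needs >= 30 subjects")
    sd = X.std(axis=0)
    degenerate = sd == 0
    Xs = (X - X.mean(axis=0)) / np.where(degenerate, 1.0, sd)
    C = (Xs.T @ Xs) / X.shape[0]
    C[degenerate, :] = 0.0
    C[:, degenerate] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip((C + C.T) / 2.0, -1.0, 1.0)


def build_affinity(corr: np.ndarray, sparsity: float = DEFAULT_SPARSITY) -> np.ndarray:
    """Row-sparsified normalized-angle affinity between parcel profiles.

    Per row, only the top (1 - sparsity) fraction of entries is retained
    (negatives always dropped); affinity between retained row profiles is
    the normalized angle 1 - arccos(cosine similarity)/pi, in [0, 1].
    """
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    C = np.asarray(corr, float)
    p = C.shape[0]
    keep = max(1, int(round((1.0 - sparsity) * p)))
    R = np.where(C > 0, C, 0.0)
    if keep < p:
        thresh_idx = np.argpartition(C, p - keep, axis=1)[:, : p - keep]
        rows = np.arange(p)[:, None]
        mask = np.ones_like(C, dtype=bool)
        mask[rows, thresh_idx] = False
        R = np.where(mask, R, 0.0)
    norms = np.linalg.norm(R, axis=1)
    if np.any(norms == 0):
        bad = np.where(norms == 0)[0]
        raise ValueError(f"parcels {bad.tolist()} have all-zero sparsified rows")
    cos = np.clip((R @ R.T) / np.outer(norms, norms), -1.0, 1.0)
    A = 1.0 - np.arccos(cos) / np.pi
    return (A + A.T) / 2.0


def _orient_sign(vec: np.ndarray, reference: np.ndarray | None) -> float:
    if reference is not None:
        r = np.corrcoef(vec, reference)[0, 1]
        if np.isfinite(r) and r != 0:
            return np.sign(r)
    return np.sign(vec[np.argmax(np.abs(vec))]) or 1.0


def diffusion_embedding(
    affinity: np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
    alpha: float = DEFAULT_ALPHA,
    *,
    orient_to: np.ndarray | None = None,
    label: str = "sample",
) -> GradientSet:
    """Diffusion-map embedding of a symmetric non-negative affinity matrix.

    Density-normalizes by degree to the power ``alpha`` (0.5 by default,
    halfway between graph Laplacian and Laplace-Beltrami), row-normalizes
    to a Markov transition operator, eigendecomposes, drops the trivial
    stationary eigenvector, and returns eigenvectors scaled by their
    eigenvalues. Components are deterministically sign-oriented: positively
    correlated with ``orient_to`` when given (e.g. the anterior-posterior
    axis), otherwise so their largest-magnitude loading is positive.
    """
    W = np.asarray(affinity, float)
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if (W < 0).any():
        raise ValueError("affinity must be non-negative")
    n_comp_graph, labels = connected_components(W > 0, directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"affinity graph has {n_comp_graph} components, sizes {sizes}")

    d = W.sum(axis=1)
    W1 = W / np.outer(d**alpha, d**alpha)
    d1 = W1.sum(axis=1)
    S = W1 / np.outer(np.sqrt(d1), np.sqrt(d1))
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the trivial (stationary) component, keep the next n_components
    evals, evecs = evals[1 : n_components + 1], evecs[:, 1 : n_components + 1]
    psi = evecs / np.sqrt(d1)[:, None]
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    loadings = psi * evals[None, :]
    for k in range(loadings.shape[1]):
        loadings[:, k] *= _orient_sign(loadings[:, k], orient_to)
    mags = np.abs(evals)
    variance_explained = mags / mags.sum() if mags.sum() > 0 else mags
    return GradientSet(
        loadings=loadings,
        eigenvalues=evals,
        variance_explained=variance_explained,
        label=label,
        params={"alpha": alpha, "n_components": n_components},
    )


def procrustes_align(source: GradientSet, template: GradientSet) -> GradientSet:
    """Align source loadings to a template by orthogonal Procrustes.

    Columns are centered, the orthogonal transform minimizing the Frobenius
    distance is found by SVD of the cross-product (no scaling), and the
    template's column means are restored — so aligning a set to itself is
    the identity.
    """
    if source.loadings.shape != template.loadings.shape:
        raise ValueError("source and template must share shape")
    S = source.loadings - source.loadings.mean(axis=0)
    T = template.loadings - template.loadings.mean(axis=0)
    R, _ = orthogonal_procrustes(S, T)
    aligned = S @ R + template.loadings.mean(axis=0)
    return GradientSet(
        loadings=aligned,
        eigenvalues=source.eigenvalues,
        variance_explained=source.variance_explained,
        label=source.label,
        aligned_to=template.label,
        params=dict(source.params, rotation=R),
    )


@dataclass
class CompressionResult:
    """Global gradient-compression statistics for high vs low groups."""

    component: int
    ks_D: float
    ks_p: float
    range_low: float
    range_high: float

    @property
    def range_ratio(self) -> float:
        return self.range_high / self.range_low

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "ks_D": self.ks_D,
            "ks_p": self.ks_p,
            "range_low": self.range_low,
            "range_high": self.range_high,
            "range_ratio": self.range_ratio,
        }


def compression_stats(
    aligned_low: GradientSet, aligned_high: GradientSet, component: int = 0
) -> CompressionResult:
    """Two-sample KS test and loading-range ratio on one aligned component."""
    if aligned_low.aligned_to is None or aligned_high.aligned_to is None:
        raise ValueError("both gradient sets must be aligned to a template")
    if aligned_low.aligned_to != aligned_high.aligned_to:
        raise ValueError("gradient sets aligned to different templates")
    lo = aligned_low.component(component)
    hi = aligned_high.component(component)
    if np.array_equal(lo, hi):
        D, p = 0.0, 1.0
    else:
        D, p = ks_2samp(lo, hi)
    return CompressionResult(
        component=component,
        ks_D=D,
        ks_p=p,
        range_low=float(np.ptp(lo)),
        range_high=float(np.ptp(hi)),
    )


def partition_compression(
    aligned_low: GradientSet,
    aligned_high: GradientSet,
    atlas: ParcelAtlas,
    partition: str,
    component: int = 0,
    min_parcels: int = 5,
) -> dict:
    """Class/network-level compression of one aligned gradient component.

    Per label: a paired signed-rank test on (high - low) parcel loadings,
    Bonferroni-corrected by the number of tested labels (4 classes or 7
    networks), and a compression-oriented flag — the high-group label
    median lies strictly closer to its group's center (the median across
    label medians) than the low-group label median does to its own center.
    Labels with fewer than ``min_parcels`` parcels are excluded as unstable.
    """
    if aligned_low.aligned_to is None or aligned_high.aligned_to is None:
        raise ValueError("both gradient sets must be aligned to a template")
    lo = aligned_low.component(component)
    hi = aligned_high.component(component)
    labels = atlas.labels(partition)
    uniq = [
        lab for lab in sorted(set(labels)) if np.sum(labels == lab) >= min_parcels
    ]
    excluded = sorted(set(labels) - set(uniq))
    factor = len(uniq)

    med_lo = {lab: float(np.median(lo[labels == lab])) for lab in uniq}
    med_hi = {lab: float(np.median(hi[labels == lab])) for lab in uniq}
    center_lo = float(np.median(list(med_lo.values())))
    center_hi = float(np.median(list(med_hi.values())))

    results = []
    for lab in uniq:
        sel = labels == lab
        diffs = hi[sel] - lo[sel]
        try:
            stat, p = signedrank_test(diffs)
        except ValueError:
            stat, p = np.nan, np.nan
        compression_oriented = abs(med_hi[lab] - center_hi) < abs(
            med_lo[lab] - center_lo
        )
        results.append(
            {
                "label": lab,
                "n_parcels": int(sel.sum()),
                "median_low": med_lo[lab],
                "median_high": med_hi[lab],
                "statistic": stat,
                "p": p,
                "p_bonferroni": min(1.0, p * factor) if np.isfinite(p) else np.nan,
                "compression_oriented": bool(compression_oriented),
            }
        )
    return {
        "partition": partition,
        "component": component,
        "n_tests": factor,
        "center_low": center_lo,
        "center_high": center_hi,
        "excluded_labels": excluded,
        "per_label": results,
    }


class StructuralCovarianceGradients:
    """Gradient analysis of one morphometric index across psychopathy groups.

    Builds the template gradients from all subjects, group-specific
    gradients from group-specific residualization, aligns the groups to the
    template, and quantifies global and partition-level compression.

    ``n_align`` caps the subspace entering the Procrustes alignment (the
    leading components): with the flat eigenvalue spectra typical of
    structural-covariance affinities, aligning many near-degenerate
    components lets the orthogonal fit absorb genuine group differences in
    the primary gradient. The default aligns only the component under
    comparison (the primary gradient), reducing the transform to sign and
    offset matching.
    """

    def __init__(
        self,
        morphometry: MorphometryMatrix,
        groups: pd.Series,
        *,
        atlas: ParcelAtlas | None = None,
        covariates=None,
        n_components: int = DEFAULT_N_COMPONENTS,
        n_align: int = 1,
        sparsity: float = DEFAULT_SPARSITY,
        alpha: float = DEFAULT_ALPHA,
    ):
        self.morphometry = morphometry
        self.groups = groups.loc[morphometry.values.index]
        self.atlas = atlas
        self.covariate_names = list(
            covariates
            if covariates is not None
            else DEFAULT_COVARIATES[morphometry.index_kind]
        )
        self.n_components = n_components
        self.n_align = min(n_align, n_components)
        self.sparsity = sparsity
        self.alpha = alpha

    def _embed(self, subject_mask: np.ndarray, label: str, orient_to=None) -> GradientSet:
        X = self.morphometry.values.to_numpy(float)[subject_mask]
        cov = self.morphometry.covariates[self.covariate_names].to_numpy(float)[
            subject_mask
        ]
        resid = _residualize(X, cov)
        C = structural_covariance(resid)
        A = build_affinity(C, self.sparsity)
        return diffusion_embedding(
            A, self.n_components, self.alpha, orient_to=orient_to, label=label
        )

    def fit(self, component: int = 0) -> "GradientResults":
        orient = self.atlas.ap_axis if self.atlas is not None else None
        n = self.morphometry.n_subjects
        template = self._embed(np.ones(n, dtype=bool), "total", orient_to=orient)
        aligned = {}
        align_template = template.truncate(self.n_align)
        for group in ("low", "high"):
            mask = (self.groups == group).to_numpy()
            if mask.sum() >= 30:
                raw = self._embed(mask, group, orient_to=template.component(0))
                aligned[group] = procrustes_align(
                    raw.truncate(self.n_align), align_template
                )
        compression = None
        partition = {}
        if "low" in aligned and "high" in aligned:
            compression = compression_stats(
                aligned["low"], aligned["high"], component
            )
            if self.atlas is not None:
                for part in ("class", "network"):
                    partition[part] = partition_compression(
                        aligned["low"], aligned["high"], self.atlas, part, component
                    )
        return GradientResults(
            index_kind=self.morphometry.index_kind,
            template=template,
            aligned=aligned,
            compression=compression,
            partition=partition,
        )


@dataclass
class GradientResults:
    """Results bundle from :class:`StructuralCovarianceGradients`."""

    index_kind: str
    template: GradientSet
    aligned: dict
    compression: CompressionResult | None
    partition: dict

    def summary(self) -> pd.Series:
        out = {
            "index": self.index_kind,
            "template_var_explained_g1": self.template.variance_explained[0],
        }
        if self.compression is not None:
            out.update(self.compression.to_dict())
        return pd.Series(out)
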
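"""Synthetic cohort generator.

Emulates the statistical structure a forensic morphometry study assumes,
without any imaging data: a 360-parcel atlas, subject x parcel cortical
thickness (CT, mm) and surface area (SA, mm^2) matrices whose inter-parcel
correlation follows an anterior-posterior gradient, group-specific
compression of that covariance, positive SA group effects concentrated in
paralimbic/somatomotor cortex, age/IQ/TIV covariate effects, and integer
psychometric scores (PCL-R items 0-2, IRI items 0-4) whose factor structure
links interpersonal/affective psychopathy (F1) negatively to empathic
concern (IRI-EC) and lifestyle/antisocial psychopathy (F2) negatively to
perspective taking (IRI-PT).

Everything is reproducible from a single seed expanded into fixed per-stage
child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import as_rng, child_seed
from .atlas import ParcelAtlas, make_parcellation

#: 0-based indices of the 20 PCL-R items belonging to each factor
#: (8 interpersonal/affective, 10 lifestyle/antisocial, 2 on neither).
DEFAULT_FACTOR_MAP = {
    "f1": tuple(range(0, 8)),
    "f2": tuple(range(8, 18)),
}

# latent-to-item loading shared by all thresholded item models
_ITEM_LOADING = np.sqrt(0.5)

# marginal probabilities of PCL-R item scores 0/1/2 at latent mean 0
_PCLR_ITEM_PROBS = (0.35, 0.35, 0.30)
# marginal probabilities of IRI item scores 0..4 at latent mean 0
_IRI_ITEM_PROBS = (0.10, 0.20, 0.30, 0.25, 0.15)

#: latent (F1, F2) mean shift used when a subject is designated to a group,
#: chosen so rejection sampling against the PCL-R cutoffs (>=30 high,
#: <=20 low) accepts quickly while keeping within-group item variability.
_GROUP_LATENT_SHIFT = {"low": -0.9, "moderate": 0.55, "high": 1.9}

#: Pearson latent correlation yielding Spearman rho ~ 0.5 between factors
_FACTOR_LATENT_R = 2.0 * np.sin(np.pi * 0.5 / 6.0)


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic cohort.

    n_subjects maps group name -> count; gradient_strength scales how fast
    inter-parcel correlation decays along the anterior-posterior axis;
    compression_c in [0, 1) blends the high-psychopathy group's parcel
    covariance toward a uniform matrix (0 = no compression);
    covariate_slopes are morphometry SDs per covariate SD; group_effect_sd
    is the standardized SA increase planted in paralimbic/somatomotor
    parcels of the high group; behavior_effects are the signed latent
    coefficients of F1 -> IRI-EC and F2 -> IRI-PT; noise_sd is iid
    measurement noise relative to unit latent SD.
    """

    n_subjects: dict = field(
        default_factory=lambda: {"low": 289, "moderate": 337, "high": 178}
    )
    n_parcels: int = 360
    gradient_strength: float = 1.0
    compression_c: float = 0.0
    covariate_slopes: dict = field(
        default_factory=lambda: {
            "CT": {"age": -0.25, "iq": 0.05, "tiv": 0.0},
            "SA": {"age": -0.10, "iq": 0.10, "tiv": 0.55},
        }
    )
    group_effect_sd: float = 0.4
    behavior_effects: dict = field(
        default_factory=lambda: {"f1_ec": -0.4, "f2_pt": -0.4}
    )
    noise_sd: float = 0.3
    pclr_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.compression_c < 1.0):
            raise ValueError("compression_c must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for g in self.n_subjects:
            if g not in ("low", "moderate", "high"):
                raise ValueError(f"unknown group {g!r}")


@dataclass
class MorphometryMatrix:
    """Subject x parcel morphometry with its per-subject covariates.

    ``values`` is a DataFrame indexed by subject_id with one column per
    parcel name; ``index_kind`` is "CT" (mm) or "SA" (mm^2); ``covariates``
    holds age (years), iq, and tiv (mm^3) plus any extras.
    """

    values: pd.DataFrame
    index_kind: str
    covariates: pd.DataFrame

    def __post_init__(self):
        if self.index_kind not in ("CT", "SA"):
            raise ValueError("index_kind must be 'CT' or 'SA'")
        if self.values.isna().any().any():
            raise ValueError("morphometry contains missing values")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("morphometry values must be positive")
        if not self.values.index.equals(self.covariates.index):
            raise ValueError("values and covariates must share subject index")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "subject_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, index_kind: str, covariates: pd.DataFrame):
        df = pd.read_csv(path, sep="\t").set_index("subject_id")
        return cls(df, index_kind, covariates.loc[df.index])


def make_covariance_model(
    atlas: ParcelAtlas, gradient_strength: float = 1.0, c: float = 0.0
) -> np.ndarray:
    """Parcel correlation matrix with an anterior-posterior gradient.

    The base kernel is a squared-exponential in anterior-posterior distance,
    K_ij = exp(-2 (g d_ij)^2) with d_ij = |ap_i - ap_j| and g the gradient
    strength, so nearby parcels along the axis covary strongly and the
    matrix is positive semi-definite by construction. Compression blends the
    off-diagonal structure toward its constant mean: (1-c) K + c K_bar,
    with the unit diagonal fixed.
    """
    if gradient_strength <= 0:
        raise ValueError("gradient_strength must be positive")
    if not (0.0 <= c < 1.0):
        raise ValueError("c must lie in [0, 1)")
    ap = atlas.ap_axis
    d = np.abs(ap[:, None] - ap[None, :])
    K = np.exp(-2.0 * (gradient_strength * d) ** 2)
    if c > 0:
        off = ~np.eye(len(ap), dtype=bool)
        m = K[off].mean()
        K = (1.0 - c) * K + c * (m * np.ones_like(K))
        np.fill_diagonal(K, 1.0)
    return K


def _check_psd_cholesky(K: np.ndarray) -> np.ndarray:
    """Cholesky factor with a tiny jitter; raises on genuinely non-PSD input."""
    jitter = 1e-10 * np.eye(K.shape[0])
    try:
        return np.linalg.cholesky(K + jitter)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "covariance model is not positive semi-definite"
        ) from err


def simulate_covariates(n_subjects: int, seed: int) -> pd.DataFrame:
    """Age/IQ/TIV drawn to match an adult incarcerated male sample."""
    rng = as_rng(seed)
    age = np.clip(rng.normal(33.8, 8.2, n_subjects), 18.0, 63.0)
    iq = np.clip(rng.normal(98.0, 13.1, n_subjects), 70.0, 137.0)
    tiv = np.clip(rng.normal(1.58e6, 1.5e5, n_subjects), 0.96e6, 2.0e6)
    return pd.DataFrame({"age": age, "iq": iq, "tiv": tiv})


def simulate_morphometry(
    cov_model: np.ndarray,
    config: SyntheticConfig,
    group_labels: np.ndarray,
    seed: int,
    *,
    atlas: ParcelAtlas,
    covariates: pd.DataFrame,
    index_kind: str = "CT",
    group_effect_map: np.ndarray | None = None,
) -> MorphometryMatrix:
    """Draw a subject x parcel morphometry matrix.

    Low/moderate subjects are drawn from the uncompressed parcel covariance;
    high-psychopathy subjects from the same model blended toward uniformity
    by ``config.compression_c``. Covariate effects enter linearly on the
    standardized scale, ``group_effect_map`` (per-parcel standardized shift)
    is added for the high group only, and iid noise of SD
    ``config.noise_sd`` is superimposed before mapping to physical units.
    """
    group_labels = np.asarray(group_labels)
    n = len(group_labels)
    if covariates.shape[0] != n:
        raise ValueError("covariates and group_labels disagree on n_subjects")
    p = cov_model.shape[0]
    rng = as_rng(seed)

    chol_base = _check_psd_cholesky(cov_model)
    signal = np.empty((n, p))
    high = group_labels == "high"
    z = rng.standard_normal((n, p))
    signal[~high] = z[~high] @ chol_base.T
    if high.any():
        if config.compression_c > 0:
            off = ~np.eye(p, dtype=bool)
            m = cov_model[off].mean()
            K_high = (1 - config.compression_c) * cov_model + config.compression_c * (
                m * np.ones_like(cov_model)
            )
            np.fill_diagonal(K_high, 1.0)
            chol_high = _check_psd_cholesky(K_high)
        else:
            chol_high = chol_base
        signal[high] = z[high] @ chol_high.T

    slopes = config.covariate_slopes.get(index_kind, {})
    for name, slope in slopes.items():
        if slope == 0.0 or name not in covariates:
            continue
        cz = covariates[name].to_numpy(dtype=float)
        cz = (cz - cz.mean()) / cz.std()
        signal += slope * cz[:, None]

    if group_effect_map is not None:
        signal[high] += np.asarray(group_effect_map, dtype=float)[None, :]

    signal += config.noise_sd * rng.standard_normal((n, p))

    if index_kind == "CT":
        baseline = np.full(p, 2.5)
        scale = np.full(p, 0.15)
    else:
        # parcel areas vary over roughly an order of magnitude
        baseline = 700.0 * np.exp(0.5 * np.sin(7.0 * atlas.ap_axis))
        scale = 0.12 * baseline
    values = baseline[None, :] + scale[None, :] * signal
    values = np.maximum(values, 1e-3)  # physical positivity floor

    subject_ids = covariates.index
    df = pd.DataFrame(values, index=subject_ids, columns=atlas.names)
    return MorphometryMatrix(df, index_kind, covariates)


def default_group_effect_map(
    atlas: ParcelAtlas, effect_sd: float
) -> np.ndarray:
    """Standardized SA shift concentrated in paralimbic and somatomotor parcels."""
    target = (atlas.mesulam_class == "paralimbic") | (
        atlas.yeo_network == "somatomotor"
    )
    return np.where(target, effect_sd, 0.0)


# ---------------------------------------------------------------------------
# behavior


def _threshold_items(
    latent: np.ndarray, rng: np.random.Generator, probs: tuple[float, ...]
) -> np.ndarray:
    """Threshold latent + item noise into ordinal scores with given marginals."""
    from scipy.stats import norm

    noise = rng.standard_normal(latent.shape)
    u = _ITEM_LOADING * latent + np.sqrt(1.0 - _ITEM_LOADING**2) * noise
    cuts = norm.ppf(np.cumsum(probs[:-1]))
    return np.searchsorted(cuts, u, side="right").astype(float)


def _draw_behavior_batch(
    n: int,
    rng: np.random.Generator,
    behavior_effects: dict,
    latent_shift: float = 0.0,
) -> pd.DataFrame:
    """One batch of integer PCL-R and IRI item scores from latent factors."""
    r = _FACTOR_LATENT_R
    z = rng.standard_normal((n, 2))
    f1 = z[:, 0] + latent_shift
    f2 = r * z[:, 0] + np.sqrt(1 - r**2) * z[:, 1] + latent_shift

    n_items = 20
    f1_idx = set(DEFAULT_FACTOR_MAP["f1"])
    f2_idx = set(DEFAULT_FACTOR_MAP["f2"])
    items = np.empty((n, n_items))
    for j in range(n_items):
        if j in f1_idx:
            lat = f1
        elif j in f2_idx:
            lat = f2
        else:  # the two items outside both factors track their average
            lat = (f1 + f2) / np.sqrt(2.0 + 2.0 * r)
        items[:, j] = _threshold_items(lat, rng, _PCLR_ITEM_PROBS)

    b_ec = float(behavior_effects.get("f1_ec", 0.0))
    b_pt = float(behavior_effects.get("f2_pt", 0.0))
    lat_ec = b_ec * f1 + np.sqrt(max(0.0, 1.0 - b_ec**2)) * rng.standard_normal(n)
    lat_pt = b_pt * f2 + np.sqrt(max(0.0, 1.0 - b_pt**2)) * rng.standard_normal(n)
    iri_ec_items = np.column_stack(
        [_threshold_items(lat_ec, rng, _IRI_ITEM_PROBS) for _ in range(7)]
    )
    iri_pt_items = np.column_stack(
        [_threshold_items(lat_pt, rng, _IRI_ITEM_PROBS) for _ in range(7)]
    )

    out = {}
    for j in range(n_items):
        out[f"pclr_item_{j + 1:02d}"] = items[:, j].astype(int)
    for j in range(7):
        out[f"iri_pt_item_{j + 1}"] = iri_pt_items[:, j].astype(int)
        out[f"iri_ec_item_{j + 1}"] = iri_ec_items[:, j].astype(int)
    return pd.DataFrame(out)


def simulate_behavior(
    n_subjects: int,
    behavior_effects: dict | None = None,
    seed: int = 0,
    *,
    latent_shift: float = 0.0,
) -> pd.DataFrame:
    """Item-level behavioral table for ``n_subjects`` unselected subjects.

    Returns a DataFrame of integer PCL-R items (0-2) and IRI items (0-4)
    plus summed/scored columns (iri_pt, iri_ec, pclr_f1, pclr_f2,
    pclr_total, group). The two PCL-R factors are correlated latents
    (Spearman rho ~ 0.5); behavior_effects["f1_ec"] and ["f2_pt"] are the
    signed latent regressions of IRI-EC on F1 and IRI-PT on F2.
    """
    if behavior_effects is None:
        behavior_effects = {"f1_ec": -0.4, "f2_pt": -0.4}
    for v in behavior_effects.values():
        if not np.isfinite(v):
            raise ValueError("behavior effects must be finite")
    rng = as_rng(seed)
    df = _draw_behavior_batch(n_subjects, rng, behavior_effects, latent_shift)
    return _score_behavior_frame(df)


def _score_behavior_frame(df: pd.DataFrame) -> pd.DataFrame:
    from .psychometrics import DEFAULT_FACTOR_MAP as FMAP
    from .psychometrics import assign_group, prorate_pclr

    item_cols = [f"pclr_item_{j + 1:02d}" for j in range(20)]
    pt_cols = [f"iri_pt_item_{j + 1}" for j in range(7)]
    ec_cols = [f"iri_ec_item_{j + 1}" for j in range(7)]
    out = df.copy()
    out["iri_pt"] = df[pt_cols].to_numpy(dtype=int).sum(axis=1)
    out["iri_ec"] = df[ec_cols].to_numpy(dtype=int).sum(axis=1)

    items = df[item_cols].to_numpy(dtype=float)
    if not np.isnan(items).any():
        # complete items: prorating reduces to plain sums (vectorized)
        out["pclr_total"] = items.sum(axis=1)
        out["pclr_f1"] = items[:, list(FMAP["f1"])].sum(axis=1)
        out["pclr_f2"] = items[:, list(FMAP["f2"])].sum(axis=1)
    else:
        scored = np.array([prorate_pclr(list(row)) for row in items])
        out["pclr_total"] = scored[:, 0]
        out["pclr_f1"] = scored[:, 1]
        out["pclr_f2"] = scored[:, 2]
    out["group"] = [assign_group(t) for t in out["pclr_total"]]
    return out


# ---------------------------------------------------------------------------
# full cohort


@dataclass
class Cohort:
    """A complete synthetic study: atlas, behavior, and CT/SA matrices."""

    atlas: ParcelAtlas
    subjects: pd.DataFrame  # behavior + covariates, indexed by subject_id
    ct: MorphometryMatrix
    sa: MorphometryMatrix
    config: SyntheticConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.atlas.to_tsv(outdir / "parcels.tsv")
        subj = self.subjects.copy()
        subj.insert(0, "subject_id", subj.index)
        subj.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
        self.ct.to_tsv(outdir / "ct.tsv")
        self.sa.to_tsv(outdir / "sa.tsv")


def generate_cohort(config: SyntheticConfig, atlas: ParcelAtlas | None = None) -> Cohort:
    """Generate the full synthetic study defined by ``config``.

    Behavioral rows are rejection-sampled per designated group (latent
    factors shifted by a group-specific offset, redrawn until the prorated
    PCL-R total lands in the group's cutoff band: <=20 low, 21-29 moderate,
    >=30 high), then CT and SA matrices are drawn around the
    anterior-posterior covariance model, with the high group's covariance
    compressed by ``config.compression_c`` and its SA shifted by the
    paralimbic/somatomotor effect map.
    """
    seed = config.seed
    if atlas is None:
        atlas = make_parcellation(config.n_parcels, seed=child_seed(seed, "atlas"))
    elif atlas.n_parcels != config.n_parcels:
        raise ValueError("supplied atlas does not match config.n_parcels")
    rng = as_rng(child_seed(seed, "behavior"))

    frames = []
    group_labels = []
    for group, n_needed in config.n_subjects.items():
        if n_needed == 0:
            continue
        shift = _GROUP_LATENT_SHIFT[group]
        collected = []
        n_have = 0
        tries = 0
        while n_have < n_needed:
            tries += 1
            if tries > 400:
                raise RuntimeError(f"rejection sampling stalled for group {group!r}")
            batch = _draw_behavior_batch(
                max(4 * n_needed, 64), rng, config.behavior_effects, shift
            )
            batch = _score_behavior_frame(batch)
            keep = batch[batch["group"] == group]
            collected.append(keep)
            n_have += len(keep)
        frames.append(pd.concat(collected).iloc[:n_needed])
        group_labels.extend([group] * n_needed)

    subjects = pd.concat(frames, ignore_index=True)
    group_labels = np.asarray(group_labels)
    n = len(subjects)
    subjects.index = pd.Index([f"sub-{i + 1:04d}" for i in range(n)], name="subject_id")

    if config.pclr_missing_rate > 0:
        # knock out a few PCL-R items, then re-prorate
        item_cols = [f"pclr_item_{j + 1:02d}" for j in range(20)]
        mask = rng.random((n, 20)) < config.pclr_missing_rate
        vals = subjects[item_cols].to_numpy(dtype=float)
        vals[mask] = np.nan
        subjects[item_cols] = vals
        subjects = _score_behavior_frame(subjects)
        subjects.index = pd.Index(
            [f"sub-{i + 1:04d}" for i in range(n)], name="subject_id"
        )

    covariates = simulate_covariates(n, child_seed(seed, "covariates"))
    covariates.index = subjects.index

    K = make_covariance_model(atlas, config.gradient_strength, c=0.0)
    ct = simulate_morphometry(
        K,
        config,
        group_labels,
        child_seed(seed, "morphometry_ct"),
        atlas=atlas,
        covariates=covariates,
        index_kind="CT",
        group_effect_map=None,
    )
    sa = simulate_morphometry(
        K,
        config,
        group_labels,
        child_seed(seed, "morphometry_sa"),
        atlas=atlas,
        covariates=covariates,
        index_kind="SA",
        group_effect_map=default_group_effect_map(atlas, config.group_effect_sd),
    )

    subjects = subjects.join(covariates)
    return Cohort(atlas=atlas, subjects=subjects, ct=ct, sa=sa, config=config)
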
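"""Synthetic cohort generator for activation-idiosyncrasy analyses.

Emulates a three-group task-fMRI study (typically developing controls and
two autistic subgroups, with and without intellectual impairment) in which
every participant's whole-brain activation vector is a noisy copy of a
shared canonical template:

    v_i = a_i * T + e_i,      e_i ~ N(0, sigma_i^2 I)

``T`` is the canonical contrast template over ROIs, ``a_i`` a per-person
template weight, and ``sigma_i`` the individual deviation scale.  Group
membership scales ``sigma_i`` (amplified in the intellectually impaired
group) and age enters log-linearly with a non-positive slope, so older
participants deviate less.  Behavioural scores are generated from the
latent deviation scale through configurable linear / quadratic / null
links, which is exactly the structure the downstream brain-behaviour
battery is designed to detect.

Nothing here requires imaging data on disk; atlases and 4-D runs can be
generated on demand for end-to-end tests of the GLM and parcellation
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BehaviourLink",
    "GroupSpec",
    "CohortConfig",
    "CohortConfigError",
    "MEASURES",
    "generate_cohort",
    "generate_behaviour",
    "generate_composite_atlas",
    "generate_bold_run",
    "table1_config",
    "balanced_config",
]

#: Behavioural battery column names (phenotype table order).
MEASURES = (
    "srs",
    "rbs_r",
    "ssp",
    "nviq",
    "ados_css",
    "brief_gec",
    "snap_iv",
    "vabs_abc",
)


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class BehaviourLink:
    """Generative link from the latent deviation scale to one score.

    form:
        ``linear``    score = intercept + slope * latent + noise
        ``quadratic`` score = intercept + slope * (latent - center)^2 + noise
        ``null``      score = intercept + noise
    noise_family:
        ``normal`` or ``lognormal`` (centered, right-skewed; negated when
        ``noise_sd`` < 0 is requested via ``skew_sign``).
    """

    form: str = "null"
    intercept: float = 0.0
    slope: float = 0.0
    center: float = 0.0
    noise_sd: float = 1.0
    noise_family: str = "normal"
    skew_sign: float = 1.0

    def validate(self) -> None:
        if self.form not in ("linear", "quadratic", "null"):
            raise CohortConfigError(f"unknown link form {self.form!r}")
        if self.noise_family not in ("normal", "lognormal"):
            raise CohortConfigError(
                f"unknown noise family {self.noise_family!r}"
            )
        if self.noise_sd < 0:
            raise CohortConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group of the synthetic cohort."""

    name: str
    n: int
    deviation_sd: float
    diagnostic_group: str = "ASC"  # binary label used by within/TDC schemes
    template_weight_mean: float = 1.0
    template_weight_sd: float = 0.1
    male_fraction: float = 0.5
    adhd_rate: float = 0.0
    fd_median: float = 0.08  # mm; FD is log-normal
    fd_log_sd: float = 0.3

    def validate(self) -> None:
        if self.n < 2:
            raise CohortConfigError(f"group {self.name!r}: n must be >= 2")
        if self.deviation_sd <= 0:
            raise CohortConfigError(
                f"group {self.name!r}: deviation_sd must be > 0"
            )
        if not 0.0 <= self.male_fraction <= 1.0:
            raise CohortConfigError("male_fraction must be in [0, 1]")
        if self.fd_median <= 0 or self.fd_log_sd <= 0:
            raise CohortConfigError("FD distribution parameters must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``age_variability_slope`` is the per-year slope on the *log* deviation
    scale (non-positive: older participants are less idiosyncratic).
    """

    group_specs: tuple[GroupSpec, ...]
    n_rois: int = 284
    age_range: tuple[float, float] = (8.0, 30.0)
    age_mean: float = 17.0
    age_sd: float = 6.0
    age_variability_slope: float = -0.02
    deviation_log_sd: float = 0.25
    template_sd: float = 1.0
    behaviour_links: dict[str, BehaviourLink] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.group_specs:
            raise CohortConfigError("at least one group is required")
        for g in self.group_specs:
            g.validate()
        names = [g.name for g in self.group_specs]
        if len(set(names)) != len(names):
            raise CohortConfigError("group names must be unique")
        if self.n_rois < 2:
            raise CohortConfigError("n_rois must be >= 2")
        if self.age_variability_slope > 0:
            raise CohortConfigError("age_variability_slope must be <= 0")
        if self.deviation_log_sd < 0:
            raise CohortConfigError("deviation_log_sd must be >= 0")
        if self.template_sd <= 0:
            raise CohortConfigError("template_sd must be > 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise CohortConfigError("age_range must be increasing")
        for name, link in self.behaviour_links.items():
            if name not in MEASURES:
                raise CohortConfigError(f"unknown measure {name!r}")
            link.validate()

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.group_specs)


def _default_links() -> dict[str, BehaviourLink]:
    # Intercepts/slopes chosen so group means track the published cohort's
    # demographics; linear links keep Gaussian noise with a moderate
    # signal/noise ratio so their marginals stay near-normal, quadratic
    # links add right-skewed noise so a KS normality gate routes them to
    # smooth terms.
    return {
        # near-normal marginals -> linear terms
        "snap_iv": BehaviourLink("linear", -6.0, 12.0, noise_sd=11.0),
        "brief_gec": BehaviourLink("linear", 65.0, 40.0, noise_sd=34.0),
        "vabs_abc": BehaviourLink("linear", 150.0, -38.0, noise_sd=30.0),
        "ados_css": BehaviourLink("linear", 1.5, 2.8, noise_sd=2.4),
        # skewed marginals -> smooth terms
        "srs": BehaviourLink(
            "quadratic", 15.0, 55.0, center=0.8, noise_sd=30.0,
            noise_family="lognormal",
        ),
        "rbs_r": BehaviourLink(
            "quadratic", 2.0, 18.0, center=0.8, noise_sd=14.0,
            noise_family="lognormal",
        ),
        "ssp": BehaviourLink(
            "quadratic", 185.0, -22.0, center=0.8, noise_sd=16.0,
            noise_family="lognormal", skew_sign=-1.0,
        ),
        "nviq": BehaviourLink(
            "quadratic", 122.0, -30.0, center=0.8, noise_sd=18.0,
            noise_family="lognormal", skew_sign=-1.0,
        ),
    }


def table1_config(seed: int = 0, n_rois: int = 284) -> CohortConfig:
    """Preset replicating the reference cohort's composition.

    33 controls (25M:8F), 28 intellectually able autistic participants
    (25M:3F, 11 with ADHD), 19 intellectually impaired autistic
    participants (all male, 8 with ADHD); deviation-sd ratio 1 : 1.1 : 2
    with the amplification in the impaired group.
    """
    groups = (
        GroupSpec("TDC", 33, 1.0, "TDC", male_fraction=25 / 33,
                  adhd_rate=0.0, fd_median=0.065),
        GroupSpec("ASC-IA", 28, 1.1, "ASC", male_fraction=25 / 28,
                  adhd_rate=11 / 28, fd_median=0.083),
        GroupSpec("ASC-II", 19, 2.0, "ASC", male_fraction=1.0,
                  adhd_rate=8 / 19, fd_median=0.087),
    )
    return CohortConfig(group_specs=groups, n_rois=n_rois, seed=seed,
                        behaviour_links=_default_links())


def balanced_config(seed: int = 0, n_per_group: int = 30,
                    n_rois: int = 284,
                    deviation_sds: tuple[float, float, float] = (1.0, 1.0, 2.0),
                    ) -> CohortConfig:
    """Sex-balanced three-group preset (deviation-sd ratio configurable)."""
    groups = (
        GroupSpec("TDC", n_per_group, deviation_sds[0], "TDC"),
        GroupSpec("ASC-IA", n_per_group, deviation_sds[1], "ASC",
                  adhd_rate=0.4),
        GroupSpec("ASC-II", n_per_group, deviation_sds[2], "ASC",
                  adhd_rate=0.4),
    )
    return CohortConfig(group_specs=groups, n_rois=n_rois, seed=seed,
                        behaviour_links=_default_links())


def null_config(seed: int = 0, n_per_group: int = 20,
                n_rois: int = 284) -> CohortConfig:
    """All groups share one deviation scale; behaviour links all null."""
    cfg = balanced_config(seed=seed, n_per_group=n_per_group, n_rois=n_rois,
                          deviation_sds=(1.0, 1.0, 1.0))
    links = {m: BehaviourLink("null", noise_sd=1.0) for m in MEASURES}
    return replace(cfg, behaviour_links=links, age_variability_slope=0.0)


def battery_sim_config(seed: int = 0, n_per_group: int = 60,
                       n_rois: int = 150) -> CohortConfig:
    """Battery-recovery preset: 2 linear + 2 quadratic links, 4 null.

    The four null measures are pure Gaussian noise (so the normality gate
    routes them to linear terms and their association p-values are
    exactly null-calibrated); the linked measures keep the default
    effect sizes.
    """
    cfg = balanced_config(seed=seed, n_per_group=n_per_group,
                          n_rois=n_rois)
    defaults = _default_links()
    links = {
        "snap_iv": defaults["snap_iv"],    # linear +
        "vabs_abc": defaults["vabs_abc"],  # linear -
        "srs": defaults["srs"],            # quadratic
        "nviq": defaults["nviq"],          # quadratic
        "brief_gec": BehaviourLink("null", 100.0, noise_sd=20.0),
        "ados_css": BehaviourLink("null", 5.0, noise_sd=2.0),
        "rbs_r": BehaviourLink("null", 10.0, noise_sd=5.0),
        "ssp": BehaviourLink("null", 170.0, noise_sd=15.0),
    }
    return replace(cfg, behaviour_links=links)


#: Measures carrying a generative link in :func:`battery_sim_config`.
BATTERY_SIM_LINKED = ("snap_iv", "vabs_abc", "srs", "nviq")


def generate_behaviour(latent: np.ndarray, link: BehaviourLink,
                       rng: np.random.Generator) -> np.ndarray:
    """Generate one behavioural score vector from latent deviation scales."""
    link.validate()
    latent = np.asarray(latent, dtype=float)
    if link.form == "linear":
        signal = link.intercept + link.slope * latent
    elif link.form == "quadratic":
        signal = link.intercept + link.slope * (latent - link.center) ** 2
    else:  # null
        signal = np.full(latent.shape, link.intercept)
    if link.noise_sd == 0:
        return signal
    if link.noise_family == "normal":
        noise = rng.normal(0.0, link.noise_sd, size=latent.shape)
    else:
        # centered log-normal, scaled to the requested sd
        s = 0.8
        raw = rng.lognormal(mean=0.0, sigma=s, size=latent.shape)
        raw -= np.exp(s**2 / 2)
        raw /= np.sqrt((np.exp(s**2) - 1) * np.exp(s**2))
        noise = link.skew_sign * link.noise_sd * raw
    return signal + noise


def _truncated_normal(rng, mean, sd, lo, hi, size):
    from scipy.stats import truncnorm

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=rng)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (phenotype table, participant x ROI activation matrix).

    The two frames share the participant id (index of the matrix, ``id``
    column of the table) in the same order.  Identical config (including
    seed) yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    template = rng.normal(0.0, config.template_sd, size=config.n_rois)
    if np.allclose(template.std(), 0.0):
        raise CohortConfigError("degenerate template: zero variance")

    lo, hi = config.age_range
    age_ref = 0.5 * (lo + hi)

    rows = []
    vectors = []
    counter = 0
    for g in config.group_specs:
        ages = _truncated_normal(rng, config.age_mean, config.age_sd,
                                 lo, hi, g.n)
        n_male = int(round(g.male_fraction * g.n))
        sexes = np.array(["M"] * n_male + ["F"] * (g.n - n_male))
        rng.shuffle(sexes)
        n_adhd = int(round(g.adhd_rate * g.n))
        adhd = np.array([True] * n_adhd + [False] * (g.n - n_adhd))
        rng.shuffle(adhd)
        fd = rng.lognormal(mean=np.log(g.fd_median), sigma=g.fd_log_sd,
                           size=g.n)
        weights = rng.normal(g.template_weight_mean, g.template_weight_sd,
                             size=g.n)
        # latent idiosyncrasy scale: group deviation sd, modulated by age
        # and an individual lognormal multiplier (within-group
        # heterogeneity, which keeps group effect sizes realistic)
        sigma = g.deviation_sd * np.exp(
            config.age_variability_slope * (ages - age_ref))
        if config.deviation_log_sd > 0:
            sigma = sigma * rng.lognormal(0.0, config.deviation_log_sd,
                                          size=g.n)

        for j in range(g.n):
            counter += 1
            pid = f"sub-{counter:04d}"
            v = weights[j] * template + rng.normal(
                0.0, sigma[j], size=config.n_rois)
            vectors.append(v)
            rows.append({
                "id": pid,
                "group": g.name,
                "diagnostic_group": g.diagnostic_group,
                "adhd": bool(adhd[j]),
                "age": float(ages[j]),
                "sex": str(sexes[j]),
                "mean_fd": float(fd[j]),
                "_latent_sigma": float(sigma[j]),
            })

    phenotype = pd.DataFrame(rows)
    latent = phenotype["_latent_sigma"].to_numpy()
    for measure in MEASURES:
        link = config.behaviour_links.get(measure, BehaviourLink("null"))
        phenotype[measure] = generate_behaviour(latent, link, rng)
    phenotype = phenotype.drop(columns="_latent_sigma").join(
        pd.Series(latent, name="latent_sigma"))

    matrix = pd.DataFrame(
        np.vstack(vectors),
        index=pd.Index(phenotype["id"], name="id"),
        columns=[f"roi_{k + 1}" for k in range(config.n_rois)],
    )
    return phenotype, matrix


def generate_composite_atlas(shape: tuple[int, int, int],
                             parcel_counts: list[int],
                             seed: int = 0,
                             affine: np.ndarray | None = None):
    """Build a synthetic composite label atlas as a NIfTI-1 image.

    The composite mimics stitching several component parcellations into
    one label image: component ``c`` contributes ``parcel_counts[c]``
    parcels, labelled contiguously after the previous component's labels
    (so counts [200, 50, 34] give labels 1..284).  Parcels are compact
    nearest-seed (Voronoi) regions inside an ellipsoidal foreground mask;
    background is 0.
    """
    import nibabel as nib
    from scipy.spatial import cKDTree

    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise CohortConfigError("shape must be three positive dims")
    counts = [int(c) for c in parcel_counts]
    if not counts or any(c < 1 for c in counts):
        raise CohortConfigError("parcel counts must be positive")
    k_total = sum(counts)
    if int(np.prod(shape)) < k_total:
        raise CohortConfigError(
            f"volume of {np.prod(shape)} voxels cannot hold {k_total} parcels")

    rng = np.random.default_rng(seed)
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    center = (np.asarray(shape, float) - 1) / 2
    semi = np.maximum(np.asarray(shape, float) * 0.45, 0.5)
    inside = (((grid - center) / semi) ** 2).sum(axis=1) <= 1.0
    if inside.sum() < k_total:  # tiny volumes: use every voxel
        inside = np.ones(len(grid), dtype=bool)
    fg = grid[inside]

    seed_idx = rng.choice(len(fg), size=k_total, replace=False)
    seeds = fg[seed_idx]
    _, nearest = cKDTree(seeds).query(fg, k=1)
    labels = np.zeros(int(np.prod(shape)), dtype=np.int32)
    labels[np.flatnonzero(inside)] = nearest + 1  # labels 1..K

    data = labels.reshape(shape)
    if affine is None:
        affine = np.diag([2.6, 2.6, 2.6, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = f"synthetic composite atlas {counts}".encode()[:80]
    return img


def generate_bold_run(activation_vector: np.ndarray, atlas, design,
                      noise_sd: float = 1.0, seed: int = 0):
    """Simulate a 4-D BOLD run whose task response encodes an ROI vector.

    Each voxel of ROI ``k`` responds to the first task condition with
    amplitude ``activation_vector[k]`` and not at all to the second, so
    the first-vs-second contrast recovers the vector.  Gaussian noise is
    added everywhere (including background).  Returns the 4-D NIfTI image
    and a 6-column motion-parameter table (slow random walk).
    """
    import nibabel as nib

    vec = np.asarray(activation_vector, dtype=float)
    atlas_data = np.asarray(
        atlas.get_fdata() if hasattr(atlas, "get_fdata") else atlas)
    atlas_int = np.rint(atlas_data).astype(int)
    k_max = atlas_int.max()
    if k_max != len(vec):
        raise CohortConfigError(
            f"activation vector length {len(vec)} does not match atlas "
            f"label count {k_max}")
    X = design.values
    names = list(design.names)
    n_frames = X.shape[0]
    if n_frames < 1:
        raise CohortConfigError("design must have at least one frame")

    task_col = X[:, names.index("BM")]
    rng = np.random.default_rng(seed)

    beta_map = np.zeros(k_max + 1)
    beta_map[1:] = vec
    amp = beta_map[atlas_int]  # voxelwise amplitude
    series = amp[..., None] * task_col[None, None, None, :]
    if noise_sd > 0:
        series = series + rng.normal(0.0, noise_sd, size=series.shape)

    affine = atlas.affine if hasattr(atlas, "affine") else np.eye(4)
    img = nib.Nifti1Image(series.astype(np.float32), affine)

    motion = np.cumsum(rng.normal(0.0, 0.01, size=(n_frames, 6)), axis=0)
    motion_tbl = pd.DataFrame(
        motion,
        columns=["trans_x", "trans_y", "trans_z",
                 "rot_x", "rot_y", "rot_z"],
    )
    return img, motion_tbl
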
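"""Synthetic multimodal cohort generator.

Emulates the statistical structure an obesity/brain-age analysis assumes:
an adult-lifespan cohort (18-89 y) with BMI classes, grey-matter ROI volumes
that decline with age, diffusion white-matter indices with age trends but no
obesity effect by default, and network-structured functional connectivity
whose within-network coupling falls and between-network coupling rises with
age.  Obesity-related acceleration is injected as a shift in *effective age*:
an obese participant's brain features are those of a non-obese participant who
is ``accel_years`` older (optionally only inside an age window), matching the
construct that obese brains resemble older normal-weight brains.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .connectivity import (  # re-exported: parcellation is shared plumbing
    DEFAULT_NETWORK_SIZES,
    Parcellation,
    make_parcellation,
    timeseries_to_connectivity,
)

__all__ = [
    "BMI_CUTOFFS",
    "EffectSpec",
    "Cohort",
    "classify_bmi",
    "generate_cohort",
    "effective_age",
    "generate_gm_features",
    "generate_dwi_features",
    "generate_connectivity",
    "make_parcellation",
    "DEFAULT_NETWORK_SIZES",
]

#: WHO BMI class boundaries (kg/m^2): normal 18.5-24.9, overweight 25-29.9,
#: obese >= 30.
BMI_CUTOFFS = {"normal": (18.5, 24.9), "overweight": (25.0, 29.9), "obese": (30.0, 40.0)}

AGE_MIN, AGE_MAX = 18.0, 89.0

DWI_METRICS = ("FA", "MD", "AD", "RD")


def classify_bmi(bmi: float) -> str:
    if bmi >= 30.0:
        return "obese"
    if bmi >= 25.0:
        return "overweight"
    if bmi >= 18.5:
        return "normal"
    raise ValueError(f"BMI {bmi} below the normal-weight range")


@dataclass(frozen=True)
class EffectSpec:
    """Generative effect parameters for one feature modality.

    Parameters
    ----------
    accel_years
        Years added to the *effective* brain age of obese participants;
        0 encodes the null hypothesis.
    accel_window
        Optional (lower, upper) chronological-age interval within [18, 90];
        the acceleration applies only to obese participants inside it.
    noise_sd
        Per-feature residual standard deviation (feature units).
    age_slopes / baselines
        Optional per-feature linear age coefficients and intercepts; drawn
        deterministically from the seed when omitted.
    obese_roi_offsets
        Optional {roi_index: offset} additive group effect for obese
        participants on specific ROIs (feature units), on top of the
        effective-age shift — used to plant region-specific group signatures
        for classifier-recovery studies.
    """

    accel_years: float = 0.0
    accel_window: tuple[float, float] | None = None
    noise_sd: float = 0.1
    age_slopes: np.ndarray | None = None
    baselines: np.ndarray | None = None
    obese_roi_offsets: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.accel_window is not None:
            lo, hi = self.accel_window
            if not (AGE_MIN <= lo < hi <= 90.0):
                raise ValueError("accel_window must be a valid interval in [18, 90]")


@dataclass(frozen=True)
class Cohort:
    """Ordered participant table plus the seed that produced it."""

    table: pd.DataFrame
    rng_seed: int

    def __post_init__(self) -> None:
        if self.table["id"].duplicated().any():
            raise ValueError("participant ids must be unique")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def subset(self, mask: np.ndarray | pd.Series) -> pd.DataFrame:
        return self.table.loc[np.asarray(mask)].reset_index(drop=True)


def generate_cohort(
    n: int,
    obese_fraction: float,
    seed: int,
    overweight_fraction: float = 0.3,
    age_range: tuple[float, float] = (AGE_MIN, AGE_MAX),
) -> Cohort:
    """Sample a cohort with a fixed obese/non-obese split.

    Ages are uniform over ``age_range`` (default the full 18-89 adult
    lifespan), sex is Bernoulli(0.5), education uniform on the ordinal levels
    1-5 and MMSE uniform on 25-30, all independent of group.  Exactly
    ``round(n * obese_fraction)`` participants are obese; of the remainder,
    ``overweight_fraction`` are overweight and the rest normal weight, with
    BMI sampled uniformly inside the class range.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not (0.0 <= obese_fraction <= 1.0):
        raise ValueError("obese_fraction must lie in [0, 1]")
    if not (0.0 <= overweight_fraction <= 1.0):
        raise ValueError("overweight_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_obese = int(round(n * obese_fraction))
    n_over = int(round((n - n_obese) * overweight_fraction))
    n_normal = n - n_obese - n_over
    classes = ["obese"] * n_obese + ["overweight"] * n_over + ["normal"] * n_normal
    rng.shuffle(classes)

    lo, hi = age_range
    ages = rng.uniform(lo, hi, size=n)
    sexes = rng.choice(["female", "male"], size=n)
    education = rng.integers(1, 6, size=n)
    mmse = rng.integers(25, 31, size=n)
    bmi = np.array(
        [rng.uniform(*BMI_CUTOFFS[c]) for c in classes]
    )
    table = pd.DataFrame(
        {
            "id": [f"sub-{i:04d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "education": education,
            "bmi": bmi,
            "bmi_class": classes,
            "mmse": mmse,
        }
    )
    return Cohort(table=table, rng_seed=seed)


def effective_age(cohort: Cohort | pd.DataFrame, effect: EffectSpec) -> np.ndarray:
    """Chronological age plus the obesity acceleration where it applies."""
    table = cohort.table if isinstance(cohort, Cohort) else cohort
    age = table["age"].to_numpy(dtype=float)
    obese = (table["bmi_class"] == "obese").to_numpy()
    if effect.accel_window is not None:
        lo, hi = effect.accel_window
        in_window = (age >= lo) & (age < hi)
    else:
        in_window = np.ones_like(obese)
    return age + effect.accel_years * (obese & in_window)


def _default_gm_params(n_rois: int, rng: np.random.Generator):
    """Baselines and slopes for normalized GM ROI volumes.

    A configurable majority of ROIs decline with age (atrophy); a minority
    (occipital-like) increase slightly, mirroring regions where obese > normal
    findings are reported.  Units are fraction-of-brain-volume x 100.
    """
    n_pos = max(1, n_rois // 8)
    slopes = np.empty(n_rois)
    slopes[: n_rois - n_pos] = rng.uniform(-0.004, -0.001, size=n_rois - n_pos)
    slopes[n_rois - n_pos:] = rng.uniform(0.0005, 0.0015, size=n_pos)
    rng.shuffle(slopes)
    baselines = rng.uniform(0.9, 1.6, size=n_rois)
    return baselines, slopes


def _linear_features(
    cohort: Cohort,
    effect: EffectSpec,
    baselines: np.ndarray,
    slopes: np.ndarray,
    rng: np.random.Generator,
    prefix: str,
) -> pd.DataFrame:
    eff_age = effective_age(cohort, effect)
    n, p = len(cohort), len(slopes)
    values = baselines[None, :] + slopes[None, :] * eff_age[:, None]
    values = values + rng.normal(0.0, effect.noise_sd, size=(n, p))
    if effect.obese_roi_offsets:
        obese = (cohort.table["bmi_class"] == "obese").to_numpy()
        for roi, offset in effect.obese_roi_offsets.items():
            values[obese, roi] += offset
    cols = [f"{prefix}_{r:02d}" for r in range(p)]
    out = pd.DataFrame(values, columns=cols)
    out.insert(0, "id", cohort.ids)
    return out


def generate_gm_features(
    cohort: Cohort,
    n_rois: int = 48,
    effect: EffectSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalized grey-matter ROI volumes (48 cortical ROIs by default).

    Feature r = baseline_r + slope_r * effective_age + noise; most slopes are
    negative (grey-matter decline), a minority positive.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    effect = effect or EffectSpec()
    rng = np.random.default_rng(seed)
    if effect.age_slopes is not None or effect.baselines is not None:
        if effect.age_slopes is None or effect.baselines is None:
            raise ValueError("age_slopes and baselines must be given together")
        slopes = np.asarray(effect.age_slopes, dtype=float)
        baselines = np.asarray(effect.baselines, dtype=float)
        if len(slopes) != len(baselines):
            raise ValueError("age_slopes and baselines length mismatch")
        if len(slopes) != n_rois:
            raise ValueError(
                f"effect specifies {len(slopes)} features but n_rois={n_rois}"
            )
    else:
        baselines, slopes = _default_gm_params(n_rois, rng)
    return _linear_features(cohort, effect, baselines, slopes, rng, "gm_roi")


#: (baseline range, slope range) per diffusion metric.  FA (anisotropy) falls
#: with age; mean/axial/radial diffusivity rise.  Diffusivities are in units
#: of 1e-3 mm^2/s.
_DWI_PARAMS = {
    "FA": ((0.35, 0.55), (-0.0015, -0.0005)),
    "MD": ((0.65, 0.85), (0.0005, 0.0015)),
    "AD": ((1.0, 1.3), (0.0005, 0.0015)),
    "RD": ((0.45, 0.65), (0.0005, 0.0015)),
}


def generate_dwi_features(
    cohort: Cohort,
    metrics: tuple[str, ...] = DWI_METRICS,
    n_rois: int = 48,
    effect: EffectSpec | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """White-matter integrity tables (one per diffusion metric, 48 ROIs).

    By default the obesity acceleration is zero for these modalities (the
    white-matter null); pass an ``effect`` with nonzero ``accel_years`` to
    override.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    effect = effect or EffectSpec(accel_years=0.0, noise_sd=0.03)
    out: dict[str, pd.DataFrame] = {}
    for m_index, metric in enumerate(metrics):
        if metric not in _DWI_PARAMS:
            raise ValueError(f"unknown DWI metric {metric!r}")
        rng = np.random.default_rng(np.random.SeedSequence((seed, m_index)))
        (b_lo, b_hi), (s_lo, s_hi) = _DWI_PARAMS[metric]
        baselines = rng.uniform(b_lo, b_hi, size=n_rois)
        slopes = rng.uniform(s_lo, s_hi, size=n_rois)
        out[metric] = _linear_features(
            cohort, effect, baselines, slopes, rng, f"{metric.lower()}_roi"
        )
    return out


def generate_connectivity(
    cohort: Cohort,
    parcellation: Parcellation,
    effect: EffectSpec | None = None,
    seed: int = 0,
    n_timepoints: int = 261,
    min_timepoints: int = 100,
    intra_baseline: float = 0.50,
    intra_slope: float = -0.003,
    inter_baseline: float = 0.05,
    inter_slope: float = 0.0015,
) -> dict[str, np.ndarray]:
    """Per-participant node-by-node correlation matrices.

    Node time-series follow a two-factor model: every node loads on its
    network factor and on a global factor, so the expected within-network
    correlation is ``intra_baseline + intra_slope * (effective_age - 18)``
    (declining with age) and the between-network correlation is
    ``inter_baseline + inter_slope * (effective_age - 18)`` (rising with age).
    Correlating the sampled series yields symmetric, unit-diagonal matrices
    with entries in [-1, 1]; sampling noise comes from the finite run length.

    Returns a dict mapping participant id to its matrix, in cohort order.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if n_timepoints < min_timepoints:
        raise ValueError(
            f"n_timepoints={n_timepoints} below the minimum {min_timepoints} "
            "required for stable correlations"
        )
    effect = effect or EffectSpec(noise_sd=1.0)
    eff_age = effective_age(cohort, effect)
    labels = np.asarray(parcellation.labels)
    networks = parcellation.networks
    net_index = np.array([networks.index(lab) for lab in labels])
    n_nodes = parcellation.n_nodes

    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for pid, ea in zip(cohort.ids, eff_age):
        within = intra_baseline + intra_slope * (ea - AGE_MIN)
        between = inter_baseline + inter_slope * (ea - AGE_MIN)
        if not (0.0 <= between <= within <= 1.0):
            raise ValueError(
                "connectivity trajectory produced an invalid coupling "
                f"(within={within:.3f}, between={between:.3f}) at effective "
                f"age {ea:.1f}"
            )
        c = np.sqrt(between)  # global-factor loading
        a = np.sqrt(within - between)  # network-factor loading
        e = np.sqrt(max(1.0 - within, 0.0))  # unique noise scale
        global_factor = rng.standard_normal(n_timepoints)
        net_factors = rng.standard_normal((len(networks), n_timepoints))
        noise = rng.standard_normal((n_nodes, n_timepoints))
        ts = a * net_factors[net_index] + c * global_factor + e * noise
        out[pid] = timeseries_to_connectivity(ts)
    return out


def with_null_effect(effect: EffectSpec) -> EffectSpec:
    """Copy of an effect spec with the obesity acceleration switched off."""
    return replace(effect, accel_years=0.0)
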
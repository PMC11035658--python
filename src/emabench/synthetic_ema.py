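"""Synthetic EMA study generator.

Emulates the structure of mobile-health EMA datasets: many users joining a
study over time, heavy-tailed per-user assessment counts (power users),
within-user correlation of the outcome (a user effect plus an AR(1) mood
chain), optional cohort-level concept drift over sign-up time, informative
and pure-noise features, and missing answers.

Latent model for user *i*, assessment *t*::

    y*_it = u_i + delta * q_i + s_it + e_it

where ``u_i ~ N(0, icc)`` is the user effect, ``q_i`` the user's sign-up
quantile, ``delta`` the drift strength, ``s_it`` a stationary AR(1) chain
with coefficient ``rho`` and variance ``ar_share * (1 - icc)``, and ``e_it``
white noise with the remaining variance, so that the drift-free latent
variance is 1.  The recorded target is ``Phi(y*_it)`` mapped to [0, 1]
(``Phi`` = standard normal CDF), matching visual-analogue-scale targets that
are later binned into ordinal classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import (
    ID_COL,
    KIND_CATEGORICAL,
    KIND_NUMERIC,
    TARGET_COL,
    TIME_COL,
    USER_COL,
    EMADataset,
    FeatureSchema,
    FeatureSpec,
    TargetSpec,
)
from .preprocess import bin_target

__all__ = ["GeneratorConfig", "UserProfile", "generate", "drift_profile"]

_EPOCH = pd.Timestamp("2021-01-01T00:00:00Z")


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study.

    count_dist is (median, sigma) of the log-normal per-user assessment
    count (minimum 1); sigma > 0 produces the heavy right tail of power
    users.  icc is the share of drift-free latent variance carried by the
    user effect; rho the AR(1) persistence of the within-user chain;
    ar_share how much of the within-user variance sits in the chain versus
    white noise.  drift_strength shifts the latent mean per unit sign-up
    quantile (cohort drift).  feature_snr is the signal-to-noise ratio of
    informative features (np.inf → noise-free copies of the latent).
    feature_user_sd adds a stable per-user intercept to every feature — the
    idiosyncratic answer style that lets a model fingerprint users it has
    already seen (the subject-specific, rather than outcome-related, signal
    that group-unaware cross-validation can exploit).
    """

    n_users: int = 300
    span_days: float = 365.0
    count_dist: tuple = (12.0, 1.0)
    median_gap_hours: float = 24.0
    icc: float = 0.5
    rho: float = 0.6
    drift_strength: float = 0.0
    n_informative: int = 6
    n_noise: int = 2
    n_categorical: int = 1
    feature_snr: float = 4.0
    feature_user_sd: float = 0.5
    ar_share: float = 0.8
    gap_sigma: float = 1.0
    gap_scale_sigma: float = 0.25
    missing_rate: float = 0.05
    n_classes: int = 5
    seed: int = 0
    dataset_label: str = "synthetic"

    def validate(self) -> None:
        if self.n_users < 1:
            raise ConfigError("n_users must be >= 1")
        if not (0.0 <= self.icc < 1.0):
            raise ConfigError("icc must lie in [0, 1)")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError("rho must lie in [0, 1)")
        if not (0.0 <= self.ar_share <= 1.0):
            raise ConfigError("ar_share must lie in [0, 1]")
        if self.n_informative + self.n_noise < 1:
            raise ConfigError("need at least one feature")
        if self.n_informative < 1:
            raise ConfigError("need at least one informative feature")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.n_categorical > self.n_informative + self.n_noise:
            raise ConfigError("n_categorical exceeds the feature count")
        med, sigma = self.count_dist
        if med < 1 or sigma < 0:
            raise ConfigError("count_dist must be (median >= 1, sigma >= 0)")
        if self.median_gap_hours <= 0 or self.span_days <= 0:
            raise ConfigError("median_gap_hours and span_days must be positive")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["count_dist"] = list(self.count_dist)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "count_dist" in d:
            d["count_dist"] = tuple(d["count_dist"])
        return cls(**d)


@dataclass(frozen=True)
class UserProfile:
    """Latent per-user state drawn by the generator."""

    user_id: str
    signup_time: pd.Timestamp
    signup_quantile: float
    n_assessments: int
    u_i: float
    gap_scale: float


def _feature_names(config: GeneratorConfig) -> tuple[list[str], list[str]]:
    inf = [f"feat_inf{j}" for j in range(config.n_informative)]
    noise = [f"feat_noise{j}" for j in range(config.n_noise)]
    return inf, noise


def _categorical_targets(config: GeneratorConfig) -> list[str]:
    # the last n_categorical features (noise first, then informative) become
    # 4-level categoricals, exercising mode-based imputation and encoding
    inf, noise = _feature_names(config)
    ordered = noise[::-1] + inf[::-1]
    return ordered[: config.n_categorical]


def generate(config: GeneratorConfig) -> EMADataset:
    """Draw one synthetic EMA study; fully deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_users

    # sign-up times uniform over the study span; users indexed by sign-up order
    signup_days = np.sort(rng.uniform(0.0, config.span_days, size=n))
    q = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    width = len(str(max(n - 1, 1)))
    user_ids = [f"u{idx:0{width}d}" for idx in range(n)]

    med, csigma = config.count_dist
    counts = np.maximum(
        1, np.rint(rng.lognormal(np.log(med), csigma, size=n)).astype(int)
    )
    u_i = rng.normal(0.0, np.sqrt(config.icc), size=n)
    gap_scale = rng.lognormal(0.0, config.gap_scale_sigma, size=n)

    within = 1.0 - config.icc
    v_ar = config.ar_share * within
    v_e = (1.0 - config.ar_share) * within
    innov_sd = np.sqrt(v_ar * (1.0 - config.rho**2))

    inf_names, noise_names = _feature_names(config)
    if np.isinf(config.feature_snr):
        feat_noise_sd = 0.0
    else:
        feat_noise_sd = np.sqrt(1.0 / config.feature_snr)

    rows: list[pd.DataFrame] = []
    profiles: list[UserProfile] = []
    for i in range(n):
        m = counts[i]
        s = np.empty(m)
        s[0] = rng.normal(0.0, np.sqrt(v_ar)) if v_ar > 0 else 0.0
        for t in range(1, m):
            s[t] = config.rho * s[t - 1] + rng.normal(0.0, innov_sd)
        e = rng.normal(0.0, np.sqrt(v_e), size=m) if v_e > 0 else np.zeros(m)
        y = u_i[i] + config.drift_strength * q[i] + s + e

        gaps_h = rng.lognormal(
            np.log(config.median_gap_hours * gap_scale[i]), config.gap_sigma, size=m
        )
        gaps_h[0] = 0.0
        offset_s = np.floor(signup_days[i] * 86400.0 + np.cumsum(gaps_h) * 3600.0)
        times = _EPOCH + pd.to_timedelta(offset_s, unit="s")

        # stable per-user answer-style intercepts for every feature
        b = rng.normal(0.0, config.feature_user_sd, size=config.n_informative + config.n_noise)
        feats = {}
        for j, name in enumerate(inf_names):
            feats[name] = y + b[j] + rng.normal(0.0, feat_noise_sd, size=m)
        for j, name in enumerate(noise_names):
            feats[name] = b[config.n_informative + j] + rng.normal(0.0, 1.0, size=m)

        rows.append(
            pd.DataFrame(
                {
                    ID_COL: [f"{user_ids[i]}-a{t:04d}" for t in range(m)],
                    USER_COL: user_ids[i],
                    TIME_COL: times,
                    TARGET_COL: norm.cdf(y),
                    **feats,
                }
            )
        )
        profiles.append(
            UserProfile(
                user_id=user_ids[i],
                signup_time=times[0],
                signup_quantile=float(q[i]),
                n_assessments=int(m),
                u_i=float(u_i[i]),
                gap_scale=float(gap_scale[i]),
            )
        )

    frame = pd.concat(rows, ignore_index=True)

    # derive categorical features by dataset-level quantile binning (4 levels)
    cat_names = _categorical_targets(config)
    for name in cat_names:
        col = frame[name].to_numpy()
        edges = np.quantile(col, [0.25, 0.5, 0.75])
        codes = np.searchsorted(edges, col, side="right")
        frame[name] = np.array([f"q{c}" for c in codes], dtype=object)

    # MCAR masking of feature answers
    all_feats = inf_names + noise_names
    if config.missing_rate > 0:
        mask = rng.random((len(frame), len(all_feats))) < config.missing_rate
        for j, name in enumerate(all_feats):
            frame.loc[mask[:, j], name] = np.nan

    specs = tuple(
        FeatureSpec(name, KIND_CATEGORICAL if name in cat_names else KIND_NUMERIC)
        for name in all_feats
    )
    dataset = EMADataset(
        frame,
        FeatureSchema(specs),
        TargetSpec(name="target", raw_kind="continuous_0_1", n_classes=config.n_classes),
        dataset_label=config.dataset_label,
    )
    dataset.profiles = profiles  # type: ignore[attr-defined]
    return dataset


def drift_profile(dataset: EMADataset, n_bins: int) -> np.ndarray:
    """Mean binned target per sign-up-quantile bin.

    Diagnostic for injected cohort drift: with no drift the per-bin means
    agree within sampling error; with positive drift later bins sit higher.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    users = dataset.users_by_signup()
    rank = {u: k for k, u in enumerate(users)}
    n = len(users)
    f = dataset.frame
    quant = f[USER_COL].map(rank).to_numpy() / max(n - 1, 1)
    bins = np.minimum((quant * n_bins).astype(int), n_bins - 1)
    n_classes = dataset.target_spec.n_classes
    if dataset.target_spec.raw_kind == "continuous_0_1":
        classes = np.array([bin_target(v, n_classes) for v in f[TARGET_COL]])
    else:
        classes = f[TARGET_COL].to_numpy().astype(int)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            out[b] = classes[sel].mean()
    return out
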
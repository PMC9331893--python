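"""Seeded synthetic Likert-survey generation.

Emulates a large adolescent smartphone-use survey: 20 ordinal (1-4)
content-frequency items, three relationship scales measured by 11 + 10 + 5
ordinal items, and five covariates (gender, grade, subjective SES, objective
SES, daily screen time).  The data-generating process is a threshold-
discretized linear factor model:

* content-use propensities are equicorrelated standard normals, cut at
  ``likert_thresholds`` into {1..4};
* each relationship latent score is a linear combination of the
  *standardized observed* content items and covariates plus Gaussian noise
  scaled so the latent score has (approximately) unit variance;
* each scale item loads on its latent score with a common loading and is
  discretized to {1..4}.

Because discretization attenuates correlations, :func:`calibrate_effects`
rescales latent effects so the post-discretization standardized regression
slope matches the configured target.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "CONTENT_COLUMNS",
    "CONTENT_ALIASES",
    "SCALE_COLUMNS",
    "OUTCOME_COLUMNS",
    "COVARIATE_COLUMNS",
    "GeneratorConfig",
    "build_default_config",
    "generate_survey",
    "apply_missingness",
    "calibrate_effects",
    "write_survey_csv",
    "read_survey_csv",
    "load_config",
    "save_config",
]

N_CONTENT = 20
CONTENT_COLUMNS = [f"content_{i:02d}" for i in range(1, N_CONTENT + 1)]

# Human-readable aliases for the 20 content-frequency items, in fixed order.
CONTENT_ALIASES = {
    "content_01": "making_calls",
    "content_02": "browsing_social_media",
    "content_03": "posting_sharing",
    "content_04": "chatting_online",
    "content_05": "watching_tv",
    "content_06": "watching_clips",
    "content_07": "playing_games",
    "content_08": "listening_to_music",
    "content_09": "browsing_news",
    "content_10": "reading_online_novels",
    "content_11": "taking_online_courses",
    "content_12": "finishing_homework",
    "content_13": "using_search_engines",
    "content_14": "using_dictionaries",
    "content_15": "using_utilities",
    "content_16": "using_cameras",
    "content_17": "using_fitness_apps",
    "content_18": "obtaining_life_information",
    "content_19": "making_payments",
    "content_20": "consuming_online",
}
ALIAS_TO_COLUMN = {v: k for k, v in CONTENT_ALIASES.items()}

OUTCOME_COLUMNS = ["parent_child", "peer", "teacher_student"]
_SCALE_PREFIXES = {"parent_child": "pc", "peer": "pr", "teacher_student": "ts"}

COVARIATE_COLUMNS = ["gender", "grade", "sses", "oses", "screen_time"]

# Composition of the survey the generator emulates: 46,018 smartphone
# owners, 34,578 in grade 8 and 23,946 male.
DEFAULT_N = 46_018
P_GRADE8 = 34_578 / 46_018
P_MALE = 23_946 / 46_018
DEFAULT_MISSING_RATE = 0.0415

# Neutral marginals: equal-probability cuts of the standard normal.
_LIKERT4 = stats.norm.ppf([0.25, 0.5, 0.75])
_SSES5 = stats.norm.ppf(np.arange(1, 5) / 5)
_SCREEN8 = stats.norm.ppf(np.arange(1, 8) / 8)


def _scale_columns(counts: tuple[int, int, int]) -> dict[str, list[str]]:
    return {
        out: [f"{_SCALE_PREFIXES[out]}{i:02d}" for i in range(1, m + 1)]
        for out, m in zip(OUTCOME_COLUMNS, counts)
    }


SCALE_COLUMNS = _scale_columns((11, 10, 5))
ALL_SCALE_ITEMS = [c for cols in SCALE_COLUMNS.values() for c in cols]


@dataclass
class GeneratorConfig:
    """Parameters of the survey generator.

    ``effect_matrix`` holds true standardized effects of each of the 20
    content items on the three relationship latent scores (rows = content
    items, columns = parent-child, peer, teacher-student).
    ``covariate_effects`` is outcome x covariate (3 x 5), ordered as
    ``COVARIATE_COLUMNS``.
    """

    n_participants: int = DEFAULT_N
    effect_matrix: np.ndarray = field(
        default_factory=lambda: np.zeros((N_CONTENT, 3))
    )
    covariate_effects: np.ndarray = field(default_factory=lambda: np.zeros((3, 5)))
    content_intercorrelation: float = 0.4
    scale_item_counts: tuple[int, int, int] = (11, 10, 5)
    item_loading: float = 0.75
    likert_thresholds: np.ndarray = field(default_factory=lambda: _LIKERT4.copy())
    missing_rate: float = DEFAULT_MISSING_RATE
    p_grade8: float = P_GRADE8
    p_male: float = P_MALE
    ownership_rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
        self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)
        self.likert_thresholds = np.asarray(self.likert_thresholds, dtype=float)
        self.scale_item_counts = tuple(int(m) for m in self.scale_item_counts)

    def validate(self) -> None:
        if self.effect_matrix.shape != (N_CONTENT, 3):
            raise ValueError(
                f"effect_matrix must be {N_CONTENT}x3, got {self.effect_matrix.shape}"
            )
        if self.covariate_effects.shape != (3, len(COVARIATE_COLUMNS)):
            raise ValueError(
                "covariate_effects must be 3x5, got "
                f"{self.covariate_effects.shape}"
            )
        if np.any(np.abs(self.effect_matrix) > 1):
            raise ValueError("effect_matrix entries must lie in [-1, 1]")
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.content_intercorrelation < 1:
            raise ValueError("content_intercorrelation must lie in [0, 1)")
        if not 0 < self.item_loading <= 1:
            raise ValueError("item_loading must lie in (0, 1]")
        if len(self.scale_item_counts) != 3 or any(
            m < 1 for m in self.scale_item_counts
        ):
            raise ValueError("scale_item_counts must be three positive integers")
        if np.any(np.diff(self.likert_thresholds) <= 0):
            raise ValueError("likert_thresholds must be strictly increasing")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_matrix"] = self.effect_matrix.tolist()
        d["covariate_effects"] = self.covariate_effects.tolist()
        d["likert_thresholds"] = self.likert_thresholds.tolist()
        d["scale_item_counts"] = list(self.scale_item_counts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        effects = d.pop("effects", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if effects is not None:
            cfg = _apply_effect_entries(cfg, effects)
        cfg.validate()
        return cfg


def _apply_effect_entries(cfg: GeneratorConfig, entries: list[dict]) -> GeneratorConfig:
    """Sparse effect shorthand: [{predictor, outcome, value}, ...].

    ``predictor`` may be a canonical column name or an alias; ``outcome``
    may be an outcome name or ``all``.
    """
    mat = cfg.effect_matrix.copy()
    for e in entries:
        pred = e["predictor"]
        col = ALIAS_TO_COLUMN.get(pred, pred)
        if col not in CONTENT_COLUMNS:
            raise ValueError(f"unknown predictor {pred!r}")
        k = CONTENT_COLUMNS.index(col)
        outs = OUTCOME_COLUMNS if e["outcome"] == "all" else [e["outcome"]]
        for out in outs:
            if out not in OUTCOME_COLUMNS:
                raise ValueError(f"unknown outcome {out!r}")
            mat[k, OUTCOME_COLUMNS.index(out)] = float(e["value"])
    return cfg.replace(effect_matrix=mat)


def build_default_config(**overrides) -> GeneratorConfig:
    """Default configuration mirroring the emulated survey: N = 46,018,
    4.15% missingness, 20 content items, scale item counts (11, 10, 5),
    all true effects zero."""
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generation


def _discretize(latent: np.ndarray, thresholds: np.ndarray, base: int = 1) -> np.ndarray:
    return np.searchsorted(thresholds, latent, side="left") + base


def _zscore_cols(arr: np.ndarray) -> np.ndarray:
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (arr - mu) / sd


def generate_survey(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate one complete (no-missing) synthetic survey table.

    Returns a DataFrame with columns ``participant_id``, the five
    covariates, ``content_01..content_20`` and the 26 scale items
    (pc01..pc11, pr01..pr10, ts01..ts05).  Deterministic in
    ``(config, seed)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_participants

    gender = (rng.random(n) < config.p_male).astype(int)  # male = 1
    grade = np.where(rng.random(n) < config.p_grade8, 8, 4)
    sses = _discretize(rng.standard_normal(n), _SSES5)
    oses = rng.standard_normal(n)
    screen_time = _discretize(rng.standard_normal(n), _SCREEN8, base=0)

    # equicorrelated content propensities via a single common factor
    rho = config.content_intercorrelation
    common = rng.standard_normal(n)
    uniq = rng.standard_normal((n, N_CONTENT))
    latent_content = np.sqrt(rho) * common[:, None] + np.sqrt(1 - rho) * uniq
    content = _discretize(latent_content, config.likert_thresholds)

    zx = _zscore_cols(content.astype(float))
    zc = _zscore_cols(
        np.column_stack(
            [gender, (grade == 8).astype(float), sses, oses, screen_time]
        ).astype(float)
    )

    data = {
        "participant_id": np.arange(1, n + 1),
        "gender": gender,
        "grade": grade,
        "sses": sses,
        "oses": oses,
        "screen_time": screen_time,
    }
    if config.ownership_rate is not None:
        data["owns_smartphone"] = (rng.random(n) < config.ownership_rate).astype(int)

    for k in range(N_CONTENT):
        data[CONTENT_COLUMNS[k]] = content[:, k]

    scale_cols = _scale_columns(config.scale_item_counts)
    lam = config.item_loading
    for j, out in enumerate(OUTCOME_COLUMNS):
        systematic = zx @ config.effect_matrix[:, j] + zc @ config.covariate_effects[j]
        v = systematic.var(ddof=1) if n > 1 else 0.0
        if v >= 1:
            raise ValueError(
                f"configured effects for outcome {out!r} imply systematic "
                f"variance {v:.3f} >= 1; reduce effect sizes"
            )
        latent = systematic + np.sqrt(1 - v) * rng.standard_normal(n)
        noise = rng.standard_normal((n, len(scale_cols[out])))
        items = lam * latent[:, None] + np.sqrt(1 - lam**2) * noise
        items = _discretize(items, config.likert_thresholds)
        for i, col in enumerate(scale_cols[out]):
            data[col] = items[:, i]

    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# missingness


def apply_missingness(
    data: pd.DataFrame,
    rate: float,
    seed: int,
    mechanism: str = "mcar",
    driver: str = "grade",
    driver_ratio: float = 2.0,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Mask cells at random.

    ``mcar``: every eligible cell is masked independently with probability
    ``rate``.  ``mar``: the per-cell probability depends on ``driver``
    (rows in the top driver level get ``driver_ratio`` times the
    probability of the rest, rescaled so the overall expected rate equals
    ``rate``); the driver column itself is never masked.

    All analysis columns are eligible; only ``participant_id`` (and an
    ownership flag, if present) are exempt.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if mechanism not in ("mcar", "mar"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    out = data.copy()
    if rate == 0:
        return out
    if columns is None:
        columns = [
            c for c in data.columns if c not in ("participant_id", "owns_smartphone")
        ]
    if mechanism == "mar":
        columns = [c for c in columns if c != driver]

    rng = np.random.default_rng(seed)
    n = len(data)
    if mechanism == "mcar":
        p_row = np.full(n, rate)
    else:
        high = (data[driver].to_numpy() == data[driver].max()).astype(float)
        share_high = high.mean()
        # p_low * (1 - share) + ratio * p_low * share == rate
        p_low = rate / (1 - share_high + driver_ratio * share_high)
        p_row = np.where(high == 1, driver_ratio * p_low, p_low)
        p_row = np.clip(p_row, 0, 0.999)

    mask = rng.random((n, len(columns))) < p_row[:, None]
    block = out[columns].astype(float).to_numpy()
    block[mask] = np.nan
    out[columns] = block
    return out


# ---------------------------------------------------------------------------
# effect calibration

_CALIBRATION_SEED = 987_654_321


def _marginal_slope(config: GeneratorConfig, k: int, j: int, n: int, seed: int) -> float:
    """Standardized simple-regression slope of outcome-j scale total on
    content item k, on a complete sample of size n."""
    df = generate_survey(config.replace(n_participants=n), seed=seed)
    total = df[_scale_columns(config.scale_item_counts)[OUTCOME_COLUMNS[j]]].sum(axis=1)
    x = df[CONTENT_COLUMNS[k]]
    return float(np.corrcoef(total, x)[0, 1])


def calibrate_effects(
    config: GeneratorConfig,
    n_calib: int = 100_000,
    seed: int = _CALIBRATION_SEED,
    tol: float = 1e-3,
    max_iter: int = 40,
) -> GeneratorConfig:
    """Rescale latent effects so observed standardized slopes hit their targets.

    Discretizing the scale items attenuates the standardized slope of a
    scale total on a content item below the configured latent effect.  For
    every nonzero entry of ``effect_matrix``, a bisection on a fixed-seed
    calibration sample of ``n_calib`` rows finds the latent effect whose
    post-discretization marginal slope matches the configured target within
    ``tol``.  Exact when each outcome has at most one nonzero effect (each
    entry is calibrated in isolation); approximate otherwise.
    """
    config.validate()
    targets = config.effect_matrix
    out = targets.copy()
    for k, j in zip(*np.nonzero(targets)):
        t = abs(targets[k, j])
        probe_mat = np.zeros_like(targets)

        def f(b: float) -> float:
            probe_mat[k, j] = b
            probe = config.replace(effect_matrix=probe_mat)
            return _marginal_slope(probe, k, j, n_calib, seed) - t

        lo, f_lo = 0.0, f(0.0)
        cov_var = float(np.sum(config.covariate_effects[j] ** 2))
        cap = np.sqrt(max(0.95 - cov_var, 0.0))
        hi = min(1.5 * t + 0.05, cap)
        while f(hi) < 0 and hi < cap:
            hi = min(2 * hi, cap)
        if f(hi) < 0:
            raise ValueError(
                f"cannot calibrate effect ({k}, {j}) = {targets[k, j]:+.3f}: "
                "target slope unreachable under the configured measurement model"
            )
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            fm = f(mid)
            if abs(fm) < tol:
                lo = hi = mid
                break
            if fm < 0:
                lo = mid
            else:
                hi = mid
        out[k, j] = np.sign(targets[k, j]) * 0.5 * (lo + hi)
    return config.replace(effect_matrix=out)


# ---------------------------------------------------------------------------
# I/O


def write_survey_csv(data: pd.DataFrame, path) -> None:
    """RFC-4180 CSV, UTF-8, empty field = missing."""
    data.to_csv(path, index=False, na_rep="")


def read_survey_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise ValueError("not a survey CSV: missing participant_id column")
    return df


def load_config(path) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError("config file must contain a mapping")
    return GeneratorConfig.from_dict(d)


def save_config(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
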
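"""Synthetic AECOPD cohort generation, cleaning filters, and hospital partitioning.

The real study population (a single tertiary hospital's COPD admissions) is
private, so this module emulates its published summary structure: two severity
groups (mild n=220, severe n=188), exact per-group sex counts, and eight vital
signs whose per-group means are published only as normal-theory 95% confidence
intervals.  Each continuous feature is drawn from a truncated normal whose
moments are recovered by inverting the CI of the mean at the group size; the
remaining columns (to a 40-feature modeling width) are uninformative
standard-normal filler, identically distributed in both groups, so all
discriminative signal comes from the published vitals.

A cohort is a plain :class:`pandas.DataFrame` with columns
``record_id,label,sex,f001..f040`` (missing cells are NaN, written as empty
fields in CSV).  ``label`` is 0 for the mild group and 1 for the severe group;
severe is the positive class everywhere downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: two-sided 97.5% normal quantile used by normal-theory 95% CIs of the mean
Z95 = 1.959964

ID_COL = "record_id"
LABEL_COL = "label"
SEX_COL = "sex"
META_COLS = (ID_COL, LABEL_COL, SEX_COL)

MILD, SEVERE = 0, 1
MALE, FEMALE = "male", "female"


class CohortError(ValueError):
    """Invalid cohort configuration or an empty result after filtering."""


@dataclass(frozen=True)
class FeatureSpec:
    """A continuous clinical feature described by per-group 95% CIs of the mean.

    Parameters
    ----------
    name
        Human-readable feature name (the CSV column is positional, ``fNNN``).
    mild_ci, severe_ci
        ``(lower, upper)`` 95% confidence interval of the group mean.
    bounds
        Optional broad physiological truncation bounds for the draws.
    """

    name: str
    mild_ci: tuple[float, float]
    severe_ci: tuple[float, float]
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.mild_ci, self.severe_ci):
            if lo > hi:
                raise CohortError(f"{self.name}: reversed CI ({lo}, {hi})")
        if self.bounds is not None:
            blo, bhi = self.bounds
            for lo, hi in (self.mild_ci, self.severe_ci):
                mid = 0.5 * (lo + hi)
                if not (blo <= mid <= bhi):
                    raise CohortError(
                        f"{self.name}: bounds {self.bounds} do not bracket CI midpoint {mid}"
                    )

    def ci(self, group: int) -> tuple[float, float]:
        return self.mild_ci if group == MILD else self.severe_ci


#: Published per-group 95% CIs of the mean for the eight summarised vitals,
#: with broad physiological truncation bounds for the synthetic draws.
DEFAULT_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("age", (77.6, 80.0), (80.2, 82.8), bounds=(18.0, 115.0)),
    # The CI of the hospitalization count inverts to sd ~ 7 at mean ~ 6.5; a
    # floor at zero would shift the mean by ~2, so this feature is unbounded
    # under the normal marginal model (negative draws are a stated unrealism).
    FeatureSpec("n_hospitalizations", (3.3, 3.9), (5.5, 7.5), bounds=None),
    FeatureSpec("systolic_pressure", (130.6, 135.6), (128.1, 135.1), bounds=(40.0, 260.0)),
    FeatureSpec("diastolic_pressure", (74.2, 77.4), (72.5, 76.3), bounds=(30.0, 160.0)),
    FeatureSpec("temperature", (36.7, 36.9), (36.6, 36.8), bounds=(34.0, 43.0)),
    FeatureSpec("pulse", (90.5, 94.5), (96.6, 101.4), bounds=(20.0, 220.0)),
    FeatureSpec("respiratory_rate", (21.3, 22.1), (23.8, 25.6), bounds=(0.0, 80.0)),
)

#: Exact male counts per group (mild, severe); females are the remainder.
DEFAULT_MALE_COUNTS: dict[int, int] = {MILD: 188, SEVERE: 157}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the published cohort exactly in structure: 220 mild +
    188 severe records (408 total), 345 male / 63 female, 40 feature columns.
    """

    n_mild: int = 220
    n_severe: int = 188
    features: tuple[FeatureSpec, ...] = DEFAULT_FEATURES
    n_features_total: int = 40
    male_counts: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MALE_COUNTS)
    )
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mild <= 0 or self.n_severe <= 0:
            raise CohortError("group sizes must be positive")
        if self.n_features_total < len(self.features):
            raise CohortError(
                "n_features_total smaller than the number of named features"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise CohortError("missing_rate must lie in [0, 1)")
        for grp, n in ((MILD, self.n_mild), (SEVERE, self.n_severe)):
            if not (0 <= self.male_counts[grp] <= n):
                raise CohortError("male count exceeds group size")

    @property
    def n_filler(self) -> int:
        return self.n_features_total - len(self.features)

    @property
    def n_records(self) -> int:
        return self.n_mild + self.n_severe

    def group_size(self, group: int) -> int:
        return self.n_mild if group == MILD else self.n_severe

    def feature_columns(self) -> dict[str, str]:
        """Map feature names to their positional CSV column (f001..)."""
        return {
            spec.name: f"f{i + 1:03d}" for i, spec in enumerate(self.features)
        }

    def scaled(self, factor: float) -> "CohortConfig":
        """A config with group sizes (and exact sex counts) scaled up by `factor`,
        preserving the mild:severe and male:female proportions."""
        n_mild = int(np.ceil(self.n_mild * factor))
        n_severe = int(np.ceil(self.n_severe * factor))
        male = {
            MILD: int(round(self.male_counts[MILD] / self.n_mild * n_mild)),
            SEVERE: int(round(self.male_counts[SEVERE] / self.n_severe * n_severe)),
        }
        return replace(self, n_mild=n_mild, n_severe=n_severe, male_counts=male)


def feature_cols(cohort: pd.DataFrame) -> list[str]:
    """The feature columns of a cohort frame (everything but the metadata)."""
    return [c for c in cohort.columns if c not in META_COLS]


def ci_to_moments(ci_lower: float, ci_upper: float, n: int) -> tuple[float, float]:
    """Invert a normal-theory 95% CI of the mean into (mean, sd).

    The interval ``mean ± z·sd/√n`` with z = 1.959964 gives
    ``sd = (half-width / z)·√n``.

    >>> mean, sd = ci_to_moments(77.6, 80.0, 220)
    >>> round(mean, 1), round(sd, 2)
    (78.8, 9.08)
    """
    if ci_lower > ci_upper:
        raise CohortError(f"reversed interval ({ci_lower}, {ci_upper})")
    if n < 2:
        raise CohortError("n must be at least 2")
    mean = 0.5 * (ci_lower + ci_upper)
    sd = (ci_upper - ci_lower) / 2.0 / Z95 * np.sqrt(n)
    return mean, sd


def draw_feature(
    spec: FeatureSpec, group: int, n: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw `size` values of one feature for one group at CI-group-size `n`."""
    mean, sd = ci_to_moments(*spec.ci(group), n)
    if sd == 0.0:
        return np.full(size, mean)
    if spec.bounds is None:
        return rng.normal(mean, sd, size)
    lo, hi = spec.bounds
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic cohort matching the configured summary structure.

    Continuous features are moment-matched truncated-normal draws per group;
    sex is assigned by exact per-group counts (not Bernoulli), so the default
    cohort reproduces the printed 345 male / 63 female totals exactly.
    Identical config (including seed) yields byte-identical output.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    ncols = config.n_features_total

    frames = []
    for group in (MILD, SEVERE):
        n = config.group_size(group)
        cols: dict[str, np.ndarray] = {}
        for i, spec in enumerate(config.features):
            cols[f"f{i + 1:03d}"] = draw_feature(spec, group, n, n, rng)
        for i in range(len(config.features), ncols):
            cols[f"f{i + 1:03d}"] = rng.normal(0.0, 1.0, n)
        n_male = config.male_counts[group]
        sex = np.array([MALE] * n_male + [FEMALE] * (n - n_male), dtype=object)
        rng.shuffle(sex)
        frame = pd.DataFrame(cols)
        frame.insert(0, SEX_COL, sex)
        frame.insert(0, LABEL_COL, group)
        frames.append(frame)

    cohort = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(cohort))
    cohort = cohort.iloc[order].reset_index(drop=True)
    cohort.insert(0, ID_COL, [f"P{i + 1:04d}" for i in range(len(cohort))])

    if config.missing_rate > 0.0:
        fcols = feature_cols(cohort)
        mask = rng.random((len(cohort), len(fcols))) < config.missing_rate
        values = cohort[fcols].to_numpy(dtype=float)
        values[mask] = np.nan
        cohort[fcols] = values
    return cohort


def preprocess(cohort: pd.DataFrame, missing_threshold: float = 0.10) -> pd.DataFrame:
    """Apply the cleaning filters: drop leaky features, then incomplete records.

    A feature is removed when its fraction of missing cells strictly exceeds
    ``missing_threshold`` (a feature at exactly the threshold survives); any
    record still containing a missing cell is then excluded.  The counts
    dropped at each stage are stored in ``result.attrs["preprocess"]``.
    """
    if not (0.0 <= missing_threshold <= 1.0):
        raise CohortError("missing_threshold must lie in [0, 1]")
    fcols = feature_cols(cohort)
    frac = cohort[fcols].isna().mean()
    dropped_features = list(frac.index[frac > missing_threshold])
    kept = cohort.drop(columns=dropped_features)
    if not feature_cols(kept):
        raise CohortError("all features dropped at the feature-filter stage")
    complete = kept.dropna(axis=0)
    n_dropped_records = len(kept) - len(complete)
    if complete.empty:
        raise CohortError("no complete records left at the record-filter stage")
    result = complete.reset_index(drop=True)
    result.attrs["preprocess"] = {
        "dropped_features": dropped_features,
        "n_dropped_features": len(dropped_features),
        "n_dropped_records": n_dropped_records,
    }
    logger.info(
        "preprocess: dropped %d features, %d records",
        len(dropped_features),
        n_dropped_records,
    )
    return result


def partition(
    cohort: pd.DataFrame, k: int, samples_per_client: int, seed: int
) -> list[pd.DataFrame]:
    """Simple random sampling without replacement into k disjoint client shards."""
    if k < 1 or samples_per_client < 1:
        raise CohortError("k and samples_per_client must be positive")
    total = k * samples_per_client
    if total > len(cohort):
        raise CohortError(
            f"requested {total} records but cohort has only {len(cohort)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(cohort), size=total, replace=False)
    return [
        cohort.iloc[chosen[i * samples_per_client : (i + 1) * samples_per_client]]
        .reset_index(drop=True)
        for i in range(k)
    ]


@dataclass
class ClientShard:
    """One simulated hospital's private data: a train/test split of its shard."""

    client_id: int
    train: pd.DataFrame
    test: pd.DataFrame

    def arrays(self, standardize: bool = True):
        """Materialise (X_train, y_train, X_test, y_test) as float arrays.

        Standardisation uses the client's OWN training-set mean/sd (applied
        unchanged to the test set); no cross-client statistics are shared.
        """
        fcols = feature_cols(self.train)
        Xtr = self.train[fcols].to_numpy(dtype=float)
        Xte = self.test[fcols].to_numpy(dtype=float)
        ytr = self.train[LABEL_COL].to_numpy(dtype=float)
        yte = self.test[LABEL_COL].to_numpy(dtype=float)
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0.0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        return Xtr, ytr, Xte, yte


def train_test_split_shard(
    shard: pd.DataFrame,
    ratio: tuple[float, float] = (7.0, 3.0),
    seed: int = 0,
    client_id: int = 0,
) -> ClientShard:
    """Random train/test split of a shard at the given ratio.

    The train size is ``floor(train_share · n)``, clamped so that both sides
    are nonempty whenever the shard has at least two records.
    """
    tr, te = ratio
    if tr <= 0 or te <= 0:
        raise CohortError("ratio shares must be positive")
    n = len(shard)
    if n < 2:
        raise CohortError("cannot split a shard with fewer than 2 records")
    share = tr / (tr + te)
    n_train = min(max(int(np.floor(share * n)), 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = shard.iloc[order[:n_train]].reset_index(drop=True)
    test = shard.iloc[order[n_train:]].reset_index(drop=True)
    return ClientShard(client_id=client_id, train=train, test=test)


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (UTF-8, missing cells as empty fields)."""
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    return pd.read_csv(path)


def simulate_mean_ci(
    spec: FeatureSpec,
    group: int,
    n: int,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical 95% CI of the group mean under the generator's draw model.

    Simulates ``n_replicates`` groups of size ``n`` and returns the 2.5/97.5
    percentiles of the replicate means — the forward check that the CI
    inversion recovers the configured interval.
    """
    rng = np.random.default_rng(seed)
    draws = draw_feature(spec, group, n, n_replicates * n, rng)
    means = draws.reshape(n_replicates, n).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)
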
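"""Lesion-level evaluation pipeline.

Per-feature and multi-feature logistic discrimination of culprit vs
nonculprit lesions, scored by AUC under leave-pair-out cross-validation
(LPOCV); Shapley decomposition of the combined model's AUC above chance;
bootstrap AUC comparison between models; Youden-J dichotomization;
Kaplan-Meier curves with a two-group log-rank test; and the per-feature
group-comparison table (Welch's t for continuous features, Yates-corrected
chi-squared for binary flags).

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
Welch and chi-squared tests to scipy.stats; apparent AUC to scikit-learn.
The logistic fitting and the LPOCV pair loop live in
:mod:`cvikit.logistic`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .logistic import LogisticScorer, fit_logistic_array, lpocv_pair_scores

__all__ = [
    "ModelSpec",
    "LpocvResult",
    "BootstrapResult",
    "YoudenResult",
    "KmResult",
    "fit_logistic",
    "apparent_auc",
    "auc_lpocv",
    "shapley_delta_auc",
    "bootstrap_auc",
    "youden_cutoff",
    "km_logrank",
    "group_compare",
    "evaluate_cohort",
]

CONTINUOUS_FEATURES = ("ds", "length_mm", "ffr", "dffr", "wss", "aps", "cvi")
CATEGORICAL_FEATURES = ("lap", "sc", "pr", "nrs")

EXACT_SHAPLEY_MAX_K = 12


@dataclass(frozen=True)
class ModelSpec:
    """A logistic model over a feature subset of the cohort table."""

    features: tuple[str, ...]
    standardize: bool = True
    ridge: float = 1e-8
    name: str | None = None

    def __post_init__(self):
        feats = tuple(self.features)
        object.__setattr__(self, "features", feats)
        if len(feats) == 0:
            raise ValueError("feature subset must be non-empty")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")
        if self.name is None:
            object.__setattr__(self, "name", "+".join(feats))

    def design(self, df: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in df.columns]
        if missing:
            raise KeyError(f"cohort table lacks feature column(s): {missing}")
        return df.loc[:, list(self.features)].to_numpy(dtype=float)


def _labels(df: pd.DataFrame, label: str = "culprit") -> np.ndarray:
    y = df[label].to_numpy(dtype=float)
    if not np.all(np.isin(y, [0.0, 1.0])):
        raise ValueError("labels must be binary 0/1")
    return y


def fit_logistic(df: pd.DataFrame, spec: ModelSpec, label: str = "culprit") -> LogisticScorer:
    """Fit the spec's logistic model on the cohort table; returns a scorer."""
    return fit_logistic_array(
        spec.design(df), _labels(df, label), ridge=spec.ridge, standardize=spec.standardize
    )


def apparent_auc(df: pd.DataFrame, spec: ModelSpec, label: str = "culprit") -> float:
    """In-sample AUC of the spec's model (fit and scored on the same data)."""
    scorer = fit_logistic(df, spec, label)
    return float(roc_auc_score(_labels(df, label), scorer.decision(spec.design(df))))


@dataclass(frozen=True)
class LpocvResult:
    auc: float
    n_pairs: int
    n_skipped: int


def auc_lpocv(df: pd.DataFrame, spec: ModelSpec, label: str = "culprit") -> LpocvResult:
    """Leave-pair-out cross-validated AUC.

    Every (culprit, nonculprit) pair is held out in turn, the model is refit
    on the remaining n-2 lesions and the pair is scored: credit 1 if the
    culprit scores higher, 0.5 on a tie, 0 otherwise; the AUC is the mean
    credit. Pairs whose training set degenerates to a single class are
    skipped and counted.
    """
    X = spec.design(df)
    y = _labels(df, label)
    n_pos = int(y.sum())
    n_neg = int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one record per class")
    if n_pos < 2 or n_neg < 2:
        # every leave-pair-out training set is single-class
        return LpocvResult(auc=float("nan"), n_pairs=0, n_skipped=n_pos * n_neg)
    _, _, s_pos, s_neg = lpocv_pair_scores(
        X, y, ridge=spec.ridge, standardize=spec.standardize
    )
    credit = np.where(s_pos > s_neg, 1.0, np.where(s_pos == s_neg, 0.5, 0.0))
    return LpocvResult(auc=float(credit.mean()), n_pairs=credit.size, n_skipped=0)


def _value_function(df, features, mode, label):
    def v(subset: frozenset) -> float:
        if not subset:
            return 0.5
        spec = ModelSpec(features=tuple(sorted(subset)))
        if mode == "apparent":
            return apparent_auc(df, spec, label)
        if mode == "lpocv":
            return auc_lpocv(df, spec, label).auc
        raise ValueError("value_fn_mode must be 'apparent' or 'lpocv'")

    return v


def shapley_delta_auc(
    df: pd.DataFrame,
    features: list[str] | tuple[str, ...],
    value_fn_mode: str = "apparent",
    mc_samples: int | None = None,
    seed: int | None = None,
    label: str = "culprit",
) -> dict[str, float]:
    """Per-feature Shapley attribution of the model's AUC above chance.

    The coalition value ``v(S)`` is the AUC of the logistic model on feature
    subset ``S`` (``v(empty) = 0.5``); the attribution of feature ``i`` is
    the Shapley value over all subsets. Exact enumeration over the 2^k
    subsets for k <= 12 (with apparent-AUC value function by default; LPOCV
    is available but costly); beyond that, permutation-sampling Monte Carlo
    with ``mc_samples`` permutations and an explicit ``seed``.

    Efficiency holds by construction: the attributions sum to
    ``v(all) - 0.5``.
    """
    features = list(features)
    k = len(features)
    if k == 0:
        raise ValueError("feature list must be non-empty")
    v = _value_function(df, features, value_fn_mode, label)
    cache: dict[frozenset, float] = {}

    def val(s: frozenset) -> float:
        if s not in cache:
            cache[s] = v(s)
        return cache[s]

    phi = dict.fromkeys(features, 0.0)
    if k <= EXACT_SHAPLEY_MAX_K and mc_samples is None:
        for i, f in enumerate(features):
            others = [g for g in features if g != f]
            for r in range(len(others) + 1):
                w = math.factorial(r) * math.factorial(k - r - 1) / math.factorial(k)
                for combo in itertools.combinations(others, r):
                    s = frozenset(combo)
                    phi[f] += w * (val(s | {f}) - val(s))
        return phi
    if mc_samples is None:
        raise ValueError(f"k={k} exceeds the exact threshold; mc_samples is required")
    if seed is None:
        raise ValueError("Monte-Carlo Shapley requires an explicit seed")
    rng = np.random.default_rng(seed)
    for _ in range(mc_samples):
        perm = rng.permutation(features)
        s: frozenset = frozenset()
        prev = val(s)
        for f in perm:
            s = s | {f}
            cur = val(s)
            phi[f] += cur - prev
            prev = cur
    return {f: p / mc_samples for f, p in phi.items()}


@dataclass(frozen=True)
class BootstrapResult:
    name: str
    auc: float  # point estimate on the full data
    ci_low: float
    ci_high: float
    replicates: np.ndarray = field(repr=False)
    n_redrawn: int = 0


def bootstrap_auc(
    df: pd.DataFrame,
    specs: list[ModelSpec],
    n_reps: int = 1000,
    seed: int | None = None,
    label: str = "culprit",
    max_retries: int = 100,
) -> list[BootstrapResult]:
    """Bootstrap AUC replicates for each model, paired across models.

    Lesions are resampled with replacement; the same resample indexes every
    model in a replicate so the replicate vectors are directly comparable.
    Single-class resamples are redrawn (counted, capped). The point estimate
    is the apparent AUC on the full table; the CI is the 2.5/97.5 percentile
    of the replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    y = _labels(df, label)
    n = len(df)
    reps = np.empty((len(specs), n_reps))
    n_redrawn = 0
    for r in range(n_reps):
        for _ in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        boot = df.iloc[idx].reset_index(drop=True)
        for m, spec in enumerate(specs):
            reps[m, r] = apparent_auc(boot, spec, label)
    out = []
    for m, spec in enumerate(specs):
        lo, hi = np.percentile(reps[m], [2.5, 97.5])
        out.append(
            BootstrapResult(
                name=spec.name,
                auc=apparent_auc(df, spec, label),
                ci_low=float(lo),
                ci_high=float(hi),
                replicates=reps[m].copy(),
                n_redrawn=n_redrawn,
            )
        )
    return out


@dataclass(frozen=True)
class YoudenResult:
    threshold: float
    sensitivity: float
    specificity: float
    j: float
    defined: bool = True


def youden_cutoff(scores, labels) -> YoudenResult:
    """Dichotomization threshold maximizing Youden's J = sens + spec - 1.

    Candidate thresholds are the midpoints between consecutive sorted
    unique scores (positives are ``score >= threshold``); ties in J resolve
    to the smallest threshold. Constant scores return J = 0 with the
    ``defined`` flag cleared.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size < 2:
        return YoudenResult(threshold=float("nan"), sensitivity=1.0, specificity=0.0, j=0.0, defined=False)
    cands = 0.5 * (uniq[:-1] + uniq[1:])
    n_pos, n_neg = y.sum(), (1 - y).sum()
    best = None
    for t in cands:
        pred = scores >= t
        sens = float(np.sum(pred & (y == 1)) / n_pos)
        spec = float(np.sum(~pred & (y == 0)) / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best.j + 1e-15:
            best = YoudenResult(threshold=float(t), sensitivity=sens, specificity=spec, j=j)
    return best


@dataclass(frozen=True)
class KmResult:
    curves: dict[str, pd.DataFrame]  # group -> (time, survival)
    statistic: float
    p_value: float
    group_sizes: dict[str, int]


def km_logrank(
    event_time,
    observed,
    group,
    group_names: tuple[str, str] = ("low", "high"),
) -> KmResult:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    ``group`` is a boolean array (True = second group, e.g. index above the
    cutoff); ``observed`` is 1 for an event, 0 for a censored record.
    """
    t = np.asarray(event_time, dtype=float)
    e = np.asarray(observed, dtype=float)
    g = np.asarray(group, dtype=bool)
    if np.any(t < 0):
        raise ValueError("event times must be non-negative")
    if g.all() or (~g).all():
        raise ValueError("both groups must be non-empty")
    curves = {}
    for name, mask in zip(group_names, (~g, g)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = logrank_test(t[~g], t[g], event_observed_A=e[~g], event_observed_B=e[g])
    return KmResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes={group_names[0]: int((~g).sum()), group_names[1]: int(g.sum())},
    )


def group_compare(
    df: pd.DataFrame,
    continuous=CONTINUOUS_FEATURES,
    categorical=CATEGORICAL_FEATURES,
    label: str = "culprit",
) -> pd.DataFrame:
    """Per-feature culprit vs nonculprit comparison table.

    Continuous features: Welch's two-sample t-test (unequal variances,
    Welch-Satterthwaite df). Binary flags: chi-squared on the 2x2 table with
    Yates continuity correction. Features with zero variance in both groups
    are flagged and skipped.
    """
    y = _labels(df, label).astype(bool)
    rows = []
    for f in continuous:
        a = df.loc[y, f].to_numpy(dtype=float)
        b = df.loc[~y, f].to_numpy(dtype=float)
        if np.var(a) == 0 and np.var(b) == 0:
            rows.append({"feature": f, "kind": "continuous", "skipped": True})
            continue
        res = sps.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "feature": f,
                "kind": "continuous",
                "culprit_mean": a.mean(),
                "culprit_sd": a.std(ddof=1),
                "nonculprit_mean": b.mean(),
                "nonculprit_sd": b.std(ddof=1),
                "statistic": float(res.statistic),
                "df": float(res.df),
                "p_value": float(res.pvalue),
                "skipped": False,
            }
        )
    for f in categorical:
        x = df[f].to_numpy(dtype=float)
        if not np.all(np.isin(x, [0.0, 1.0])):
            raise ValueError(f"categorical feature {f!r} is not binary 0/1")
        table = np.array(
            [
                [np.sum((x == 1) & ~y), np.sum((x == 0) & ~y)],
                [np.sum((x == 1) & y), np.sum((x == 0) & y)],
            ]
        )
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            rows.append({"feature": f, "kind": "categorical", "skipped": True})
            continue
        chi2 = sps.chi2_contingency(table, correction=True)
        rows.append(
            {
                "feature": f,
                "kind": "categorical",
                "culprit_mean": x[y].mean(),
                "nonculprit_mean": x[~y].mean(),
                "statistic": float(chi2.statistic),
                "df": float(chi2.dof),
                "p_value": float(chi2.pvalue),
                "skipped": False,
            }
        )
    return pd.DataFrame(rows)


def evaluate_cohort(
    df: pd.DataFrame,
    features: list[str] | None = None,
    value_fn_mode: str = "apparent",
    n_boot: int = 1000,
    seed: int | None = None,
    cutoff_feature: str = "cvi",
    label: str = "culprit",
) -> dict:
    """Run the full evaluation pipeline on a cohort table.

    Returns a JSON-serializable report: per-feature LPOCV AUC ranking,
    Shapley attribution of the combined model, bootstrap comparison of the
    index-alone model vs the combined model, the Youden cutoff on
    ``cutoff_feature``, Kaplan-Meier/log-rank stratification by that cutoff,
    and the group-comparison table.
    """
    if seed is None:
        raise ValueError("evaluation requires an explicit seed")
    feats = list(features) if features is not None else list(CONTINUOUS_FEATURES + CATEGORICAL_FEATURES)
    per_feature = {}
    for f in feats:
        r = auc_lpocv(df, ModelSpec(features=(f,)), label)
        per_feature[f] = {"auc": r.auc, "n_pairs": r.n_pairs, "n_skipped": r.n_skipped}
    ranking = sorted(per_feature, key=lambda f: per_feature[f]["auc"], reverse=True)

    shapley = shapley_delta_auc(df, feats, value_fn_mode=value_fn_mode, label=label)

    specs = [
        ModelSpec(features=(cutoff_feature,), name=cutoff_feature),
        ModelSpec(features=tuple(feats), name="combined"),
    ]
    boots = bootstrap_auc(df, specs, n_reps=n_boot, seed=seed, label=label)

    cut = youden_cutoff(df[cutoff_feature].to_numpy(dtype=float), _labels(df, label))
    km = None
    if cut.defined and {"event_time_months", "censored"}.issubset(df.columns):
        group = df[cutoff_feature].to_numpy(dtype=float) >= cut.threshold
        if 0 < group.sum() < len(df):
            kmres = km_logrank(
                df["event_time_months"].to_numpy(dtype=float),
                1.0 - df["censored"].to_numpy(dtype=float),
                group,
                group_names=(f"{cutoff_feature}-", f"{cutoff_feature}+"),
            )
            km = {
                "statistic": kmres.statistic,
                "p_value": kmres.p_value,
                "group_sizes": kmres.group_sizes,
                "curves": {k: v.to_dict(orient="list") for k, v in kmres.curves.items()},
            }

    table = group_compare(
        df,
        continuous=[f for f in feats if f in CONTINUOUS_FEATURES],
        categorical=[f for f in feats if f in CATEGORICAL_FEATURES],
        label=label,
    )
    return {
        "per_feature_auc": per_feature,
        "ranking": ranking,
        "shapley_delta_auc": shapley,
        "bootstrap": [
            {
                "model": b.name,
                "auc": b.auc,
                "ci_low": b.ci_low,
                "ci_high": b.ci_high,
                "n_redrawn": b.n_redrawn,
            }
            for b in boots
        ],
        "cutoff": {
            "feature": cutoff_feature,
            "threshold": cut.threshold,
            "sensitivity": cut.sensitivity,
            "specificity": cut.specificity,
            "j": cut.j,
            "defined": cut.defined,
        },
        "km_logrank": km,
        "group_table": table.to_dict(orient="records"),
        "seed": seed,
        "value_fn_mode": value_fn_mode,
    }
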
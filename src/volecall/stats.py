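"""Group comparison and hybrid-intermediacy statistics.

The inference chain on a table of per-call measurements: one-way ANOVA with
Tukey HSD, Kruskal-Wallis plus the median test for non-normal parameters,
a two-group linear discriminant analysis (pooled within-group covariance,
equal priors by default) with resubstitution and split-half cross-validated
attribution, a label-permutation chance level, chi-squared comparison of
attribution proportions, and squared Mahalanobis distances of individuals to
the two parental centroids to place hybrids between the parent species.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

DEFAULT_FEATURES = ("duration_s", "q50_hz", "entropy")
DEFAULT_SEED = 20190226
RIDGE_REL = 1e-8


# ---------------------------------------------------------------------------
# univariate group comparisons

@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    posthoc: dict[tuple[str, str], bool]   # Tukey HSD reject flags at alpha=.05


@dataclass(frozen=True)
class KruskalMedianResult:
    H: float
    p_kruskal: float
    median_chi2: float
    p_median: float
    grand_median: float
    pairwise_z: dict[tuple[str, str], tuple[float, float]]  # (z, Bonferroni p)


def one_way_anova(samples: list[np.ndarray],
                  names: list[str] | None = None) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA with Tukey HSD post-hoc flags."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    names = names or [f"g{i}" for i in range(len(samples))]
    all_vals = np.concatenate(samples)
    grand = all_vals.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    dfb = len(samples) - 1
    dfw = len(all_vals) - len(samples)
    if ssw <= 0.0:
        raise ValueError("degenerate within-group variance")
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    labels = np.concatenate([[n] * len(s) for n, s in zip(names, samples)])
    tuk = pairwise_tukeyhsd(all_vals, labels, alpha=0.05)
    pairs = list(itertools.combinations(tuk.groupsunique, 2))
    posthoc = {(str(a), str(b)): bool(r)
               for (a, b), r in zip(pairs, tuk.reject)}
    return AnovaResult(F=float(F), df_between=dfb, df_within=dfw, p=p,
                       posthoc=posthoc)


def kruskal_wallis_median(samples: list[np.ndarray],
                          names: list[str] | None = None) -> KruskalMedianResult:
    """Kruskal-Wallis H and the grand-median test, with pairwise Dunn z.

    The median test counts values above/below the grand median per group and
    applies the contingency chi-squared; pairwise comparisons use rank-sum z
    statistics with Bonferroni-adjusted p-values.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(samples)
    if np.ptp(all_vals) == 0.0:
        raise ValueError("all values tied")
    names = names or [f"g{i}" for i in range(len(samples))]
    H, p_kw = sps.kruskal(*samples)
    med_res = sps.median_test(*samples)
    ranks = sps.rankdata(all_vals)
    N = len(all_vals)
    bounds = np.cumsum([0] + [len(s) for s in samples])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(samples))]
    npairs = len(samples) * (len(samples) - 1) // 2
    pairwise = {}
    for i, j in itertools.combinations(range(len(samples)), 2):
        se = np.sqrt(N * (N + 1) / 12.0
                     * (1.0 / len(samples[i]) + 1.0 / len(samples[j])))
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2.0 * sps.norm.sf(z) * npairs)
        pairwise[(names[i], names[j])] = (float(z), float(p))
    return KruskalMedianResult(
        H=float(H), p_kruskal=float(p_kw),
        median_chi2=float(med_res.statistic), p_median=float(med_res.pvalue),
        grand_median=float(med_res.median), pairwise_z=pairwise)


# ---------------------------------------------------------------------------
# two-group linear discriminant analysis

@dataclass(frozen=True)
class DfaModel:
    groups: tuple[str, str]
    features: tuple[str, ...]
    centroids: dict[str, np.ndarray]
    pooled_cov: np.ndarray
    priors: dict[str, float]
    coef: np.ndarray               # Sigma^-1 (mu_1 - mu_2)


@dataclass(frozen=True)
class ClassificationResult:
    confusion: pd.DataFrame        # rows: true group, cols: predicted
    percent_correct: float
    wilks_lambda: float
    wilks_partial: dict[str, float]   # one-feature-removed partial lambda


@dataclass(frozen=True)
class RandomizationResult:
    mean_percent: float
    se_percent: float
    n_reps: int
    per_rep: np.ndarray


def _group_matrices(data: pd.DataFrame, groups: tuple[str, str],
                    features: tuple[str, ...],
                    group_col: str) -> dict[str, np.ndarray]:
    out = {}
    for g in groups:
        X = data.loc[data[group_col] == g, list(features)].to_numpy(dtype=float)
        if X.shape[0] < 2:
            raise ValueError(f"group {g!r} needs >= 2 rows")
        if np.isnan(X).any():
            raise ValueError(f"missing values in features of group {g!r}")
        out[g] = X
    return out


def _pooled_cov(mats: dict[str, np.ndarray]) -> np.ndarray:
    p = next(iter(mats.values())).shape[1]
    scatter = np.zeros((p, p))
    ntot = 0
    for X in mats.values():
        d = X - X.mean(axis=0)
        scatter += d.T @ d
        ntot += X.shape[0]
    cov = scatter / (ntot - len(mats))
    # ridge-regularise a (near-)singular pooled covariance
    eps = RIDGE_REL * np.trace(cov)
    try:
        cond_bad = np.linalg.cond(cov) > 1e12
    except np.linalg.LinAlgError:
        cond_bad = True
    if cond_bad or not np.all(np.linalg.eigvalsh(cov) > 0):
        warnings.warn("near-singular pooled covariance: ridge applied")
        cov = cov + eps * np.eye(p)
    return cov


def fit_dfa(data: pd.DataFrame,
            groups: tuple[str, str] | None = None,
            features: tuple[str, ...] = DEFAULT_FEATURES,
            priors: str = "equal",
            group_col: str = "group") -> DfaModel:
    """Two-group linear discriminant from the pooled within-group covariance.

    ``priors`` is ``"equal"`` (the default, the legacy desktop-statistics
    convention) or ``"proportional"`` to group sizes.
    """
    if groups is None:
        found = tuple(pd.unique(data[group_col]))
        if len(found) != 2:
            raise ValueError("specify `groups`: data does not contain "
                             "exactly two groups")
        groups = found  # type: ignore[assignment]
    if priors not in ("equal", "proportional"):
        raise ValueError("priors must be 'equal' or 'proportional'")
    mats = _group_matrices(data, groups, features, group_col)
    cov = _pooled_cov(mats)
    centroids = {g: X.mean(axis=0) for g, X in mats.items()}
    if priors == "equal":
        pri = {g: 0.5 for g in groups}
    else:
        ntot = sum(X.shape[0] for X in mats.values())
        pri = {g: X.shape[0] / ntot for g, X in mats.items()}
    coef = np.linalg.solve(cov, centroids[groups[0]] - centroids[groups[1]])
    return DfaModel(groups=tuple(groups), features=tuple(features),
                    centroids=centroids, pooled_cov=cov, priors=pri, coef=coef)


def _predict(model: DfaModel, X: np.ndarray) -> np.ndarray:
    inv_mu = {g: np.linalg.solve(model.pooled_cov, model.centroids[g])
              for g in model.groups}
    scores = np.column_stack([
        X @ inv_mu[g] - 0.5 * model.centroids[g] @ inv_mu[g]
        + np.log(model.priors[g])
        for g in model.groups])
    return np.asarray(model.groups)[np.argmax(scores, axis=1)]


def _wilks(mats: dict[str, np.ndarray], cols: list[int]) -> float:
    """Wilks' lambda det(W)/det(T) over the selected feature columns."""
    if not cols:
        return 1.0
    sub = {g: X[:, cols] for g, X in mats.items()}
    p = len(cols)
    W = np.zeros((p, p))
    allX = np.concatenate(list(sub.values()), axis=0)
    for X in sub.values():
        d = X - X.mean(axis=0)
        W += d.T @ d
    dT = allX - allX.mean(axis=0)
    T = dT.T @ dT
    detT = np.linalg.det(T)
    if detT <= 0:
        return 1.0
    return float(np.linalg.det(W) / detT)


def classify(model: DfaModel, data: pd.DataFrame,
             group_col: str = "group") -> ClassificationResult:
    """Attribute each row to its higher-posterior group.

    Returns the confusion matrix, the percent of correct attributions, the
    overall Wilks' lambda of the evaluated data, and per-feature partial
    lambdas (full-model lambda over the lambda without that feature; smaller
    values mark features contributing more to the discrimination).
    """
    missing = [f for f in model.features if f not in data.columns]
    if missing:
        raise ValueError(f"data lacks model features: {missing}")
    mats = _group_matrices(data, model.groups, model.features, group_col)
    X = data.loc[data[group_col].isin(model.groups),
                 list(model.features)].to_numpy(dtype=float)
    truth = data.loc[data[group_col].isin(model.groups), group_col].to_numpy()
    pred = _predict(model, X)
    confusion = pd.crosstab(pd.Series(truth, name="true"),
                            pd.Series(pred, name="predicted"))
    confusion = confusion.reindex(index=model.groups, columns=model.groups,
                                  fill_value=0)
    correct = sum(confusion.loc[g, g] for g in model.groups)
    all_cols = list(range(len(model.features)))
    lam_full = _wilks(mats, all_cols)
    partial = {}
    for j, f in enumerate(model.features):
        lam_wo = _wilks(mats, [c for c in all_cols if c != j])
        partial[f] = float(lam_full / lam_wo) if lam_wo > 0 else 1.0
    return ClassificationResult(
        confusion=confusion,
        percent_correct=100.0 * correct / len(truth),
        wilks_lambda=lam_full,
        wilks_partial=partial)


def split_half_cv(data: pd.DataFrame,
                  groups: tuple[str, str] | None = None,
                  features: tuple[str, ...] = DEFAULT_FEATURES,
                  priors: str = "equal",
                  seed: int = DEFAULT_SEED,
                  group_col: str = "group") -> float:
    """Split-half cross-validated percent correct.

    Each group is split in half at random (stratified); discriminant keys are
    fitted on one half and tested on the held-out half.  Deterministic for a
    given ``(data, seed)``.
    """
    rng = np.random.default_rng(seed)
    if groups is None:
        found = tuple(pd.unique(data[group_col]))
        if len(found) != 2:
            raise ValueError("specify `groups`")
        groups = found  # type: ignore[assignment]
    train_idx, test_idx = [], []
    for g in groups:
        idx = data.index[data[group_col] == g].to_numpy()
        if len(idx) < 4:
            raise ValueError(f"group {g!r} too small for split-half CV")
        perm = rng.permutation(idx)
        half = len(idx) // 2
        train_idx.extend(perm[:half])
        test_idx.extend(perm[half:])
    model = fit_dfa(data.loc[train_idx], groups=groups, features=features,
                    priors=priors, group_col=group_col)
    res = classify(model, data.loc[test_idx], group_col=group_col)
    return res.percent_correct


def randomization_null(data: pd.DataFrame,
                       groups: tuple[str, str] | None = None,
                       features: tuple[str, ...] = DEFAULT_FEATURES,
                       priors: str = "equal",
                       n_reps: int = 100,
                       seed: int = DEFAULT_SEED,
                       group_col: str = "group") -> RandomizationResult:
    """Label-permutation chance level of the DFA attribution.

    ``n_reps`` times: permute the group labels (group sizes preserved), refit
    the discriminant on all rows and record its resubstitution percent
    correct.  The mean +- SE over replicates is the no-information baseline
    the observed attribution is compared against.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    if groups is None:
        found = tuple(pd.unique(data[group_col]))
        if len(found) != 2:
            raise ValueError("specify `groups`")
        groups = found  # type: ignore[assignment]
    sub = data.loc[data[group_col].isin(groups)].reset_index(drop=True)
    labels = sub[group_col].to_numpy()
    per_rep = np.empty(n_reps)
    for r in range(n_reps):
        shuffled = sub.copy()
        shuffled[group_col] = rng.permutation(labels)
        model = fit_dfa(shuffled, groups=groups, features=features,
                        priors=priors, group_col=group_col)
        per_rep[r] = classify(model, shuffled, group_col=group_col).percent_correct
    return RandomizationResult(
        mean_percent=float(per_rep.mean()),
        se_percent=float(per_rep.std(ddof=1) / np.sqrt(n_reps)),
        n_reps=n_reps, per_rep=per_rep)


def compare_proportions_chi2(p1: float, n1: int, p2: float, n2: int,
                             yates: bool = True) -> tuple[float, float]:
    """Chi-squared comparison of two attribution percentages.

    Builds the 2x2 (correct, incorrect) table from the percentages and sample
    sizes; Yates continuity correction is applied by default.
    """
    for p in (p1, p2):
        if not 0.0 <= p <= 100.0:
            raise ValueError("percentages must lie in [0, 100]")
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    c1 = round(p1 / 100.0 * n1)
    c2 = round(p2 / 100.0 * n2)
    table = np.array([[c1, n1 - c1], [c2, n2 - c2]])
    res = sps.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Mahalanobis placement of individuals between the parent species

@dataclass(frozen=True)
class MahalanobisPlacement:
    parent_groups: tuple[str, str]
    features: tuple[str, ...]
    table: pd.DataFrame     # individual_id, group, d2_a, d2_b


@dataclass(frozen=True)
class IntermediacySummary:
    per_hybrid: pd.DataFrame   # individual_id, d2_a, d2_b, nearer, intermediate
    n_intermediate: int
    nearer_counts: dict[str, int]
    majority_nearer: str


def individual_means(data: pd.DataFrame,
                     features: tuple[str, ...] = DEFAULT_FEATURES,
                     group_col: str = "group",
                     id_col: str = "individual_id") -> pd.DataFrame:
    """One feature vector per animal: the mean of its call measurements."""
    return (data.groupby([id_col, group_col], as_index=False)[list(features)]
            .mean())


def mahalanobis_placement(parents: pd.DataFrame,
                          individuals: pd.DataFrame,
                          parent_groups: tuple[str, str],
                          features: tuple[str, ...] = DEFAULT_FEATURES,
                          group_col: str = "group",
                          id_col: str = "individual_id") -> MahalanobisPlacement:
    """Squared Mahalanobis distance of each individual to both parent centroids.

    The metric is the pooled within-group covariance of the two parent
    species' call-level measurements; ``individuals`` holds one mean feature
    vector per animal (see :func:`individual_means`).  D2 to a centroid is
    zero exactly when the individual mean equals it.
    """
    mats = _group_matrices(parents, parent_groups, features, group_col)
    cov = _pooled_cov(mats)
    mu = {g: X.mean(axis=0) for g, X in mats.items()}
    X = individuals[list(features)].to_numpy(dtype=float)
    rows = []
    for g in parent_groups:
        d = X - mu[g]
        rows.append(np.einsum("ij,ij->i", d, np.linalg.solve(cov, d.T).T))
    table = pd.DataFrame({
        id_col: individuals[id_col].to_numpy(),
        group_col: individuals[group_col].to_numpy(),
        "d2_a": rows[0],
        "d2_b": rows[1],
    })
    return MahalanobisPlacement(parent_groups=tuple(parent_groups),
                                features=tuple(features), table=table)


def intermediacy_summary(pl: MahalanobisPlacement,
                         hybrid_group: str = "hybrid",
                         group_col: str = "group") -> IntermediacySummary:
    """Flag each hybrid as intermediate and name its nearer parent.

    A hybrid is *intermediate* on the parent-A axis when its D2 to A exceeds
    the median self-distance of parent-A individuals but stays below the
    median D2-to-A of parent-B individuals (and symmetrically on the B axis);
    it is intermediate overall when both hold.  The nearer parent is the one
    with the smaller D2 (a tie within 1e-9 relative is reported as "tie").
    """
    t = pl.table
    ga, gb = pl.parent_groups
    hybrids = t[t[group_col] == hybrid_group]
    if hybrids.empty:
        raise ValueError("no hybrid individuals in placement")
    a_rows = t[t[group_col] == ga]
    b_rows = t[t[group_col] == gb]
    self_a, other_a = a_rows["d2_a"].median(), b_rows["d2_a"].median()
    self_b, other_b = b_rows["d2_b"].median(), a_rows["d2_b"].median()
    recs = []
    for _, r in hybrids.iterrows():
        scale = max(r["d2_a"], r["d2_b"], 1.0)
        if abs(r["d2_a"] - r["d2_b"]) <= 1e-9 * scale:
            nearer = "tie"
        else:
            nearer = ga if r["d2_a"] < r["d2_b"] else gb
        intermediate = (self_a < r["d2_a"] < other_a
                        and self_b < r["d2_b"] < other_b)
        recs.append({"individual_id": r["individual_id"],
                     "d2_a": r["d2_a"], "d2_b": r["d2_b"],
                     "nearer": nearer, "intermediate": bool(intermediate)})
    per = pd.DataFrame(recs)
    counts = {ga: int((per["nearer"] == ga).sum()),
              gb: int((per["nearer"] == gb).sum()),
              "tie": int((per["nearer"] == "tie").sum())}
    if counts[ga] == counts[gb]:
        majority = "tie"
    else:
        majority = ga if counts[ga] > counts[gb] else gb
    return IntermediacySummary(per_hybrid=per,
                               n_intermediate=int(per["intermediate"].sum()),
                               nearer_counts=counts,
                               majority_nearer=majority)
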
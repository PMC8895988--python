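"""Evaluation designs: cross-validation, among-group and composite
prediction, the correlation-structure decomposition, and DAPC.

Predictive ability is always the Pearson correlation between predicted
values and observed BLUEs of a prediction set.  Within-group evaluation
uses repeated random 5-fold partitions (stratified proportionally by
subgroup for heterogeneous groups); among-group prediction trains on one
whole group and predicts another, with no cross-validation; composite
training sets combine a random 80% of the target group with one or more
whole other groups and predict the held-out 20%.

The decomposition reported alongside pooled predictions — the overall
correlation over all genotypes versus the mean of the correlations within
each subgroup — separates genuine within-population predictive ability
from an apparent ability driven purely by differences in subgroup means
(a population-structure artifact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import ConfigError, UndefinedStatisticError
from .predict import predict_new, solve_rrblup

__all__ = [
    "CVScheme",
    "CVResult",
    "DAPCResult",
    "predictive_ability",
    "structure_decomposition",
    "cv_structure_decomposition",
    "make_folds",
    "run_within_cv",
    "run_among",
    "run_composite",
    "dapc",
    "MIN_STANDALONE_GROUP",
]

#: groups smaller than this never form a standalone training/prediction set
MIN_STANDALONE_GROUP = 30


@dataclass
class CVScheme:
    kind: str = "within"  # within | among | composite
    k: int = 5
    n_runs: int = 1000
    target_fraction: float = 0.8  # composite: target-group share in training
    stratify_by_subgroup: bool = False
    pool_within_run: bool = False  # pool predictions per run before correlating
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("within", "among", "composite"):
            raise ConfigError(f"unknown scheme kind {self.kind!r}")
        if self.k < 2:
            raise ConfigError("k must be >= 2")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")


@dataclass
class CVResult:
    scheme: CVScheme
    r_values: np.ndarray  # fold-level (or run-level if pooled) abilities
    runs: pd.DataFrame  # tidy: run, fold, r

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.r_values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.r_values, ddof=1))


@dataclass
class DAPCResult:
    n_pc: int
    coordinates: pd.DataFrame  # genotype x discriminant axes
    explained: np.ndarray  # % discriminant variance per axis
    reassignment_rate: float


def predictive_ability(pred, obs) -> float:
    """Pearson correlation between predictions and observed BLUEs."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(pred) == 0 or np.std(obs) == 0:
        raise UndefinedStatisticError(
            "correlation undefined: zero variance in predictions or observations"
        )
    return float(np.corrcoef(pred, obs)[0, 1])


def structure_decomposition(pred, obs, subgroups) -> dict:
    """Overall r, per-subgroup r, and their unweighted mean r-bar.

    Subgroups with fewer than 3 members or zero variance are excluded from
    r-bar and listed under ``excluded``.
    """
    pred = pd.Series(np.asarray(pred, dtype=float)).reset_index(drop=True)
    obs = pd.Series(np.asarray(obs, dtype=float)).reset_index(drop=True)
    sub = pd.Series(list(subgroups)).reset_index(drop=True)
    if sub.nunique() < 2:
        raise ValueError("need at least 2 subgroups")
    overall = predictive_ability(pred, obs)
    per_group, excluded = {}, []
    for g, idx in sub.groupby(sub).groups.items():
        p, o = pred[idx], obs[idx]
        try:
            per_group[g] = predictive_ability(p, o)
        except (ValueError, UndefinedStatisticError):
            excluded.append(g)
    if not per_group:
        raise UndefinedStatisticError("no subgroup admits a correlation")
    return {
        "overall_r": overall,
        "per_subgroup": per_group,
        "r_bar": float(np.mean(list(per_group.values()))),
        "excluded": excluded,
    }


def make_folds(ids, k, rng, subgroups=None):
    """Random k-fold partition, optionally stratified by subgroup.

    Stratification allocates each subgroup proportionally: every fold gets
    floor(n_s / k) members of subgroup s and the remaining n_s mod k are
    assigned one each to the folds currently smallest overall
    (largest-remainder rule; subgroups processed in name order, residual
    ties broken by the RNG).
    """
    ids = list(ids)
    n = len(ids)
    if subgroups is None:
        order = rng.permutation(n)
        return [sorted(ids[i] for i in chunk)
                for chunk in np.array_split(order, k)]
    sub = pd.Series(list(subgroups), index=range(n))
    folds = [[] for _ in range(k)]
    for g in sorted(sub.unique()):
        members = [ids[i] for i in sub.index[sub == g]]
        perm = rng.permutation(len(members))
        base = len(members) // k
        extra = len(members) % k
        sizes = np.full(k, base)
        if extra:
            totals = np.array([len(f) for f in folds], dtype=float)
            totals += rng.random(k) * 0.5  # random tie-break among equals
            for j in np.argsort(totals)[:extra]:
                sizes[j] += 1
        start = 0
        for j in range(k):
            folds[j].extend(members[i] for i in perm[start:start + sizes[j]])
            start += sizes[j]
    return [sorted(f) for f in folds]


def _fit_and_score(y, Z, train_ids, test_ids):
    model = solve_rrblup(y.loc[train_ids], Z.loc[train_ids])
    pred = predict_new(model, Z.loc[test_ids])
    return pred, y.loc[test_ids]


def run_within_cv(y, Z, group_ids, scheme: CVScheme, subgroups=None) -> CVResult:
    """Repeated k-fold cross-validation within one group.

    Each run draws a fresh random partition (stratified proportionally per
    subgroup when requested); each fold is predicted from the remaining
    folds and the predictive ability is computed per prediction set (per
    fold) and pooled over runs, unless the scheme asks for pooling the
    predictions of a run first.
    """
    group_ids = list(group_ids)
    if len(group_ids) < MIN_STANDALONE_GROUP:
        raise ConfigError(
            f"group of size {len(group_ids)} below the minimum of "
            f"{MIN_STANDALONE_GROUP} for a standalone set"
        )
    if scheme.kind != "within":
        raise ConfigError("scheme.kind must be 'within'")
    rng = np.random.default_rng(scheme.seed)
    strat = None
    if scheme.stratify_by_subgroup:
        if subgroups is None:
            raise ConfigError("stratification requested but no subgroups given")
        strat = pd.Series(subgroups).reindex(group_ids) if isinstance(
            subgroups, pd.Series) else pd.Series(list(subgroups))
        strat = list(strat)
    records = []
    for run in range(scheme.n_runs):
        folds = make_folds(group_ids, scheme.k, rng, subgroups=strat)
        run_pred, run_obs = [], []
        for fold_no, fold in enumerate(folds):
            train = [g for g in group_ids if g not in set(fold)]
            pred, obs = _fit_and_score(y, Z, train, fold)
            if scheme.pool_within_run:
                run_pred.append(pred)
                run_obs.append(obs)
            else:
                records.append(
                    (run, fold_no, predictive_ability(pred, obs))
                )
        if scheme.pool_within_run:
            records.append(
                (run, -1,
                 predictive_ability(pd.concat(run_pred), pd.concat(run_obs)))
            )
    runs = pd.DataFrame(records, columns=["run", "fold", "r"])
    return CVResult(scheme=scheme, r_values=runs["r"].to_numpy(), runs=runs)


def cv_structure_decomposition(
    y, Z, group_ids, subgroups, n_runs: int = 10, k: int = 5, seed: int = 0
) -> dict:
    """Pool predictions from repeated stratified k-fold CV, then decompose.

    Mirrors the diagnostic display for structured groups: the predicted and
    observed values of ``n_runs`` cross-validation runs are pooled into one
    scatter, and the overall correlation is contrasted with the mean of the
    within-subgroup correlations.  A large overall r with near-zero r-bar
    flags predictive ability driven by subgroup means alone.
    """
    group_ids = list(group_ids)
    sub = pd.Series(list(subgroups), index=group_ids)
    rng = np.random.default_rng(seed)
    preds, obss = [], []
    for _ in range(n_runs):
        folds = make_folds(group_ids, k, rng, subgroups=list(sub))
        for fold in folds:
            train = [g for g in group_ids if g not in set(fold)]
            pred, obs = _fit_and_score(y, Z, train, fold)
            preds.append(pred)
            obss.append(obs)
    pred_all, obs_all = pd.concat(preds), pd.concat(obss)
    return structure_decomposition(
        pred_all.to_numpy(), obs_all.to_numpy(),
        sub.reindex(pred_all.index).to_numpy(),
    )


def run_among(y, Z, train_ids, test_ids) -> float:
    """Train on one whole group, predict another; no cross-validation.

    Negative predictive abilities are returned as-is.  For reciprocal
    predictions call twice with the sets swapped.
    """
    train_ids, test_ids = list(train_ids), list(test_ids)
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ConfigError(
            f"training and prediction sets overlap ({len(overlap)} genotypes)"
        )
    pred, obs = _fit_and_score(y, Z, train_ids, test_ids)
    return predictive_ability(pred, obs)


def run_composite(
    y, Z, target_ids, other_groups, scheme: CVScheme
) -> CVResult:
    """Composite training sets: 80% of the target group plus whole other
    groups predicts the held-out 20% of the target group, repeatedly.

    With ``other_groups`` empty this reduces exactly to an 80/20 split
    within-group evaluation.
    """
    if scheme.kind != "composite":
        raise ConfigError("scheme.kind must be 'composite'")
    target_ids = list(target_ids)
    rng = np.random.default_rng(scheme.seed)
    extra = [g for grp in other_groups for g in grp]
    if set(extra) & set(target_ids):
        raise ConfigError("other groups overlap the target group")
    n_test = int(round((1.0 - scheme.target_fraction) * len(target_ids)))
    if n_test < 3:
        raise ConfigError("prediction set would have fewer than 3 genotypes")
    records = []
    for run in range(scheme.n_runs):
        perm = rng.permutation(len(target_ids))
        test = [target_ids[i] for i in perm[:n_test]]
        train = [target_ids[i] for i in perm[n_test:]] + extra
        pred, obs = _fit_and_score(y, Z, train, test)
        records.append((run, 0, predictive_ability(pred, obs)))
    runs = pd.DataFrame(records, columns=["run", "fold", "r"])
    return CVResult(scheme=scheme, r_values=runs["r"].to_numpy(), runs=runs)


def dapc(features, groups, n_pc: int | None = None) -> DAPCResult:
    """Discriminant analysis of principal components.

    Features are projected onto the leading principal components (by
    default the smallest number explaining >= 90% of the variance, capped
    at n/3 and at n - n_groups - 1), then linear discriminant axes
    maximising between/within group variance are computed.  The
    reassignment rate is estimated leave-one-out over the discriminant
    step, with the PCA basis held fixed.
    """
    X = features.to_numpy(dtype=float) if isinstance(
        features, pd.DataFrame) else np.asarray(features, dtype=float)
    labels = np.asarray(list(groups))
    n, _ = X.shape
    n_groups = len(np.unique(labels))
    if n_groups < 2:
        raise ConfigError("need at least 2 groups")
    cap = min(n // 3, n - n_groups - 1)
    pca = PCA(n_components=min(n - 1, X.shape[1]))
    scores = pca.fit_transform(X)
    if n_pc is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pc = int(np.searchsorted(cum, 0.90) + 1)
    if n_pc > cap:
        warnings.warn(f"retained PCs reduced from {n_pc} to {cap}")
        n_pc = cap
    n_pc = max(1, n_pc)
    S = scores[:, :n_pc]

    lda = LinearDiscriminantAnalysis(solver="eigen")
    lda.fit(S, labels)
    coords = lda.transform(S)
    explained = 100.0 * lda.explained_variance_ratio_

    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(labels[mask])) < 2:
            continue
        loo = LinearDiscriminantAnalysis(solver="eigen")
        loo.fit(S[mask], labels[mask])
        correct += int(loo.predict(S[i:i + 1])[0] == labels[i])
    idx = features.index if isinstance(features, pd.DataFrame) else range(n)
    return DAPCResult(
        n_pc=n_pc,
        coordinates=pd.DataFrame(
            coords, index=idx,
            columns=[f"DA{j + 1}" for j in range(coords.shape[1])],
        ),
        explained=explained,
        reassignment_rate=correct / n,
    )
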
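"""Stability-selected gradient-boosting discrimination of the two FH groups.

The procedure mirrors a rigorous small-n omics classification protocol:

1. Repeat ``n_repeats`` times: stratified 80/20 split; on the training
   portion run stability selection (class-stratified 50% subsamples, a
   gradient-boosted tree ensemble per subsample, a probe is "selected" in a
   subsample when it carries nonzero split gain; probes selected in at
   least a fraction ``stability_threshold`` of subsamples form the stable
   set); tune the booster on the stable set by stratified K-fold
   cross-validated AUC; the K fold-models' predicted probabilities on the
   untouched test split are averaged (a small ensemble) and scored by ROC
   AUC.
2. Report mean +/- SD of the test AUCs, per-probe selection frequencies and
   gain-based importances averaged over repeats, the latter rescaled so the
   top probe scores 100.
3. Permutation test: the group labels are reshuffled ``n_permutations``
   times with the methylation profiles kept intact, the whole procedure is
   re-run (at a reduced number of outer repeats per permutation, for
   tractability), and the significance of the observed mean AUC is the
   add-one permutation p-value, p = (1 + #{perm AUC >= observed}) /
   (1 + n_permutations).

Directions (hyper/hypo in the mutation-negative group) are assigned from
the sign of the difference in median betas between the groups.
"""

from __future__ import annotations

import dataclasses
import logging

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datasets import MethylationDataset

logger = logging.getLogger(__name__)

#: fixed booster settings; single-threaded and deterministic so a (config,
#: seed) pair reproduces every output byte-identically
_BOOSTER_BASE = {
    "objective": "binary",
    "verbosity": -1,
    "num_threads": 1,
    "deterministic": True,
    "force_row_wise": True,
}

DEFAULT_CLASSIFIER_PARAMS = {
    "num_boost_round": 150,
    "max_depth": 3,
    "num_leaves": 8,
    "learning_rate": 0.1,
    "min_child_samples": 10,
}
#: deliberately small tuning grid: n ~ 136 << p, a large grid only overfits
DEFAULT_PARAM_GRID = (
    {"max_depth": 2, "num_leaves": 4, "learning_rate": 0.05},
    {"max_depth": 2, "num_leaves": 4, "learning_rate": 0.1},
    {"max_depth": 3, "num_leaves": 8, "learning_rate": 0.05},
    {"max_depth": 3, "num_leaves": 8, "learning_rate": 0.1},
)


@dataclasses.dataclass(frozen=True)
class MlConfig:
    """Knobs of the discrimination procedure (defaults = study protocol)."""

    n_repeats: int = 50
    test_fraction: float = 0.2
    cv_folds: int = 5
    n_stability_subsamples: int = 50
    stability_subsample_fraction: float = 0.5
    stability_threshold: float = 0.6
    stability_n_rounds: int = 60  # boosting rounds per stability fit
    n_permutations: int = 1000
    perm_repeats: int = 5  # outer repeats per permutation (reduced for tractability)
    perm_stability_subsamples: int | None = None  # None = same as observed run
    tune_in_permutations: bool = False
    classifier_params: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASSIFIER_PARAMS)
    )
    param_grid: tuple | None = DEFAULT_PARAM_GRID
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if not 0 < self.stability_subsample_fraction < 1:
            raise ValueError("stability_subsample_fraction must be in (0, 1)")
        if not 0 < self.stability_threshold <= 1:
            raise ValueError("stability_threshold must be in (0, 1]")
        for field in ("n_repeats", "cv_folds", "n_stability_subsamples"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")


@dataclasses.dataclass
class ModelReport:
    """Outcome of the repeated-split evaluation."""

    auc_mean: float
    auc_sd: float
    aucs: np.ndarray
    selection_frequency: pd.Series  # per probe, averaged over repeats
    raw_importance: pd.Series  # mean gain per probe, averaged over repeats
    relative_importance: pd.Series  # 0-100, descending, top probe = 100
    permutation_p: float | None = None
    directions: pd.DataFrame | None = None


def _train_booster(X, y, params: dict, seed: int, num_boost_round=None) -> lgb.Booster:
    params = dict(params)
    rounds = params.pop("num_boost_round") if num_boost_round is None else num_boost_round
    params.pop("num_boost_round", None)
    train_set = lgb.Dataset(X, label=y, params={"verbosity": -1})
    return lgb.train({**_BOOSTER_BASE, **params, "seed": seed}, train_set,
                     num_boost_round=rounds)


def _stratified_subsample(y: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Indices of a class-stratified subsample (>= 2 per class)."""
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        take = max(2, int(round(fraction * members.size)))
        idx.append(rng.choice(members, size=min(take, members.size), replace=False))
    return np.sort(np.concatenate(idx))


def _stratified_split(y: np.ndarray, test_fraction: float, rng):
    """Stratified train/test index split; both classes present in both parts."""
    train, test = [], []
    for cls in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == cls))
        n_test = max(1, int(round(test_fraction * members.size)))
        if n_test >= members.size:
            raise ValueError("class too small for the requested test fraction")
        test.append(members[:n_test])
        train.append(members[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def stability_select(
    train_betas: np.ndarray, train_labels: np.ndarray, config: MlConfig, rng=None
) -> np.ndarray:
    """Per-probe selection frequency over stratified subsamples.

    Returns a vector in [0, 1]; probes with frequency >=
    ``config.stability_threshold`` constitute the stable set.  Stability
    fits use ``stability_n_rounds`` boosting rounds: selection only needs
    to know which probes the trees use, not a fully converged model.
    """
    y = np.asarray(train_labels)
    if min(np.bincount(y.astype(int))) < 2:
        raise ValueError("need >= 2 samples per class for stability selection")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    counts = np.zeros(train_betas.shape[1])
    for _ in range(config.n_stability_subsamples):
        idx = _stratified_subsample(y, config.stability_subsample_fraction, rng)
        bst = _train_booster(
            train_betas[idx], y[idx], config.classifier_params,
            int(rng.integers(2**31)), num_boost_round=config.stability_n_rounds,
        )
        counts += bst.feature_importance(importance_type="gain") > 0
    return counts / config.n_stability_subsamples


def _cv_auc(X, y, params: dict, cv_folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, va in skf.split(X, y):
        bst = _train_booster(X[tr], y[tr], params, seed)
        aucs.append(roc_auc_score(y[va], bst.predict(X[va])))
    return float(np.mean(aucs))


def _fit_fold_ensemble(X_train, y_train, X_test, params, cv_folds, seed):
    """Average the cv-fold models' test predictions; also mean fold gains."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    probs, gains = [], []
    for tr, _ in skf.split(X_train, y_train):
        bst = _train_booster(X_train[tr], y_train[tr], params, seed)
        probs.append(bst.predict(X_test))
        gains.append(bst.feature_importance(importance_type="gain"))
    return np.mean(probs, axis=0), np.mean(gains, axis=0)


def train_evaluate(dataset: MethylationDataset, config: MlConfig) -> ModelReport:
    """Repeated stratified-split evaluation with per-repeat stability selection.

    Sample rows are canonically ordered by sample id first, so permuting the
    order of samples in the input leaves every output unchanged.
    """
    order = np.argsort(dataset.betas.index.to_numpy())
    X = dataset.betas.to_numpy(dtype=float)[order]
    y = dataset.group_mask_neg.astype(int)[order]
    return _train_evaluate_arrays(X, y, list(dataset.betas.columns), config)


def _train_evaluate_arrays(X, y, probe_ids, config: MlConfig) -> ModelReport:
    if len(np.unique(y)) < 2:
        raise ValueError("both groups must be present")
    rng = np.random.default_rng(config.seed)
    n_probes = X.shape[1]
    aucs = []
    freq_sum = np.zeros(n_probes)
    gain_sum = np.zeros(n_probes)
    for _ in range(config.n_repeats):
        repeat_seed = int(rng.integers(2**31))
        rrng = np.random.default_rng(repeat_seed)
        train_idx, test_idx = _stratified_split(y, config.test_fraction, rrng)
        X_train, y_train = X[train_idx], y[train_idx]
        X_test, y_test = X[test_idx], y[test_idx]

        freq = stability_select(X_train, y_train, config, rrng)
        freq_sum += freq
        stable = np.flatnonzero(freq >= config.stability_threshold)
        if stable.size == 0:
            logger.info("empty stable set; falling back to all probes this repeat")
            stable = np.arange(n_probes)

        params = dict(config.classifier_params)
        if config.param_grid:
            best_auc, best = -np.inf, None
            for extra in config.param_grid:
                candidate = {**params, **extra}
                cv = _cv_auc(X_train[:, stable], y_train, candidate,
                             config.cv_folds, repeat_seed)
                if cv > best_auc:
                    best_auc, best = cv, candidate
            params = best

        prob, gains = _fit_fold_ensemble(
            X_train[:, stable], y_train, X_test[:, stable], params,
            config.cv_folds, repeat_seed,
        )
        aucs.append(roc_auc_score(y_test, prob))
        gain_sum[stable] += gains

    aucs = np.asarray(aucs)
    freq_mean = pd.Series(freq_sum / config.n_repeats, index=probe_ids)
    raw_imp = pd.Series(gain_sum / config.n_repeats, index=probe_ids)
    if (raw_imp > 0).any():
        relative = rescale_importances(raw_imp[raw_imp > 0])
    else:
        relative = pd.Series(dtype=float)
    return ModelReport(
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0,
        aucs=aucs,
        selection_frequency=freq_mean,
        raw_importance=raw_imp,
        relative_importance=relative,
    )


def rescale_importances(raw_importances: pd.Series) -> pd.Series:
    """Rescale to relative importance, 100 * raw / max(raw).

    Output is sorted descending, ties broken by probe id (lexicographic).
    """
    raw = pd.Series(raw_importances, dtype=float)
    if len(raw) == 0 or (raw < 0).any() or raw.max() <= 0:
        raise ValueError("no informative features: importances must be >= 0, not all zero")
    rel = 100.0 * raw / raw.max()
    frame = rel.rename("relative_importance").rename_axis("probe_id").reset_index()
    frame = frame.sort_values(
        ["relative_importance", "probe_id"], ascending=[False, True], kind="mergesort"
    )
    return frame.set_index("probe_id")["relative_importance"]


def permutation_test(
    dataset: MethylationDataset,
    config: MlConfig,
    observed_auc: float,
) -> tuple[float, np.ndarray]:
    """Label-reshuffling significance of the observed mean AUC.

    Each permutation reshuffles the group labels (methylation profiles kept
    intact) and re-runs the evaluation at ``perm_repeats`` outer repeats and
    ``perm_stability_subsamples`` stability subsamples, without
    hyperparameter tuning unless ``tune_in_permutations`` is set.  Returns
    the add-one p-value and the permuted mean AUCs.
    """
    if config.n_permutations < 19:
        raise ValueError("n_permutations must be >= 19")
    order = np.argsort(dataset.betas.index.to_numpy())
    X = dataset.betas.to_numpy(dtype=float)[order]
    y = dataset.group_mask_neg.astype(int)[order]
    probe_ids = list(dataset.betas.columns)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    perm_aucs = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        y_perm = rng.permutation(y)
        perm_cfg = dataclasses.replace(
            config,
            n_repeats=config.perm_repeats,
            n_stability_subsamples=(
                config.perm_stability_subsamples or config.n_stability_subsamples
            ),
            param_grid=config.param_grid if config.tune_in_permutations else None,
            seed=int(rng.integers(2**31)),
        )
        report = _train_evaluate_arrays(X, y_perm, probe_ids, perm_cfg)
        perm_aucs[b] = report.auc_mean
    p = (1.0 + np.sum(perm_aucs >= observed_auc)) / (1.0 + config.n_permutations)
    return float(p), perm_aucs


def annotate_directions(dataset: MethylationDataset, top_probes) -> pd.DataFrame:
    """Hyper/hypo direction per probe from group median betas.

    ``hyper`` = median beta higher in the mutation-negative group; exact
    ties are flagged and the direction withheld.
    """
    missing = [p for p in top_probes if p not in dataset.betas.columns]
    if missing:
        raise ValueError(f"probes absent from dataset: {missing}")
    neg = dataset.betas.loc[dataset.group_mask_neg, top_probes].median(axis=0)
    pos = dataset.betas.loc[~dataset.group_mask_neg, top_probes].median(axis=0)
    diff = neg - pos
    direction = np.where(diff > 0, "hyper", np.where(diff < 0, "hypo", ""))
    return pd.DataFrame(
        {"direction": direction, "median_diff": diff, "tie": diff == 0},
        index=list(top_probes),
    )


def run_ml(
    dataset: MethylationDataset,
    config: MlConfig,
    with_permutation: bool = True,
    top_n: int = 20,
) -> ModelReport:
    """Full discrimination analysis: evaluation, permutation p, top table."""
    report = train_evaluate(dataset, config)
    if with_permutation:
        report.permutation_p, _ = permutation_test(dataset, config, report.auc_mean)
    top = report.relative_importance.head(top_n)
    if len(top):
        report.directions = annotate_directions(dataset, list(top.index))
    return report


def top_feature_table(
    report: ModelReport, dataset: MethylationDataset, top_n: int = 20
) -> pd.DataFrame:
    """Assemble the top-N probes in the published table's column layout."""
    top = report.relative_importance.head(top_n)
    ann = dataset.probes.loc[list(top.index)]
    directions = (
        report.directions
        if report.directions is not None
        else annotate_directions(dataset, list(top.index))
    )
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(top) + 1),
            "probe_id": top.index,
            "gene": ann["gene"].to_numpy(),
            "chrom": ann["chrom"].to_numpy(),
            "pos": ann["pos"].to_numpy(),
            "gene_feature": ann["gene_feature"].to_numpy(),
            "direction": directions.loc[top.index, "direction"].to_numpy(),
            "relative_importance": top.to_numpy(),
        }
    ).set_index("rank")
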
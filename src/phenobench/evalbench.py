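"""Evaluation engine: cross-validated R², train/test protocol, degradation
experiments, model-complexity diagnostics, and multi-task trait stacking.

The headline accuracy measure is the cross-validated R² computed on
accumulated out-of-fold predictions,

    cvR² = 1 − Σᵢ (yᵢ − ỹᵢ)² / Σᵢ (yᵢ − ȳ)²,

where ỹᵢ is the prediction for sample i made by the model fit on the folds
that exclude i, and ȳ is the sample mean of the observed responses. Every
model is tuned and fit strictly inside its training fold; for kinship-based
prediction (GBLUP) the similarity matrix is computed from genotypes only, so
it may be built once on all samples without phenotype leakage.

Degradation operators emulate common data pathologies at controlled rates:
class noise (±2σ shifts of a random subset of phenotype values), random
marker deletion (nested subsets across levels), and sample deletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bloomqtl, gblup, learners
from .dataio import HAPLOID, GenotypeMatrix, PhenotypeTable
from .simdata import child_rng

#: contamination schedules used in the degradation studies
NOISE_FRACTIONS = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.75, 0.90)
MARKER_FRACTIONS = (0.10, 0.25, 0.50, 0.60, 0.70, 0.80, 0.90, 0.95, 0.99)
SAMPLE_FRACTIONS = (0.10, 0.25, 0.50, 0.60, 0.70, 0.80, 0.85)


def compute_cvR2(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Proportion of variance explained by out-of-fold predictions."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y) != len(y_pred) or len(y) < 2:
        raise ValueError("y and predictions must have equal length >= 2")
    denom = ((y - y.mean()) ** 2).sum()
    if denom == 0:
        raise ValueError("constant response; cvR2 undefined")
    return float(1.0 - ((y - y_pred) ** 2).sum() / denom)


@dataclass
class CVResult:
    trait: str
    method: str
    cvr2: float
    per_run: list[float]
    fold_assignment: np.ndarray
    predictions: np.ndarray  # out-of-fold predictions of the last run
    y: np.ndarray


class _MeanPredictor:
    """Training-fold-mean baseline; its cvR² is ≤ 0 by construction."""

    def fit(self, G, y):
        self.mean = float(np.mean(y))
        return self

    def predict(self, G):
        return np.full(G.n_samples, self.mean)


def fit_predict(
    method: str,
    G_train: GenotypeMatrix,
    y_train: np.ndarray,
    G_test: GenotypeMatrix,
    policy: learners.TuningPolicy | None = None,
    seed: int = 0,
    gsm: gblup.GSM | None = None,
    train_idx: np.ndarray | None = None,
    test_idx: np.ndarray | None = None,
    bloom_B: int = 100,
) -> np.ndarray:
    """Train one method on the training fold and predict the test fold.

    ``gsm``/``train_idx``/``test_idx`` allow kinship reuse for GBLUP: the GSM
    is computed from genotypes of all samples and indexed per fold.
    """
    if method == "mean":
        return _MeanPredictor().fit(G_train, y_train).predict(G_test)
    if method == "gblup":
        if gsm is None:
            K_train = gblup.compute_gsm(G_train)
            K_cross = gblup.compute_gsm_cross(G_test, G_train)
        else:
            K_train = gsm.submatrix(np.asarray(train_idx))
            K_cross = gsm.K[np.ix_(np.asarray(test_idx), np.asarray(train_idx))]
        model = gblup.fit_gblup(K_train, y_train)
        return gblup.predict_gblup(model, K_cross, K_train)
    if method == "bloom":
        model = bloomqtl.bloom_forward_selection(G_train, y_train, B=bloom_B, seed=seed)
        if model.n_markers == 0:
            return np.full(G_test.n_samples, float(np.mean(y_train)))
        return bloomqtl.predict_qtl(model, G_test)
    fitted = learners.fit(method, G_train, y_train, policy=policy, seed=seed)
    return learners.predict(fitted, G_test)


def run_cv(
    G: GenotypeMatrix,
    y: np.ndarray,
    method: str,
    k_folds: int = 10,
    policy: learners.TuningPolicy | None = None,
    n_repeats: int = 1,
    seed: int = 0,
    trait: str = "",
    bloom_B: int = 100,
) -> CVResult:
    """k-fold CV with tuning inside each training fold; repeats averaged."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    G_obs = G.subset_samples(np.flatnonzero(obs))
    y_obs = y[obs]
    n = len(y_obs)
    if n // k_folds < 2:
        raise ValueError("a fold would have fewer than 2 samples")
    gsm = gblup.compute_gsm(G_obs) if method == "gblup" else None
    per_run = []
    for rep in range(n_repeats):
        rng = child_rng(seed, "cv-folds", rep)
        assignment = rng.permutation(np.arange(n) % k_folds)
        preds = np.empty(n)
        for k in range(k_folds):
            te = np.flatnonzero(assignment == k)
            tr = np.flatnonzero(assignment != k)
            preds[te] = fit_predict(
                method,
                G_obs.subset_samples(tr),
                y_obs[tr],
                G_obs.subset_samples(te),
                policy=policy,
                seed=int(child_rng(seed, "fold-seed", rep, k).integers(2**31)),
                gsm=gsm,
                train_idx=tr,
                test_idx=te,
                bloom_B=bloom_B,
            )
        per_run.append(compute_cvR2(y_obs, preds))
    return CVResult(
        trait=trait,
        method=method,
        cvr2=float(np.mean(per_run)),
        per_run=per_run,
        fold_assignment=assignment,
        predictions=preds,
        y=y_obs,
    )


def run_train_test(
    G: GenotypeMatrix,
    y: np.ndarray,
    method: str,
    test_fraction: float = 0.30,
    policy: learners.TuningPolicy | None = None,
    seed: int = 0,
    trait: str = "",
    bloom_B: int = 100,
) -> CVResult:
    """Single random train/test split; R² measured on the held-out share."""
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    G_obs = G.subset_samples(np.flatnonzero(obs))
    y_obs = y[obs]
    n = len(y_obs)
    rng = child_rng(seed, "train-test-split")
    perm = rng.permutation(n)
    n_test = max(2, int(round(test_fraction * n)))
    te, tr = perm[:n_test], perm[n_test:]
    preds = fit_predict(
        method,
        G_obs.subset_samples(tr),
        y_obs[tr],
        G_obs.subset_samples(te),
        policy=policy,
        seed=int(child_rng(seed, "tt-seed").integers(2**31)),
        gsm=gblup.compute_gsm(G_obs) if method == "gblup" else None,
        train_idx=tr,
        test_idx=te,
        bloom_B=bloom_B,
    )
    assignment = np.zeros(n, dtype=int)
    assignment[te] = 1
    return CVResult(
        trait=trait,
        method=method,
        cvr2=compute_cvR2(y_obs[te], preds),
        per_run=[compute_cvR2(y_obs[te], preds)],
        fold_assignment=assignment,
        predictions=preds,
        y=y_obs[te],
    )


# ---------------------------------------------------------------------------
# Degradation experiments


@dataclass
class DegradationPlan:
    kind: str  # class-noise | marker-deletion | sample-deletion
    fractions: tuple[float, ...]
    repetitions: int = 10
    nested: bool = True
    noise_sd_multiple: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("class-noise", "marker-deletion", "sample-deletion"):
            raise ValueError(f"unknown degradation kind {self.kind!r}")
        fr = np.asarray(self.fractions, dtype=float)
        if (np.diff(fr) <= 0).any() or (fr <= 0).any() or (fr > 1).any():
            raise ValueError("fractions must be strictly increasing in (0,1]")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def apply_degradation(
    G: GenotypeMatrix, y: np.ndarray, plan: DegradationPlan
) -> list[list[tuple[float, GenotypeMatrix, np.ndarray]]]:
    """Degraded copies of (G, y): one list of (fraction, G', y') per repetition.

    Class noise shifts the selected samples' phenotype by ±(2σ of the
    original trait) with independent random signs. Marker and sample deletion
    remove nested random subsets, so each level's retained set contains the
    next level's.
    """
    y = np.asarray(y, dtype=float)
    out = []
    for rep in range(plan.repetitions):
        rng = child_rng(plan.seed, "degradation", rep)
        levels = []
        if plan.kind == "class-noise":
            sigma = np.nanstd(y, ddof=1)
            order = rng.permutation(len(y))  # nested contamination sets
            signs = rng.choice([-1.0, 1.0], size=len(y))
            for f in plan.fractions:
                k = int(round(f * len(y)))
                y2 = y.copy()
                idx = order[:k]
                y2[idx] = y2[idx] + signs[idx] * plan.noise_sd_multiple * sigma
                levels.append((f, G, y2))
        elif plan.kind == "marker-deletion":
            order = rng.permutation(G.n_markers)
            for f in plan.fractions:
                k = int(round(f * G.n_markers))
                keep = np.sort(order[k:]) if plan.nested else np.sort(
                    rng.permutation(G.n_markers)[k:]
                )
                G2 = G.subset_markers([G.marker_ids[j] for j in keep])
                levels.append((f, G2, y))
        else:  # sample-deletion
            order = rng.permutation(G.n_samples)
            for f in plan.fractions:
                k = int(round(f * G.n_samples))
                keep = np.sort(order[k:]) if plan.nested else np.sort(
                    rng.permutation(G.n_samples)[k:]
                )
                levels.append((f, G.subset_samples(keep), y[keep]))
        out.append(levels)
    return out


def run_degradation(
    G: GenotypeMatrix,
    y: np.ndarray,
    methods: list[str],
    plan: DegradationPlan,
    policy: learners.TuningPolicy | None = None,
    test_fraction: float = 0.30,
    seed: int = 0,
    trait: str = "",
) -> pd.DataFrame:
    """Baseline + per-level test R² for each method and repetition."""
    rows = []
    for method in methods:
        base = run_train_test(
            G, y, method, test_fraction=test_fraction, policy=policy, seed=seed
        ).cvr2
        rows.append((trait, method, 0, 0.0, base))
        for rep, levels in enumerate(apply_degradation(G, y, plan)):
            for f, G2, y2 in levels:
                r2 = run_train_test(
                    G2, y2, method, test_fraction=test_fraction, policy=policy, seed=seed
                ).cvr2
                rows.append((trait, method, rep, f, r2))
    return pd.DataFrame(rows, columns=["trait", "method", "repetition", "fraction", "r2"])


def degradation_curves(results: pd.DataFrame) -> pd.DataFrame:
    """Per method × level mean ratio (degraded R² / baseline R²) and mean R².

    A zero or negative baseline leaves the ratio undefined (NaN).
    """
    out = []
    for (trait, method), grp in results.groupby(["trait", "method"]):
        base = grp.loc[grp["fraction"] == 0.0, "r2"].mean()
        for f, lvl in grp[grp["fraction"] > 0].groupby("fraction"):
            mean_r2 = lvl["r2"].mean()
            ratio = mean_r2 / base if base > 0 else np.nan
            out.append((trait, method, f, mean_r2, ratio))
        out.append((trait, method, 0.0, base, 1.0 if base > 0 else np.nan))
    df = pd.DataFrame(out, columns=["trait", "method", "fraction", "r2", "ratio"])
    return df.sort_values(["trait", "method", "fraction"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Diagnostics


def lasso_support_size(
    G: GenotypeMatrix,
    y: np.ndarray,
    test_fraction: float = 0.30,
    seed: int = 0,
    policy: learners.TuningPolicy | None = None,
) -> tuple[int, float]:
    """Lasso non-zero coefficient count as a proxy for mechanistic complexity.

    Fits the tuned lasso on a 70% training split and returns (number of
    non-zero coefficients, R² on the held-out 30%).
    """
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    G_obs = G.subset_samples(np.flatnonzero(obs))
    y_obs = y[obs]
    rng = child_rng(seed, "train-test-split")
    perm = rng.permutation(len(y_obs))
    n_test = max(2, int(round(test_fraction * len(y_obs))))
    te, tr = perm[:n_test], perm[n_test:]
    fitted = learners.fit(
        "lasso", G_obs.subset_samples(tr), y_obs[tr], policy=policy, seed=seed
    )
    support = int(np.sum(fitted.estimator.coef_ != 0))
    preds = learners.predict(fitted, G_obs.subset_samples(te))
    return support, compute_cvR2(y_obs[te], preds)


# ---------------------------------------------------------------------------
# Multi-task stacking


@dataclass
class MultiTaskDataset:
    """Stacked per-trait observations with a one-hot trait indicator."""

    G_stacked: GenotypeMatrix
    y: np.ndarray
    row_trait: np.ndarray  # trait name per stacked row
    row_sample: np.ndarray  # original sample id per stacked row
    traits: list[str]


def build_multitask(
    G: GenotypeMatrix, P: PhenotypeTable, traits: list[str]
) -> MultiTaskDataset:
    """One large regression problem over a trait group sharing the genotypes.

    Every observed (sample, trait) pair becomes one row: the sample's marker
    vector plus a one-hot trait indicator. The row count is the sum of
    observed sample counts over the grouped traits.
    """
    if not traits:
        raise ValueError("empty trait group")
    missing = [t for t in traits if t not in P.trait_names]
    if missing:
        raise ValueError(f"traits not in phenotype table: {missing}")
    sample_pos = {s: i for i, s in enumerate(G.sample_ids)}
    blocks, ys, row_trait, row_sample = [], [], [], []
    for t in traits:
        col = P.traits[t]
        obs = col.dropna()
        idx = [sample_pos[s] for s in obs.index]
        blocks.append(G.values[idx])
        ys.append(obs.to_numpy(dtype=float))
        row_trait.extend([t] * len(obs))
        row_sample.extend(list(obs.index))
    X = np.vstack(blocks)
    onehot = np.zeros((X.shape[0], len(traits)))
    rt = np.asarray(row_trait)
    for k, t in enumerate(traits):
        onehot[rt == t, k] = 1.0
    stacked = GenotypeMatrix(
        values=np.hstack([X, onehot]),
        coding=HAPLOID if G.coding == HAPLOID else G.coding,
        sample_ids=[f"row{i}" for i in range(X.shape[0])],
        marker_ids=list(G.marker_ids) + [f"trait_{t}" for t in traits],
    )
    return MultiTaskDataset(
        G_stacked=stacked,
        y=np.concatenate(ys),
        row_trait=rt,
        row_sample=np.asarray(row_sample),
        traits=list(traits),
    )


def run_multitask_train_test(
    mt: MultiTaskDataset,
    method: str = "rf",
    test_fraction: float = 0.30,
    policy: learners.TuningPolicy | None = None,
    seed: int = 0,
) -> dict:
    """Grouped fit evaluated on the aggregation of per-trait test sets."""
    test_mask = np.zeros(len(mt.y), dtype=bool)
    for t in mt.traits:
        rows = np.flatnonzero(mt.row_trait == t)
        rng = child_rng(seed, "mt-split", mt.traits.index(t))
        perm = rng.permutation(len(rows))
        n_test = max(2, int(round(test_fraction * len(rows))))
        test_mask[rows[perm[:n_test]]] = True
    tr = np.flatnonzero(~test_mask)
    te = np.flatnonzero(test_mask)
    fitted = learners.fit(
        method, mt.G_stacked.subset_samples(tr), mt.y[tr], policy=policy, seed=seed
    )
    preds = learners.predict(fitted, mt.G_stacked.subset_samples(te))
    per_trait = {}
    for t in mt.traits:
        sel = mt.row_trait[te] == t
        per_trait[t] = compute_cvR2(mt.y[te][sel], preds[sel])
    return {
        "overall_r2": compute_cvR2(mt.y[te], preds),
        "per_trait_r2": per_trait,
        "test_rows": te,
    }
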
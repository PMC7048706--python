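"""Sequential QTL mapping: LOD scans, permutation-FDR thresholds, forward
selection of additive markers and a pairwise interaction scan.

This is the classical two-step procedure used for biparental-cross growth
traits. Step one is a four-stage forward selection: each stage scans the
current residuals marker-by-marker with the LOD statistic

    LOD_j = (n/2) · log10(SS0 / SS1_j) = −(n/2) · log10(1 − ρ_j²),

keeps markers whose LOD clears a permutation-based 5% FDR threshold, reduces
significant LD blocks to their per-chromosome peak markers, refits the joint
linear model over all selected markers, and recomputes residuals. Step two
scans for pairwise interactions involving the selected additive markers with
the likelihood-ratio statistic n·ln(RSS_reduced/RSS_full) of nested OLS fits,
again thresholded by permutation FDR.

The FDR estimate is the plug-in (Storey-type) ratio

    FDR(t) = mean over permutations of #{null LOD ≥ t} / #{observed LOD ≥ t},

clipped to 1; the threshold is the smallest statistic value achieving
FDR ≤ level. Attribute selection and thresholding always use training data
only — fitting is unaffected by anything in a held-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import GenotypeMatrix
from .simdata import child_rng

#: LOD cap for numerically collinear markers (ρ² indistinguishable from 1)
MAX_RHO2 = 1 - 1e-12


@dataclass
class LODScan:
    lod: np.ndarray
    trait: str = ""
    stage: int = 0

    def __post_init__(self) -> None:
        if (self.lod < 0).any():
            raise ValueError("LOD scores must be non-negative")


@dataclass
class PermutationNull:
    B: int
    null_max_count: np.ndarray  # per-threshold mean null exceedances (diagnostic)
    threshold: float
    attained_fdr: float


@dataclass
class QTLModel:
    """Selected markers with jointly refit coefficients and provenance."""

    marker_ids: list[str] = field(default_factory=list)
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(0))
    intercept: float = 0.0
    stages: list[int] = field(default_factory=list)  # stage each marker entered
    thresholds: list[float] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    interaction_coefs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    interaction_lr: list[float] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


def _standardized(G: GenotypeMatrix) -> np.ndarray:
    vals = G.values
    if np.isnan(vals).any():
        raise ValueError("complete genotypes required; impute first")
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)
    sd[sd == 0] = np.inf  # constant markers get correlation 0
    return (vals - mean) / sd


def _lod_from_corr(rho: np.ndarray, n: int) -> np.ndarray:
    rho2 = np.clip(rho * rho, 0.0, MAX_RHO2)
    return -(n / 2.0) * np.log10(1.0 - rho2)


def lod_scan(G: GenotypeMatrix, r: np.ndarray, trait: str = "", stage: int = 0) -> LODScan:
    """Marker-wise LOD of the one-marker regression of residuals r."""
    r = np.asarray(r, dtype=float)
    if np.isnan(r).any():
        raise ValueError("residual vector must be fully observed")
    n = len(r)
    Z = _standardized(G)
    rc = r - r.mean()
    denom = np.sqrt((rc * rc).sum())
    if denom == 0:
        return LODScan(lod=np.zeros(G.n_markers), trait=trait, stage=stage)
    rho = (Z.T @ rc) / (denom * np.sqrt(n))
    return LODScan(lod=_lod_from_corr(rho, n), trait=trait, stage=stage)


def _null_lods(Z: np.ndarray, r: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """B × p matrix of LODs for permuted residuals (genotypes kept fixed)."""
    n = len(r)
    rc = r - r.mean()
    denom = np.sqrt((rc * rc).sum()) * np.sqrt(n)
    perms = np.empty((n, B))
    for b in range(B):
        perms[:, b] = rc[rng.permutation(n)]
    rho = (Z.T @ perms).T / denom  # B × p
    return _lod_from_corr(rho, n)


def plugin_fdr_threshold(
    observed: np.ndarray, null_stats: np.ndarray, fdr_level: float
) -> tuple[float, float]:
    """Smallest observed-statistic threshold with plug-in FDR ≤ level.

    ``null_stats`` has one row per permutation. Returns (threshold,
    attained FDR); (+inf, nan) when no observed value qualifies.
    """
    B = null_stats.shape[0]
    cand = np.unique(observed)
    null_flat = np.sort(null_stats.ravel())
    obs_sorted = np.sort(observed)
    n_obs = len(obs_sorted) - np.searchsorted(obs_sorted, cand, side="left")
    mean_null = (len(null_flat) - np.searchsorted(null_flat, cand, side="left")) / B
    fdr = np.minimum(mean_null / n_obs, 1.0)
    ok = np.flatnonzero(fdr <= fdr_level)
    if ok.size == 0:
        return (np.inf, np.nan)
    k = ok[0]  # candidates ascend, so this is the smallest qualifying t
    return (float(cand[k]), float(fdr[k]))


def permutation_threshold(
    G: GenotypeMatrix,
    r: np.ndarray,
    B: int = 1000,
    fdr_level: float = 0.05,
    seed: int = 0,
) -> PermutationNull:
    """Permutation null for the LOD scan and the plug-in FDR threshold."""
    if B < 1:
        raise ValueError("B must be >= 1")
    r = np.asarray(r, dtype=float)
    Z = _standardized(G)
    rng = child_rng(seed, "permutation")
    obs = lod_scan(G, r).lod
    null = _null_lods(Z, r, B, rng)
    t, fdr = plugin_fdr_threshold(obs, null, fdr_level)
    return PermutationNull(
        B=B, null_max_count=null.max(axis=1), threshold=t, attained_fdr=fdr
    )


def _peak_reduce(sig_idx: np.ndarray, lods: np.ndarray, chrom: np.ndarray) -> list[int]:
    """Reduce contiguous runs of significant markers to the per-run LOD peak."""
    peaks = []
    run: list[int] = []
    for k, j in enumerate(sig_idx):
        if run and (j != run[-1] + 1 or chrom[j] != chrom[run[-1]]):
            peaks.append(int(run[int(np.argmax(lods[run]))]))
            run = []
        run.append(int(j))
    if run:
        peaks.append(int(run[int(np.argmax(lods[run]))]))
    return peaks


def _ols_refit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """OLS with intercept; drops later columns that do not increase rank.

    Returns (coefs incl. intercept first, residuals, kept column indices).
    """
    n = len(y)
    design = np.ones((n, 1))
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = np.hstack([design, X[:, [j]]])
        if np.linalg.matrix_rank(trial) > design.shape[1]:
            design = trial
            kept.append(j)
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coefs
    return coefs, resid, kept


def bloom_forward_selection(
    G: GenotypeMatrix,
    y: np.ndarray,
    max_stages: int = 4,
    B: int = 1000,
    fdr_level: float = 0.05,
    seed: int = 0,
) -> QTLModel:
    """Iterative additive-QTL forward selection with permutation-FDR gating."""
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("y must be fully observed (drop missing samples first)")
    chrom = (
        G.mapping["chromosome"].to_numpy()
        if G.mapping is not None
        else np.zeros(G.n_markers, dtype=int)
    )
    Z = _standardized(G)
    selected: list[int] = []
    stages: list[int] = []
    thresholds: list[float] = []
    resid = y - y.mean()
    intercept = y.mean()
    coefs = np.zeros(0)
    for stage in range(1, max_stages + 1):
        scan = lod_scan(G, resid, stage=stage)
        rng = child_rng(seed, "permutation", stage)
        null = _null_lods(Z, resid, B, rng)
        t, _ = plugin_fdr_threshold(scan.lod, null, fdr_level)
        thresholds.append(t)
        if not np.isfinite(t):
            break
        sig = np.flatnonzero(scan.lod >= t)
        sig = np.array([j for j in sig if j not in selected], dtype=int)
        if sig.size == 0:
            break
        peaks = _peak_reduce(sig, scan.lod, chrom)
        new = [j for j in peaks if j not in selected]
        if not new:
            break
        selected.extend(new)
        stages.extend([stage] * len(new))
        all_coefs, resid, kept = _ols_refit(G.values[:, selected], y)
        if len(kept) < len(selected):
            # drop later-entering collinear markers from the model
            selected = [selected[k] for k in kept]
            stages = [stages[k] for k in kept]
        intercept = float(all_coefs[0])
        coefs = all_coefs[1:]
    return QTLModel(
        marker_ids=[G.marker_ids[j] for j in selected],
        coefficients=np.asarray(coefs, dtype=float),
        intercept=intercept,
        stages=stages,
        thresholds=thresholds,
    )


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    r = y - design @ coefs
    return float(r @ r)


def interaction_lr_stats(
    G: GenotypeMatrix, y: np.ndarray, model: QTLModel
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """LR statistic n·ln(RSS_red/RSS_full) for every (selected m, marker j) pair.

    The reduced model is the joint additive model plus the main effect of j;
    the full model adds the m×j product term. Computed with the
    Frisch–Waugh residualization of y, g_j and g_m·g_j against the base
    additive design, vectorized over j.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    sel_pos = [G.marker_ids.index(m) for m in model.marker_ids]
    base = np.hstack([np.ones((n, 1)), G.values[:, sel_pos]])
    Q, _ = np.linalg.qr(base)
    proj = lambda M: M - Q @ (Q.T @ M)
    y_t = proj(y[:, None])[:, 0]
    rss_y = float(y_t @ y_t)
    G_t = proj(G.values)
    stats, pairs = [], []
    gg = (G_t * G_t).sum(axis=0)
    gy = G_t.T @ y_t
    tol = 1e-9 * n
    ok_g = gg > tol
    with np.errstate(divide="ignore", invalid="ignore"):
        expl_red = np.where(ok_g, gy * gy / gg, 0.0)
    for m in sel_pos:
        inter = G.values[:, [m]] * G.values  # n × p product columns
        I_t = proj(inter)
        # orthogonalize the interaction column against the residualized g_j
        gi = (G_t * I_t).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            coef = np.where(ok_g, gi / gg, 0.0)
        U2 = I_t - G_t * coef
        uu = (U2 * U2).sum(axis=0)
        uy = U2.T @ y_t
        ok_u = uu > tol
        with np.errstate(divide="ignore", invalid="ignore"):
            expl_full = expl_red + np.where(ok_u, uy * uy / uu, 0.0)
        rss_red = np.clip(rss_y - expl_red, 1e-300, None)
        rss_full = np.clip(rss_y - expl_full, 1e-300, None)
        lr = n * np.log(np.clip(rss_red / rss_full, 1.0, None))
        stats.append(lr)
        pairs.extend((m, j) for j in range(G.n_markers))
    return np.concatenate(stats), pairs


def interaction_scan(
    G: GenotypeMatrix,
    y: np.ndarray,
    model: QTLModel,
    B: int = 1000,
    fdr_level: float = 0.05,
    seed: int = 0,
) -> QTLModel:
    """Append permutation-FDR-significant pairwise interactions to the model."""
    if model.n_markers == 0:
        raise ValueError("interaction scan requires at least one additive marker")
    y = np.asarray(y, dtype=float)
    obs, pairs = interaction_lr_stats(G, y, model)
    rng = child_rng(seed, "interaction-permutation")
    null = np.empty((B, len(obs)))
    for b in range(B):
        yp = y[rng.permutation(len(y))]
        null[b], _ = interaction_lr_stats(G, yp, model)
    t, _ = plugin_fdr_threshold(obs, null, fdr_level)
    chosen: list[tuple[int, int]] = []
    if np.isfinite(t):
        seen = set()
        for stat, (m, j) in zip(obs, pairs):
            key = (min(m, j), max(m, j))
            if stat >= t and m != j and key not in seen:
                seen.add(key)
                chosen.append((m, j))
    sel_pos = [G.marker_ids.index(mk) for mk in model.marker_ids]
    cols = [G.values[:, j] for j in sel_pos]
    for m, j in chosen:
        if j not in sel_pos:
            cols.append(G.values[:, j])  # main effect of the partner marker
            sel_pos.append(j)
    inter_cols = [G.values[:, m] * G.values[:, j] for m, j in chosen]
    X = np.column_stack(cols + inter_cols) if cols else np.zeros((len(y), 0))
    coefs, _, kept = _ols_refit(X, y)
    lr_by_pair = {
        (min(m, j), max(m, j)): float(s) for s, (m, j) in zip(obs, pairs)
    }
    return QTLModel(
        marker_ids=[G.marker_ids[j] for j in sel_pos],
        coefficients=coefs[1 : 1 + len(sel_pos)],
        intercept=float(coefs[0]),
        stages=model.stages + [0] * (len(sel_pos) - model.n_markers),
        thresholds=model.thresholds + [t],
        interactions=[(G.marker_ids[m], G.marker_ids[j]) for m, j in chosen],
        interaction_coefs=coefs[1 + len(sel_pos) :],
        interaction_lr=[lr_by_pair[(min(m, j), max(m, j))] for m, j in chosen],
    )


def predict_qtl(model: QTLModel, G_test: GenotypeMatrix) -> np.ndarray:
    """Evaluate the fitted linear model (main + interaction terms) on new data."""
    missing = [m for m in model.marker_ids if m not in G_test.marker_ids]
    if missing:
        raise ValueError(f"test data lacks model markers: {missing}")
    pred = np.full(G_test.n_samples, model.intercept)
    pos = {m: j for j, m in enumerate(G_test.marker_ids)}
    for mk, beta in zip(model.marker_ids, model.coefficients):
        pred += beta * G_test.values[:, pos[mk]]
    for (ma, mb), gamma in zip(model.interactions, model.interaction_coefs):
        pred += gamma * G_test.values[:, pos[ma]] * G_test.values[:, pos[mb]]
    return pred
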
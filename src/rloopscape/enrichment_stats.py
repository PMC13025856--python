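"""Statistics for window-feature, motif and gene-set enrichment.

The workhorse is a permutation-subsampling null: within one chromatin
state, background windows are subsampled (without replacement) to the
size of the R-loop window set many times; the empirical p-value is the
plain proportion of null means >= the observed mean, the Z-score is the
standardized effect against the null distribution, and the enrichment is
log2(mean_rloop / mean_background).

Also provided: HOMER-style known-motif enrichment (hypergeometric or
binomial), gene-set over-representation (hypergeometric upper tail with
Benjamini-Hochberg correction; significant iff p < 0.01 and q < 0.05),
and random-forest permutation importance measured as mean decrease in
held-out AUC.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "permutation_enrichment",
    "MotifEnrichment",
    "motif_enrichment",
    "ora",
    "read_gmt",
    "bh_adjust",
    "permutation_importance",
]


@dataclass
class PermutationResult:
    observed_mean: float
    null_mean: float
    null_sd: float
    empirical_p: float
    z: float
    enrichment: float  # log2(observed mean / background pool mean)
    n_rloop: int
    n_background_pool: int
    n_permutations: int
    p_floor: float  # resolution of the empirical p (1/n_perm)
    sampled_with_replacement: bool = False
    degenerate_null: bool = False  # null sd was 0
    undefined_enrichment: bool = False  # background mean was 0
    state: str | None = None
    feature: str | None = None


def permutation_enrichment(
    rloop_values: Sequence[float],
    background_values: Sequence[float],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    exhaustive: bool = False,
    state: str | None = None,
    feature: str | None = None,
) -> PermutationResult:
    """Permutation-subsampling test of an observed mean against a background.

    Each permutation draws ``len(rloop_values)`` values from the
    background pool without replacement (with replacement, flagged, only
    when the pool is smaller than the input) and records the mean.
    ``empirical_p`` is the plain proportion of null means >= the observed
    mean (no smoothing; ``p_floor`` = 1/n_perm documents the resolution).
    With ``exhaustive=True`` every subset of the pool is enumerated
    instead of sampled, which is exact for small pools.
    """
    x = np.asarray(rloop_values, dtype=float)
    bg = np.asarray(background_values, dtype=float)
    if x.size == 0 or bg.size == 0:
        raise ValueError("both value lists must be non-empty")
    observed = float(x.mean())
    bg_mean = float(bg.mean())

    with_replacement = bg.size < x.size
    if exhaustive:
        if with_replacement:
            raise ValueError("exhaustive enumeration needs pool >= input size")
        null_means = np.array(
            [np.mean(c) for c in itertools.combinations(bg, x.size)]
        )
        n_used = len(null_means)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if with_replacement:
            warnings.warn("background pool smaller than input; sampling with replacement")
            draws = rng.choice(bg, size=(n_perm, x.size), replace=True)
            null_means = draws.mean(axis=1)
        else:
            # without-replacement subsampling, vectorized in memory-bounded
            # chunks: the k smallest of n random keys index a uniform subset
            null_means = np.empty(n_perm)
            chunk = max(1, int(2_000_000 // max(bg.size, 1)))
            pos = 0
            while pos < n_perm:
                c = min(chunk, n_perm - pos)
                keys = rng.random((c, bg.size))
                idx = np.argpartition(keys, x.size - 1, axis=1)[:, : x.size]
                null_means[pos : pos + c] = bg[idx].mean(axis=1)
                pos += c
        n_used = n_perm

    null_mean = float(null_means.mean())
    null_sd = float(null_means.std(ddof=0))
    p = float(np.mean(null_means >= observed))
    degenerate = null_sd == 0
    z = 0.0 if degenerate else (observed - null_mean) / null_sd
    undefined = bg_mean <= 0
    if observed == bg_mean:
        enrichment, undefined = 0.0, False
    elif undefined:
        enrichment = math.nan
    elif observed <= 0:
        enrichment = -math.inf
    else:
        enrichment = math.log2(observed / bg_mean)
    return PermutationResult(
        observed_mean=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        empirical_p=p,
        z=z,
        enrichment=enrichment,
        n_rloop=int(x.size),
        n_background_pool=int(bg.size),
        n_permutations=n_used,
        p_floor=1.0 / n_used,
        sampled_with_replacement=with_replacement,
        degenerate_null=degenerate,
        undefined_enrichment=undefined,
        state=state,
        feature=feature,
    )


def state_feature_enrichment(
    windows: pd.DataFrame,
    features: Sequence[str],
    n_perm: int = 10_000,
    seed: int | None = None,
    min_windows: int = 10,
) -> pd.DataFrame:
    """Run the permutation test per (state, feature) on a classified window table.

    Requires ``state`` and boolean ``rloop`` columns. States with fewer
    than ``min_windows`` windows in either class are skipped. BH q-values
    are added per feature family across states.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for state, sub in windows.groupby("state", sort=True):
        fg = sub[sub["rloop"]]
        bg = sub[~sub["rloop"]]
        if len(fg) < min_windows or len(bg) < min_windows:
            continue
        for feat in features:
            res = permutation_enrichment(
                fg[feat].to_numpy(),
                bg[feat].to_numpy(),
                n_perm=n_perm,
                seed=rng,
                state=state,
                feature=feat,
            )
            rows.append(vars(res))
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = np.nan
        for feat in df["feature"].unique():
            mask = df["feature"] == feat
            df.loc[mask, "q"] = bh_adjust(df.loc[mask, "empirical_p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# motif enrichment
# ---------------------------------------------------------------------------

@dataclass
class MotifEnrichment:
    motif: str
    state: str | None
    n_target: int
    n_background: int
    target_hits: int
    background_hits: int
    pct_target: float
    pct_background: float
    fold: float
    p: float
    q: float = math.nan


def motif_enrichment(
    target_hits: Sequence[bool],
    background_hits: Sequence[bool],
    model: str = "hypergeometric",
    motif: str = "",
    state: str | None = None,
) -> MotifEnrichment:
    """Known-motif over-representation of target vs background sequences.

    ``hypergeometric``: upper-tail P[X >= k] with the combined sequence
    set as the universe. ``binomial``: upper tail of Binomial(n_target,
    background rate). A zero background rate gives infinite fold, flagged
    by the value itself.
    """
    t = np.asarray(target_hits, dtype=bool)
    b = np.asarray(background_hits, dtype=bool)
    if t.size == 0 or b.size == 0:
        raise ValueError("need >= 1 target and >= 1 background sequence")
    k, n = int(t.sum()), int(t.size)
    kb, nb = int(b.sum()), int(b.size)
    pct_t, pct_b = 100.0 * k / n, 100.0 * kb / nb
    if k == 0:
        fold, p = 0.0, 1.0
    elif kb == 0:
        fold = math.inf
        p = _motif_p(k, n, kb, nb, model)
    else:
        fold = pct_t / pct_b
        p = _motif_p(k, n, kb, nb, model)
    return MotifEnrichment(motif, state, n, nb, k, kb, pct_t, pct_b, fold, p)


def _motif_p(k: int, n: int, kb: int, nb: int, model: str) -> float:
    if model == "hypergeometric":
        # universe n+nb sequences, k+kb total hits, n drawn (the targets)
        return float(sps.hypergeom.sf(k - 1, n + nb, k + kb, n))
    if model == "binomial":
        return float(sps.binom.sf(k - 1, n, kb / nb)) if nb else 1.0
    raise ValueError(f"unknown model {model!r}")


def motif_enrichment_table(
    per_state_hits: Mapping[str, Mapping[str, tuple[Sequence[bool], Sequence[bool]]]],
    model: str = "hypergeometric",
) -> pd.DataFrame:
    """Motif x state enrichment with BH across the whole family."""
    results = [
        motif_enrichment(t, b, model=model, motif=motif, state=state)
        for state, motifs in per_state_hits.items()
        for motif, (t, b) in motifs.items()
    ]
    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# gene-set over-representation
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term, description, member genes."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line needs >= 3 columns: {fields[0]!r}")
            out[fields[0]] = set(fields[2:])
    return out


def ora(
    selected: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    p_cut: float = 0.01,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against term sets.

    Terms are intersected with the universe before testing; terms with no
    universe overlap are skipped.  Significance follows the joint rule
    p < ``p_cut`` and BH q < ``q_cut``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sel = set(selected) & uni
    if set(selected) - uni:
        warnings.warn(
            f"{len(set(selected) - uni)} selected gene(s) outside universe; dropped"
        )
    rows = []
    for term, members in term_sets.items():
        term_in_uni = set(members) & uni
        if not term_in_uni:
            continue
        overlap = len(term_in_uni & sel)
        p = float(sps.hypergeom.sf(overlap - 1, len(uni), len(term_in_uni), len(sel)))
        expected = len(term_in_uni) * len(sel) / len(uni)
        rows.append(
            {
                "term": term,
                "universe_size": len(uni),
                "term_size": len(term_in_uni),
                "selected_size": len(sel),
                "overlap": overlap,
                "fold_enrichment": overlap / expected if expected else math.nan,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = (df["p"] < p_cut) & (df["q"] < q_cut)
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    return df


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([])
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# random-forest permutation importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceResult:
    feature: str
    mean_decrease_auc: float
    sd_decrease_auc: float
    baseline_auc: float


def permutation_importance(
    features: pd.DataFrame,
    labels: Sequence[bool],
    k_folds: int = 5,
    n_repeats: int = 10,
    seed: int | None = None,
    classifier=None,
) -> pd.DataFrame:
    """Feature relevance as mean decrease in held-out AUC under permutation.

    Stratified k-fold cross-validation; the classifier (default: a
    500-tree random forest) is trained per fold, each feature column is
    shuffled within the held-out fold ``n_repeats`` times, and the drop
    from the fold's baseline AUC is averaged over folds x repeats. Any
    estimator with ``fit``/``predict_proba`` can be plugged in.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, dtype=bool)
    x = features.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    if x.shape[1] < 2:
        raise ValueError("need >= 2 features")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    decreases: dict[str, list[float]] = {c: [] for c in features.columns}
    baselines = []
    for train_idx, test_idx in skf.split(x, y):
        clf = classifier
        if clf is None:
            clf = RandomForestClassifier(
                n_estimators=500, random_state=int(rng.integers(2**31)), n_jobs=1
            )
        else:
            from sklearn.base import clone

            clf = clone(classifier)
        clf.fit(x[train_idx], y[train_idx])
        prob = clf.predict_proba(x[test_idx])[:, 1]
        base_auc = roc_auc_score(y[test_idx], prob)
        baselines.append(base_auc)
        for f_i, col in enumerate(features.columns):
            for _ in range(n_repeats):
                xp = x[test_idx].copy()
                xp[:, f_i] = rng.permutation(xp[:, f_i])
                perm_auc = roc_auc_score(y[test_idx], clf.predict_proba(xp)[:, 1])
                decreases[col].append(base_auc - perm_auc)
    return pd.DataFrame(
        [
            ImportanceResult(
                feature=col,
                mean_decrease_auc=float(np.mean(vals)),
                sd_decrease_auc=float(np.std(vals, ddof=1)),
                baseline_auc=float(np.mean(baselines)),
            ).__dict__
            for col, vals in decreases.items()
        ]
    ).sort_values("mean_decrease_auc", ascending=False, kind="mergesort").reset_index(drop=True)
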
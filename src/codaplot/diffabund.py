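"""Dirichlet Monte-Carlo differential abundance in CLR space.

The sampling model treats each sample's counts as a multinomial draw from
unknown proportions.  Posterior uncertainty is propagated by drawing K
instances of the proportion vector from Dirichlet(counts + prior) per
sample, CLR-transforming each instance (base 2), and computing every
statistic across instances:

* the standardized effect size — the median between-group difference
  divided by the larger within-group dispersion, both defined as medians
  over pairwise differences of the pooled per-group CLR values;
* expected p-values — two-sided Welch t and Wilcoxon rank-sum tests run
  per instance across samples, Benjamini-Hochberg adjusted across features
  within each instance, then averaged over instances (the "expected BH"
  or eBH value).

The pairwise-difference estimands are defined by full enumeration over the
pooled values (``mode="exact"``); ``mode="subsample"`` draws a fixed
number of random pairs with an explicit seed and converges to the exact
values as the pair budget grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.base import BaseEstimator

from .io import CountTable
from .transform import clr

__all__ = [
    "GroupDesign",
    "MonteCarloEnsemble",
    "sample_mc_instances",
    "effect_statistics",
    "per_instance_effects",
    "per_instance_tests",
    "benjamini_hochberg",
    "aldex_effects",
    "effect_plot_data",
    "ma_plot_data",
    "DirichletEffectEstimator",
]


@dataclass(frozen=True)
class GroupDesign:
    """A two-group comparison: one of exactly two labels per sample.

    Label order is fixed by first appearance in ``conditions``; the first
    label is group A, the second group B, and ``diff.btw`` reads B minus A.
    """

    sample_ids: tuple[str, ...]
    conditions: tuple[str, ...]

    def __init__(self, sample_ids: Sequence[str], conditions: Sequence[str]):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in sample_ids))
        object.__setattr__(self, "conditions", tuple(str(c) for c in conditions))
        if len(self.sample_ids) != len(self.conditions):
            raise ValueError("one condition label per sample is required")
        labels = list(dict.fromkeys(self.conditions))
        if len(labels) != 2:
            raise ValueError(
                f"exactly two condition labels are required, got {labels}"
            )

    @property
    def labels(self) -> tuple[str, str]:
        ordered = list(dict.fromkeys(self.conditions))
        return ordered[0], ordered[1]

    def indices(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of group A and group B within ``sample_ids``."""
        lab = dict(zip(self.sample_ids, self.conditions))
        missing = [s for s in sample_ids if s not in lab]
        if missing:
            raise ValueError(f"design does not cover samples: {missing}")
        a, b = self.labels
        ia = np.array([i for i, s in enumerate(sample_ids) if lab[s] == a], dtype=int)
        ib = np.array([i for i, s in enumerate(sample_ids) if lab[s] == b], dtype=int)
        if ia.size == 0 or ib.size == 0:
            raise ValueError("both groups must be non-empty on these samples")
        return ia, ib

    @classmethod
    def from_metadata(cls, metadata, variable: str) -> "GroupDesign":
        col = metadata.column(variable).dropna()
        return cls(list(col.index), [str(v) for v in col])


@dataclass
class MonteCarloEnsemble:
    """K posterior CLR instances of a count table.

    ``instances`` has shape (K, n_features, n_samples); regenerating with
    the same seed reproduces it bit-identically.  ``proportions`` holds the
    pre-CLR Dirichlet draws when they were requested.
    """

    instances: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    prior: float
    seed: int
    proportions: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]


def _as_count_array(counts) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(counts, CountTable):
        return (
            counts.counts.to_numpy(dtype=float),
            counts.feature_ids,
            counts.sample_ids,
        )
    if isinstance(counts, pd.DataFrame):
        return (
            counts.to_numpy(dtype=float),
            [str(i) for i in counts.index],
            [str(c) for c in counts.columns],
        )
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2:
        raise ValueError("counts must be a 2-D features x samples array")
    return (
        arr,
        [f"F{i}" for i in range(arr.shape[0])],
        [f"S{j}" for j in range(arr.shape[1])],
    )


def sample_mc_instances(
    counts,
    n_instances: int = 128,
    prior: float = 0.5,
    seed: int = 0,
    keep_proportions: bool = False,
) -> MonteCarloEnsemble:
    """Draw K Dirichlet posterior instances per sample and CLR them.

    For each sample independently, each instance is a draw from
    Dirichlet(x + prior) over features, transformed with the base-2 CLR.
    Deterministic given ``seed``.

    Parameters
    ----------
    counts
        CountTable, features x samples DataFrame, or 2-D array.
    n_instances
        K, the number of Monte-Carlo instances (>= 1).
    prior
        Dirichlet concentration added to every count (> 0); 0.5 is the
        Jeffreys-style default of the compositional literature.
    keep_proportions
        Also retain the pre-CLR proportion draws (for calibration checks).
    """
    x, feature_ids, sample_ids = _as_count_array(counts)
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if prior <= 0:
        raise ValueError("prior must be positive")
    if x.shape[0] < 2:
        raise ValueError("need at least two features for a log-ratio analysis")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if (x.sum(axis=0) <= 0).any():
        raise ValueError("every sample must have a positive total count")

    rng = np.random.default_rng(seed)
    alpha = x + prior  # (F, S)
    # Dirichlet via normalized gammas, one vectorized draw for the ensemble
    gammas = rng.standard_gamma(alpha, size=(n_instances,) + alpha.shape)
    props = gammas / gammas.sum(axis=1, keepdims=True)
    logs = np.log2(props)
    clr_vals = logs - logs.mean(axis=1, keepdims=True)
    return MonteCarloEnsemble(
        instances=clr_vals,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        prior=prior,
        seed=seed,
        proportions=props if keep_proportions else None,
    )


# ---------------------------------------------------------------------------
# effect-size estimands
# ---------------------------------------------------------------------------

_MAX_EXACT_PAIRS = 1 << 26  # per-feature pair budget for exact enumeration


def _pooled(ensemble: MonteCarloEnsemble, idx: np.ndarray) -> np.ndarray:
    """Pool CLR values across instances and group samples -> (F, n*K)."""
    # (K, F, n) -> (F, K*n)
    sub = ensemble.instances[:, :, idx]
    return np.moveaxis(sub, 0, 1).reshape(sub.shape[1], -1)


@lru_cache(maxsize=8)
def _triu_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def effect_statistics(
    ensemble: MonteCarloEnsemble,
    design: GroupDesign,
    mode: str = "subsample",
    max_pairs: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median-of-pairwise-differences effect sizes per feature.

    Pools the CLR values of each group across instances, then per feature:

    * ``diff.btw`` — median of ``b - a`` over ordered between-group pairs;
    * ``diff.win`` — the larger of the two within-group medians of
      ``|u - v|`` over unordered pairs;
    * ``effect`` — ``diff.btw / diff.win`` (0/0 -> 0, x/0 -> signed inf);
    * ``overlap`` — the smaller of the fractions of between-group pairs
      above and below zero, zero differences split evenly;
    * ``rab.all`` and ``rab.win.<group>`` — median CLR abundances.

    ``mode="exact"`` enumerates every pair (the defining estimand);
    ``mode="subsample"`` draws ``max_pairs`` seeded random pairs.
    """
    if mode not in ("exact", "subsample"):
        raise ValueError(f"unknown mode {mode!r}")
    ia, ib = design.indices(ensemble.sample_ids)
    pa = _pooled(ensemble, ia)
    pb = _pooled(ensemble, ib)
    na, nb = pa.shape[1], pb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(
            "each group needs at least 2 pooled values for within-group dispersion"
        )
    n_feat = pa.shape[0]

    if mode == "exact":
        if max(na * nb, na * (na - 1) // 2, nb * (nb - 1) // 2) > _MAX_EXACT_PAIRS:
            raise MemoryError(
                "exact pair enumeration too large; use mode='subsample'"
            )
        diff_btw = np.empty(n_feat)
        diff_win_a = np.empty(n_feat)
        diff_win_b = np.empty(n_feat)
        frac_pos = np.empty(n_feat)
        frac_neg = np.empty(n_feat)
        ti_a = _triu_pairs(na)
        ti_b = _triu_pairs(nb)
        for f in range(n_feat):
            btw = np.subtract.outer(pb[f], pa[f]).ravel()
            diff_btw[f] = np.median(btw)
            n_pos = np.count_nonzero(btw > 0)
            n_neg = np.count_nonzero(btw < 0)
            n_zero = btw.size - n_pos - n_neg
            frac_pos[f] = (n_pos + 0.5 * n_zero) / btw.size
            frac_neg[f] = (n_neg + 0.5 * n_zero) / btw.size
            wa = np.abs(pa[f][ti_a[0]] - pa[f][ti_a[1]])
            wb = np.abs(pb[f][ti_b[0]] - pb[f][ti_b[1]])
            diff_win_a[f] = np.median(wa)
            diff_win_b[f] = np.median(wb)
    else:
        if max_pairs < 1:
            raise ValueError("max_pairs must be >= 1")
        rng = np.random.default_rng(seed)
        ja = rng.integers(0, na, size=max_pairs)
        jb = rng.integers(0, nb, size=max_pairs)
        btw = pb[:, jb] - pa[:, ja]  # (F, max_pairs)
        diff_btw = np.median(btw, axis=1)
        n_pos = np.count_nonzero(btw > 0, axis=1)
        n_neg = np.count_nonzero(btw < 0, axis=1)
        n_zero = max_pairs - n_pos - n_neg
        frac_pos = (n_pos + 0.5 * n_zero) / max_pairs
        frac_neg = (n_neg + 0.5 * n_zero) / max_pairs

        def _within(p: np.ndarray, n: int) -> np.ndarray:
            i = rng.integers(0, n, size=max_pairs)
            j = rng.integers(0, n - 1, size=max_pairs)
            j = j + (j >= i)  # uniform over distinct ordered pairs
            return np.median(np.abs(p[:, i] - p[:, j]), axis=1)

        diff_win_a = _within(pa, na)
        diff_win_b = _within(pb, nb)

    diff_win = np.maximum(diff_win_a, diff_win_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = diff_btw / diff_win
    with np.errstate(invalid="ignore"):
        effect = np.where(
            diff_win > 0,
            effect,
            np.where(diff_btw == 0, 0.0, np.sign(diff_btw) * np.inf),
        )
    overlap = np.minimum(frac_pos, frac_neg)

    lab_a, lab_b = design.labels
    out = pd.DataFrame(
        {
            "rab.all": np.median(np.concatenate([pa, pb], axis=1), axis=1),
            f"rab.win.{lab_a}": np.median(pa, axis=1),
            f"rab.win.{lab_b}": np.median(pb, axis=1),
            "diff.btw": diff_btw,
            "diff.win": diff_win,
            "effect": effect,
            "overlap": overlap,
        },
        index=pd.Index(ensemble.feature_ids, name="feature_id"),
    )
    out.attrs["group_labels"] = (lab_a, lab_b)
    return out


def per_instance_effects(
    ensemble: MonteCarloEnsemble, design: GroupDesign
) -> np.ndarray:
    """Effect size computed within each instance separately -> (K, F).

    The spread of these values across instances is the uncertainty band an
    effect plot's hover detail would show; summarize with quantiles.
    """
    ia, ib = design.indices(ensemble.sample_ids)
    a = ensemble.instances[:, :, ia]  # (K, F, nA)
    b = ensemble.instances[:, :, ib]
    btw = b[..., None, :] - a[..., :, None]  # (K, F, nA, nB)
    diff_btw = np.median(btw.reshape(*btw.shape[:2], -1), axis=-1)

    def win(g: np.ndarray) -> np.ndarray:
        n = g.shape[-1]
        if n < 2:
            raise ValueError("each group needs at least 2 samples")
        i, j = _triu_pairs(n)
        return np.median(np.abs(g[..., i] - g[..., j]), axis=-1)

    diff_win = np.maximum(win(a), win(b))
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = diff_btw / diff_win
        return np.where(
            diff_win > 0,
            eff,
            np.where(diff_btw == 0, 0.0, np.sign(diff_btw) * np.inf),
        )


# ---------------------------------------------------------------------------
# per-instance hypothesis tests
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _rank_sum_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of the group-1 rank sum (no ties): counts per sum.

    counts[s] = number of n1-subsets of ranks {1..n1+n2} summing to
    ``s + n1(n1+1)/2`` (index offset by the minimal sum).
    """
    total = n1 + n2
    max_u = n1 * n2
    ways = np.zeros((n1 + 1, max_u + 1))
    ways[0, 0] = 1.0
    # subset-sum DP over ranks; track sum above the minimal possible
    for r in range(1, total + 1):
        for k in range(min(r, n1), 0, -1):
            shift = r - k  # adding rank r as the k-th smallest element
            if shift <= max_u:
                ways[k, shift:] += ways[k - 1, : max_u + 1 - shift]
    return ways[n1]


def _wilcoxon_exact_p(u: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Two-sided exact rank-sum p for tie-free data, vectorized over u."""
    counts = _rank_sum_counts(n1, n2)
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    sf_incl = np.cumsum(counts[::-1])[::-1] / total  # P(U >= u)
    u = np.asarray(u, dtype=int)
    p = 2.0 * np.minimum(cdf[u], sf_incl[u])
    return np.minimum(p, 1.0)


def per_instance_tests(
    ensemble: MonteCarloEnsemble,
    design: GroupDesign,
    exact_threshold: int = 20,
) -> pd.DataFrame:
    """Expected p and expected-BH values per feature.

    Per instance and feature, a two-sided Welch unequal-variance t-test and
    a two-sided Wilcoxon rank-sum test compare the two groups' CLR values
    across samples; within each instance p-values are Benjamini-Hochberg
    adjusted across features; the report is the arithmetic mean over
    instances (columns ``we.ep``, ``we.eBH``, ``wi.ep``, ``wi.eBH``).

    The rank-sum test uses exact enumeration when the combined sample size
    is at most ``exact_threshold`` and the feature is tie-free in that
    instance, and the normal approximation with tie and continuity
    correction otherwise.
    """
    ia, ib = design.indices(ensemble.sample_ids)
    n1, n2 = ia.size, ib.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples for testing")
    a = ensemble.instances[:, :, ia]  # (K, F, n1)
    b = ensemble.instances[:, :, ib]

    # Welch t, vectorized across instances and features
    res = _stats.ttest_ind(a, b, axis=-1, equal_var=False)
    we_p = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=-1, ddof=1)
    var_b = b.var(axis=-1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=-1), b.mean(axis=-1))
        we_p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), we_p)

    # Wilcoxon rank-sum
    combined = np.concatenate([a, b], axis=-1)  # (K, F, n)
    ranks = _stats.rankdata(combined, axis=-1)
    w1 = ranks[..., :n1].sum(axis=-1)
    u1 = w1 - n1 * (n1 + 1) / 2.0

    # tie detection per (instance, feature)
    srt = np.sort(combined, axis=-1)
    has_ties = (np.diff(srt, axis=-1) == 0).any(axis=-1)

    n = n1 + n2
    wi_p = np.empty_like(u1)
    use_exact = (n <= exact_threshold) & ~has_ties
    if use_exact.any():
        wi_p[use_exact] = _wilcoxon_exact_p(
            np.rint(u1[use_exact]).astype(int), n1, n2
        )
    approx = ~use_exact
    if approx.any():
        # normal approximation with tie and continuity correction;
        # tie-term sum(t^3 - t) per (K, F) via run-length of equal values
        tie_term = np.zeros(u1.shape)
        flat_srt = srt.reshape(-1, n)
        flat_tt = tie_term.reshape(-1)
        for idx in np.flatnonzero(approx.reshape(-1)):
            vals = flat_srt[idx]
            _, cnt = np.unique(vals, return_counts=True)
            flat_tt[idx] = float((cnt**3 - cnt).sum())
        mu = n1 * n2 / 2.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (np.abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
        p_approx = 2.0 * _stats.norm.sf(z)
        p_approx = np.where(sigma2 > 0, np.minimum(p_approx, 1.0), 1.0)
        wi_p[approx] = p_approx[approx]

    # adjust across features (last axis) within each instance
    we_bh = _bh_along_last(we_p)
    wi_bh = _bh_along_last(wi_p)

    out = pd.DataFrame(
        {
            "we.ep": we_p.mean(axis=0),
            "we.eBH": we_bh.mean(axis=0),
            "wi.ep": wi_p.mean(axis=0),
            "wi.eBH": wi_bh.mean(axis=0),
        },
        index=pd.Index(ensemble.feature_ids, name="feature_id"),
    )
    return out


def _bh_along_last(p: np.ndarray) -> np.ndarray:
    """BH step-up along the last axis; input must be NaN-free."""
    m = p.shape[-1]
    order = np.argsort(p, axis=-1, kind="stable")
    ranked = np.take_along_axis(p, order, axis=-1)
    q = ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[..., ::-1], axis=-1)[..., ::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    np.put_along_axis(out, order, q, axis=-1)
    return out


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of a p-value vector.

    Sorts ascending, multiplies by m/rank, enforces monotonicity by a
    cumulative minimum from the largest rank, caps at 1 and returns in the
    input order.  NaN entries propagate and are excluded from m.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("benjamini_hochberg expects a 1-D vector")
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = _bh_along_last(p[finite])
    return out


# ---------------------------------------------------------------------------
# convenience: the full differential-abundance table, ALDEx2 dialect
# ---------------------------------------------------------------------------

def aldex_effects(
    counts,
    design: GroupDesign,
    n_instances: int = 128,
    prior: float = 0.5,
    seed: int = 0,
    mode: str = "subsample",
    max_pairs: int = 10000,
    include_tests: bool = True,
    exact_threshold: int = 20,
) -> pd.DataFrame:
    """Monte-Carlo sampling, effect sizes and expected tests in one call.

    Returns the full per-feature table in the ALDEx2 column dialect so it
    can round-trip through :func:`codaplot.io.read_effect_table`.
    """
    ensemble = sample_mc_instances(
        counts, n_instances=n_instances, prior=prior, seed=seed
    )
    eff = effect_statistics(
        ensemble, design, mode=mode, max_pairs=max_pairs, seed=seed
    )
    if include_tests:
        tests = per_instance_tests(ensemble, design, exact_threshold=exact_threshold)
        eff = eff.join(tests)
    eff.attrs["group_labels"] = design.labels
    return eff


# ---------------------------------------------------------------------------
# plot record sets
# ---------------------------------------------------------------------------

def _classify(
    effects: pd.DataFrame,
    effect_cutoff: float,
    ebh_cutoff: float,
    test: str,
) -> pd.Series:
    col = {"wilcoxon": "wi.eBH", "welch": "we.eBH"}.get(test)
    if col is None:
        raise ValueError(f"unknown test {test!r}")
    big_effect = effects["effect"].abs() >= effect_cutoff
    if col in effects.columns:
        significant = effects[col].le(ebh_cutoff).fillna(False)
    else:
        significant = pd.Series(False, index=effects.index)
    cls = np.select(
        [big_effect & significant, big_effect, significant],
        ["both", "effect_only", "test_significant"],
        default="nonsignificant",
    )
    return pd.Series(cls, index=effects.index, name="class")


def effect_plot_data(
    effects: pd.DataFrame,
    effect_cutoff: float = 1.0,
    ebh_cutoff: float = 0.05,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Effect-plot records: within-group vs between-group difference.

    One record per feature with x = ``diff.win``, y = ``diff.btw`` and a
    significance class; the y = +/-x diagonals correspond to |effect| = 1.
    """
    return pd.DataFrame(
        {
            "x": effects["diff.win"],
            "y": effects["diff.btw"],
            "effect": effects["effect"],
            "class": _classify(effects, effect_cutoff, ebh_cutoff, test),
        },
        index=effects.index,
    )


def ma_plot_data(
    effects: pd.DataFrame,
    effect_cutoff: float = 1.0,
    ebh_cutoff: float = 0.05,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """MA-plot records: difference (M) vs median abundance (A) per feature."""
    return pd.DataFrame(
        {
            "x": effects["rab.all"],
            "y": effects["diff.btw"],
            "effect": effects["effect"],
            "class": _classify(effects, effect_cutoff, ebh_cutoff, test),
        },
        index=effects.index,
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class DirichletEffectEstimator(BaseEstimator):
    """Two-group Dirichlet Monte-Carlo differential abundance (sklearn API).

    ``fit(X, y)`` takes counts with samples as rows and features as
    columns (the sklearn layout) and a two-level label vector ``y``; the
    fitted per-feature statistics live in ``effects_``.

    Parameters
    ----------
    n_instances : int, default 128
        Monte-Carlo instances K.
    prior : float, default 0.5
        Dirichlet prior added to every count.
    mode : {"subsample", "exact"}
        Pairwise-difference enumeration strategy for the effect size.
    max_pairs : int, default 10000
        Pair budget per feature in subsample mode.
    effect_cutoff, ebh_cutoff
        Thresholds used by :meth:`decision_function`-style classing in
        :meth:`plot_frame`.
    random_state : int, default 0
        Seed for Dirichlet sampling and pair subsampling.
    """

    def __init__(
        self,
        n_instances: int = 128,
        prior: float = 0.5,
        mode: str = "subsample",
        max_pairs: int = 10000,
        effect_cutoff: float = 1.0,
        ebh_cutoff: float = 0.05,
        random_state: int = 0,
    ):
        self.n_instances = n_instances
        self.prior = prior
        self.mode = mode
        self.max_pairs = max_pairs
        self.effect_cutoff = effect_cutoff
        self.ebh_cutoff = ebh_cutoff
        self.random_state = random_state

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("y must label every row of X")
        sample_ids = [f"S{i}" for i in range(X.shape[0])]
        if feature_names is None:
            feature_names = [f"F{j}" for j in range(X.shape[1])]
        counts = pd.DataFrame(X.T, index=list(feature_names), columns=sample_ids)
        design = GroupDesign(sample_ids, [str(v) for v in y])
        self.design_ = design
        self.classes_ = np.array(design.labels)
        self.effects_ = aldex_effects(
            counts,
            design,
            n_instances=self.n_instances,
            prior=self.prior,
            seed=self.random_state,
            mode=self.mode,
            max_pairs=self.max_pairs,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def plot_frame(self, kind: str = "effect") -> pd.DataFrame:
        """Effect- or MA-plot records for the fitted comparison."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "effects_")
        fn = {"effect": effect_plot_data, "ma": ma_plot_data}.get(kind)
        if fn is None:
            raise ValueError(f"unknown plot kind {kind!r}")
        return fn(
            self.effects_,
            effect_cutoff=self.effect_cutoff,
            ebh_cutoff=self.ebh_cutoff,
        )
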
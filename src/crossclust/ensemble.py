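"""Monte Carlo iterative one-against-one ensemble classification.

Used twice in the pipeline: first to clean main-class labels (removing or
correcting low-confidence samples), then to finalize subtype labels. Each
round draws bootstrap training sets (``n_per_class`` samples per class,
with replacement) over ``n_iters`` iterations; for every pair of classes,
every supervised feature-selection method (moderated-t q-values, density
overlap, SVM weights), every feature-count in a doubling grid and every
classifier (kNN, random forest, linear SVM), the out-of-bootstrap samples
are predicted. An expert casts a vote for class *c* on a sample only when
the sample wins all of *c*'s one-against-one decisions (w − 1 wins).
High-confidence labels (> 90% vote share) feed back into the training set
for the next round; after convergence, samples above the 75% share keep
their (possibly corrected) labels and the rest are flagged removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .matrix import as_frame

FS_METHODS = ("modt", "ovl", "wsv")
CLF_METHODS = ("knn", "rf", "svm")
DEFAULT_FEATURE_GRID = (32, 64, 128, 256, 512, 1024)


@dataclass
class EnsembleConfig:
    """Knobs of the iterative ensemble.

    ``total_possible`` (votes available per round) is
    ``n_iters × |fs_methods| × |clf_methods| × |n_feature_grid|`` — 5400 at
    the defaults.
    """

    n_rounds_max: int = 5
    n_iters: int = 100
    n_per_class: int = 100
    fs_methods: tuple = FS_METHODS
    clf_methods: tuple = CLF_METHODS
    n_feature_grid: tuple = DEFAULT_FEATURE_GRID
    feedback_threshold: float = 0.90
    final_threshold: float = 0.75
    plateau_tol: float = 0.01
    knn_k: int = 5
    rf_trees: int = 100
    svm_c: float = 1.0
    seed: int = 0

    def validate(self) -> "EnsembleConfig":
        if not (0 < self.final_threshold <= self.feedback_threshold < 1):
            raise ValueError("need 0 < final_threshold <= feedback_threshold < 1")
        unknown = set(self.fs_methods) - set(FS_METHODS)
        if unknown:
            raise ValueError(f"unknown feature-selection method(s): {sorted(unknown)}")
        unknown = set(self.clf_methods) - set(CLF_METHODS)
        if unknown:
            raise ValueError(f"unknown classifier(s): {sorted(unknown)}")
        return self

    @property
    def total_possible(self) -> int:
        return (self.n_iters * len(self.fs_methods) * len(self.clf_methods)
                * len(self.n_feature_grid))


@dataclass
class VoteTally:
    """Accumulated votes of one round."""

    votes: pd.DataFrame          # samples × classes integer counts
    opportunities: pd.Series     # per-sample experts the sample was eligible for
    total_possible: int

    def shares(self) -> pd.DataFrame:
        """Per-sample vote shares, normalized by individual opportunity.

        At desk-scale cohorts a sample sits inside the bootstrap for many
        iterations; dividing by the per-sample out-of-bootstrap expert
        count rather than ``total_possible`` keeps shares comparable to
        the large-cohort regime where the two denominators coincide.
        """
        denom = self.opportunities.replace(0, np.nan)
        return self.votes.div(denom, axis=0).fillna(0.0)


# ---------------------------------------------------------------------------
# supervised feature scoring
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float, iters: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration (Smyth's scheme)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(iters):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y - dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderated_t_qvalues(matrix, group_labels, d0_override: float | None = None):
    """Empirical-Bayes moderated two-group t-test with BH q-values.

    Per-gene residual variances are shrunk toward a common prior variance
    s0² with prior degrees of freedom d0, both estimated from the marginal
    distribution of the log sample variances via digamma/trigamma moments;
    the moderated t uses d0 + d_g degrees of freedom. ``d0_override``
    forces the prior df (0 → ordinary t; ``inf`` → all variances equal
    s0²), mainly for validation.

    Returns ``(qvalues, tstats)`` as per-gene Series.
    """
    frame = as_frame(matrix)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {len(groups)}")
    x = frame.to_numpy(dtype=float)
    m1 = labels == groups[0]
    m2 = labels == groups[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    mean1 = x[:, m1].mean(axis=1)
    mean2 = x[:, m2].mean(axis=1)
    dg = n1 + n2 - 2
    s2 = (x[:, m1].var(axis=1, ddof=1) * (n1 - 1)
          + x[:, m2].var(axis=1, ddof=1) * (n2 - 1)) / dg

    # prior (d0, s0²) from the marginal distribution of log s²
    positive = s2 > 0
    if d0_override is not None:
        d0 = float(d0_override)
        if positive.any():
            z = np.log(s2[positive])
            e = z - special.digamma(dg / 2) + np.log(dg / 2)
            s0_sq = float(np.exp(e.mean()))
        else:
            s0_sq = 1e-8
    elif positive.sum() >= 2:
        z = np.log(s2[positive])
        e = z - special.digamma(dg / 2) + np.log(dg / 2)
        evar = max(np.var(e, ddof=1) - special.polygamma(1, dg / 2), 0.0)
        if evar > 0:
            d0 = 2.0 * _trigamma_inverse(evar)
            s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2)
                                 - np.log(d0 / 2)))
        else:
            d0, s0_sq = np.inf, float(np.exp(e.mean()))
    else:
        d0, s0_sq = 0.0, float(s2.mean() if s2.size else 1e-8)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg) if d0 > 0 else s2
        df_total = np.full_like(s2, d0 + dg)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean1 - mean2) / se
    t = np.where(se > 0, t, 0.0)
    p = np.where(np.isinf(df_total), 2 * stats.norm.sf(np.abs(t)),
                 2 * stats.t.sf(np.abs(t), np.where(np.isinf(df_total), 1, df_total)))
    q = multipletests(p, method="fdr_bh")[1]
    return (pd.Series(q, index=frame.index, name="qvalue"),
            pd.Series(t, index=frame.index, name="moderated_t"))


def _silverman_bw(x: np.ndarray) -> float:
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(x.mean()) * 1e-3, 1e-3)  # point-mass smoothing
    return 0.9 * spread * n ** (-0.2)


def _adaptive_bandwidths(x: np.ndarray) -> np.ndarray:
    """Per-point bandwidths by the Abramson square-root law."""
    n = len(x)
    h = _silverman_bw(x)
    d = (x[:, None] - x[None, :]) / h
    pilot = np.exp(-0.5 * d ** 2).sum(axis=1) / (n * h * np.sqrt(2 * np.pi))
    pilot = np.maximum(pilot, 1e-300)
    g = np.exp(np.mean(np.log(pilot)))
    lam = np.sqrt(g / pilot)  # (pilot/g)^(-1/2)
    return h * lam


def _adaptive_density(x: np.ndarray, bw: np.ndarray, grid: np.ndarray) -> np.ndarray:
    u = (grid[None, :] - x[:, None]) / bw[:, None]
    return (np.exp(-0.5 * u ** 2) / (bw[:, None] * np.sqrt(2 * np.pi))
            ).sum(axis=0) / len(x)


def ovl_coefficient(x1, x2, n_grid: int = 512) -> float:
    """Overlap coefficient of two locally adaptive kernel densities.

    ``OVL = ∫ min(f̂₁, f̂₂)`` on a shared grid spanning both samples plus
    three maximal (adaptive) bandwidths of margin; 0 = disjoint,
    1 = identical.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each sample needs at least 5 points")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if np.allclose(a.mean(), b.mean()) else 0.0
    bw_a = _adaptive_bandwidths(a)
    bw_b = _adaptive_bandwidths(b)
    margin = 3 * max(bw_a.max(), bw_b.max())
    lo = min(a.min(), b.min()) - margin
    hi = max(a.max(), b.max()) + margin
    grid = np.linspace(lo, hi, n_grid)
    f1 = _adaptive_density(a, bw_a, grid)
    f2 = _adaptive_density(b, bw_b, grid)
    return float(np.clip(np.trapezoid(np.minimum(f1, f2), grid), 0.0, 1.0))


def ovl_scores(matrix, group_labels) -> pd.Series:
    """Per-gene OVL between the two groups (smaller = more discriminative)."""
    frame = as_frame(matrix)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    m1 = labels == groups[0]
    m2 = labels == groups[1]
    x = frame.to_numpy(dtype=float)
    vals = np.array([ovl_coefficient(x[g, m1], x[g, m2], n_grid=256)
                     for g in range(x.shape[0])])
    return pd.Series(vals, index=frame.index, name="ovl")


def svm_weight_ranks(matrix, group_labels, c: float = 1.0) -> pd.Series:
    """Rank genes by |weight| of a linear max-margin classifier (1 = best).

    Features are standardized before the fit; ties keep stable gene order.
    """
    frame = as_frame(matrix)
    labels = np.asarray(group_labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("exactly two groups required")
    x = frame.to_numpy(dtype=float).T  # samples × genes
    if min((labels == g).sum() for g in np.unique(labels)) < 2:
        raise ValueError("each class needs at least 2 samples")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel="linear", C=c)
    clf.fit((x - mu) / sd, labels)
    w = np.abs(np.asarray(clf.coef_).ravel())
    order = np.argsort(-w, kind="stable")
    ranks = np.empty(len(w), dtype=int)
    ranks[order] = np.arange(1, len(w) + 1)
    return pd.Series(ranks, index=frame.index, name="wsv_rank")


def rank_features(matrix, group_labels, method: str) -> pd.Index:
    """Ordered gene index, best first, for one supervised FS method."""
    if method == "modt":
        q, t = moderated_t_qvalues(matrix, group_labels)
        key = np.lexsort((np.arange(len(q)), q.to_numpy()))
        return q.index[key]
    if method == "ovl":
        s = ovl_scores(matrix, group_labels)
        key = np.lexsort((np.arange(len(s)), s.to_numpy()))
        return s.index[key]
    if method == "wsv":
        r = svm_weight_ranks(matrix, group_labels)
        return r.sort_values(kind="stable").index
    raise ValueError(f"unknown feature-selection method {method!r}")


# ---------------------------------------------------------------------------
# iteration machinery
# ---------------------------------------------------------------------------

def _make_classifier(name: str, config: EnsembleConfig, seed: int):
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=config.knn_k)
    if name == "rf":
        return RandomForestClassifier(n_estimators=config.rf_trees,
                                      random_state=seed, n_jobs=1)
    if name == "svm":
        return SVC(kernel="linear", C=config.svm_c)
    raise ValueError(f"unknown classifier {name!r}")


def run_iteration(x, labeled: pd.Series, config: EnsembleConfig, iter_seed: int):
    """One Monte Carlo iteration: bootstrap, train OAO experts, collect votes.

    ``x`` is the genes × samples matrix; ``labeled`` maps sample id →
    class for the current training pool. Returns ``(votes, opportunities)``
    — votes is a samples × classes count DataFrame over the out-of-bootstrap
    samples, opportunities the per-sample number of expert decisions the
    sample was eligible for in this iteration.
    """
    config.validate()
    frame = as_frame(x)
    labeled = pd.Series(labeled).dropna()
    classes = sorted(labeled.unique())
    w = len(classes)
    if w < 2:
        raise ValueError("need at least two labeled classes")
    rng = np.random.default_rng(iter_seed)

    boot_ids: dict[str, np.ndarray] = {}
    in_boot: set = set()
    for c in classes:
        pool = labeled.index[labeled == c].to_numpy()
        if len(pool) == 0:
            raise ValueError(f"class {c!r} has no labeled samples")
        draw = rng.choice(pool, size=config.n_per_class, replace=True)
        boot_ids[c] = draw
        in_boot.update(draw.tolist())

    test_ids = [s for s in frame.columns if s not in in_boot]
    votes = pd.DataFrame(0, index=frame.columns, columns=classes, dtype=int)
    opportunities = pd.Series(0, index=frame.columns, dtype=int)
    if not test_ids:
        return votes, opportunities

    pairs = list(combinations(classes, 2))
    grid = [n for n in config.n_feature_grid if n <= frame.shape[0]]
    if len(grid) < len(config.n_feature_grid):
        warnings.warn("feature grid truncated to the number of available genes")
    n_experts = len(config.fs_methods) * len(config.clf_methods) * len(grid)
    opportunities.loc[test_ids] = n_experts

    # wins[(fs, n_feat, clf)] : samples × classes pairwise-win counts
    expert_keys = [(fs, n, clf) for fs in config.fs_methods
                   for n in grid for clf in config.clf_methods]
    wins = {key: np.zeros((len(test_ids), w), dtype=int) for key in expert_keys}
    class_pos = {c: j for j, c in enumerate(classes)}

    for a, b in pairs:
        train_ids = np.concatenate([boot_ids[a], boot_ids[b]])
        y_train = np.array([a] * config.n_per_class + [b] * config.n_per_class)
        x_pair = frame[train_ids]
        for fs in config.fs_methods:
            ranked = rank_features(x_pair, y_train, fs)
            for n_feat in grid:
                top = ranked[:n_feat]
                xt = frame.loc[top, train_ids].to_numpy(dtype=float).T
                xs = frame.loc[top, test_ids].to_numpy(dtype=float).T
                for clf_name in config.clf_methods:
                    clf = _make_classifier(clf_name, config,
                                           int(rng.integers(2 ** 31 - 1)))
                    clf.fit(xt, y_train)
                    pred = clf.predict(xs)
                    win = wins[(fs, n_feat, clf_name)]
                    for i, p in enumerate(pred):
                        win[i, class_pos[p]] += 1

    for key in expert_keys:
        win = wins[key]
        for i in range(len(test_ids)):
            j = vote_from_wins(win[i], w)
            if j is not None:
                votes.loc[test_ids[i], classes[j]] += 1
    return votes, opportunities


def vote_from_wins(win_counts, w: int):
    """Index of the class winning all of its w − 1 pairwise decisions.

    Returns ``None`` when the one-against-one outcomes are cyclic and no
    class reaches the maximal count (so the expert casts no vote).
    """
    win_counts = np.asarray(win_counts)
    maximal = np.flatnonzero(win_counts == w - 1)
    if len(maximal) != 1:
        return None
    return int(maximal[0])


def run_round(x, labeled: pd.Series, config: EnsembleConfig,
              round_seed: int) -> VoteTally:
    """Sum votes over ``config.n_iters`` iterations."""
    frame = as_frame(x)
    votes = None
    opps = pd.Series(0, index=frame.columns, dtype=int)
    rng = np.random.default_rng(round_seed)
    for _ in range(config.n_iters):
        it_seed = int(rng.integers(2 ** 31 - 1))
        v, o = run_iteration(frame, labeled, config, it_seed)
        votes = v if votes is None else votes.add(v, fill_value=0).astype(int)
        opps = opps.add(o, fill_value=0).astype(int)
    return VoteTally(votes=votes, opportunities=opps,
                     total_possible=config.total_possible)


def iterate_to_convergence(x, meta: pd.DataFrame, config: EnsembleConfig):
    """Full iterative ensemble: feedback rounds, plateau stop, final cut.

    ``meta`` must carry a ``label`` column (NaN = initially unlabeled).
    Samples whose winning vote share exceeds the feedback threshold join
    (or correct their label in) the training pool for the next round;
    rounds stop at ``n_rounds_max`` or when the count of confidently
    classified samples changes by less than ``plateau_tol``. Finally every
    sample above the final threshold is assigned its winning class; the
    rest are flagged removed.

    Confidence is judged *against the label a sample carries*: for an
    initially labeled sample, the final vote share of its own class must
    exceed the threshold for it to be retained (label cleaning removes
    unconfirmed samples rather than relabeling them); initially unlabeled
    samples are assigned their winning class when its share clears the
    threshold.

    Returns a copy of ``meta`` with columns ``final_label``, ``confidence``
    and ``removed``, plus the per-round :class:`VoteTally` list.
    """
    config.validate()
    frame = as_frame(x)
    if "label" not in meta.columns:
        raise ValueError("meta must have a 'label' column")
    labels = meta["label"].reindex(frame.columns)
    if labels.dropna().empty:
        raise ValueError("no initially labeled samples")

    current = labels.copy()
    rng = np.random.default_rng(config.seed)
    tallies: list[VoteTally] = []
    prev_confident = -np.inf
    shares = None
    for _ in range(config.n_rounds_max):
        tally = run_round(frame, current, config, int(rng.integers(2 ** 31 - 1)))
        tallies.append(tally)
        shares = tally.shares()
        best = shares.max(axis=1)
        winner = shares.idxmax(axis=1)
        confident = best > config.feedback_threshold
        # feedback: confident samples adopt the ensemble label; the training
        # pool only ever grows (initial labels stay unless corrected)
        current = labels.copy()
        current[confident] = winner[confident]
        n_conf = int(confident.sum())
        if prev_confident >= 0 and abs(n_conf - prev_confident) < config.plateau_tol * len(current):
            prev_confident = n_conf
            break
        prev_confident = n_conf

    best = shares.max(axis=1)
    winner = shares.idxmax(axis=1)
    # per-sample confidence: share of the sample's own initial label when it
    # has one (cleaning confirms existing labels), else the winning share
    conf = best.copy()
    final = winner.copy().astype(object)
    for s in frame.columns:
        init = labels.loc[s]
        if pd.notna(init):
            conf.loc[s] = shares.loc[s, init] if init in shares.columns else 0.0
            final.loc[s] = init
    keep = conf > config.final_threshold
    out = meta.copy()
    out["confidence"] = conf.reindex(out.index)
    out["final_label"] = final.reindex(out.index).where(keep.reindex(out.index),
                                                        other=pd.NA)
    out["removed"] = ~keep.reindex(out.index).fillna(False)
    return out, tallies
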
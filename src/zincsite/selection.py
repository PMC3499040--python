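"""Two-step random-forest feature selection.

Step one ranks features by the mean decrease in Gini impurity (MDGI)
averaged over repeated forests, standardized to Z-scores, and keeps the
top-k as optimal feature candidates (OFCs, k = 70 by default). Step two is
a backward stepwise elimination driven by the combined cross-validated
score AUC x recall x precision, with recall and precision read at the
fixed-precision operating point; a feature is removed only when its removal
strictly increases the combined score, and elimination stops when no
removal improves it.

Both steps are exposed as sklearn-style selector estimators so they compose
with pipelines; module-level functions wrap them for script use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .evaluate import (TARGET_PRECISION, counts_at_threshold, roc_auc,
                       threshold_at_precision)

OFC_SIZE = 70
N_TREES = 500
FULL_REPETITIONS = 100


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _combined_cv_score(
    X: np.ndarray,
    y: np.ndarray,
    columns: np.ndarray,
    rep_seeds: list[int],
    cv: int,
    n_trees: int,
    target_precision: float,
) -> float:
    """Mean over repetitions of the fold-averaged AUC*REC*PRE.

    Each repetition reshuffles stratified folds and refits forests with its
    own seed; recall and precision are read at the fixed-precision threshold
    chosen on each held-out fold. The same seed list is reused across
    candidate feature sets so comparisons within a round are paired.
    """
    Xs = X[:, columns]
    scores = []
    for seed in rep_seeds:
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        fold_scores = []
        for train_idx, test_idx in skf.split(Xs, y):
            rf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                        random_state=seed, n_jobs=1)
            rf.fit(Xs[train_idx], y[train_idx])
            pos_col = int(np.nonzero(rf.classes_ == 1)[0][0])
            s = rf.predict_proba(Xs[test_idx])[:, pos_col]
            yt = y[test_idx]
            if len(np.unique(yt)) < 2:
                continue
            auc = roc_auc(yt, s)
            thr, _ = threshold_at_precision(yt, s, target_precision)
            c = counts_at_threshold(yt, s, thr)
            rec = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
            pre = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
            fold_scores.append(auc * rec * pre)
        if fold_scores:
            scores.append(float(np.mean(fold_scores)))
    return float(np.mean(scores)) if scores else 0.0


# ---------------------------------------------------------------------------
# step one: MDGI Z-score ranking

class MDGIZScoreSelector(SelectorMixin, BaseEstimator):
    """Keep the top-k features by standardized mean-decrease-Gini importance.

    Importance x_i of feature i is the MDGI averaged over ``repetitions``
    independently seeded forests; the Z-score is (x_i - mean(x)) / sd(x)
    with the population standard deviation over all scored features. Ties
    at the rank boundary keep the lexicographically smaller feature name.

    Attributes (after fit): ``mean_importances_``, ``zscores_``, ``ranks_``,
    ``support_``, ``importance_table_``.
    """

    def __init__(self, top_k: int = OFC_SIZE, n_estimators: int = N_TREES,
                 repetitions: int = 10, random_state: int | None = None):
        self.top_k = top_k
        self.n_estimators = n_estimators
        self.repetitions = repetitions
        self.random_state = random_state

    def fit(self, X, y):
        frame = _as_frame(X)
        names = np.array([str(c) for c in frame.columns])
        Xa = frame.to_numpy(dtype=float)
        y = np.asarray(y)
        if Xa.shape[1] < 2:
            raise ValueError("need at least two features to rank")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes required")
        seeds = _spawn_seeds(self.random_state, self.repetitions)
        acc = np.zeros(Xa.shape[1])
        for seed in seeds:
            rf = RandomForestClassifier(n_estimators=self.n_estimators,
                                        max_features="sqrt", random_state=seed, n_jobs=1)
            rf.fit(Xa, y)
            acc += rf.feature_importances_
        mean_imp = acc / len(seeds)
        sd = float(np.std(mean_imp))  # population convention
        if sd == 0:
            raise ValueError("degenerate importances: zero variance across features")
        z = (mean_imp - mean_imp.mean()) / sd
        order = sorted(range(len(names)), key=lambda i: (-z[i], names[i]))
        ranks = np.empty(len(names), dtype=int)
        for rank, i in enumerate(order, start=1):
            ranks[i] = rank
        self.feature_names_in_ = names
        self.n_features_in_ = len(names)
        self.mean_importances_ = mean_imp
        self.zscores_ = z
        self.ranks_ = ranks
        k = min(self.top_k, len(names))
        if k < self.top_k:
            import warnings
            warnings.warn(f"only {len(names)} features scored; keeping all", stacklevel=2)
        self.support_ = ranks <= k
        self.importance_table_ = pd.DataFrame(
            {"mean_mdgi": mean_imp, "zscore": z, "rank": ranks},
            index=pd.Index(names, name="feature")).sort_values("rank")
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def _spawn_seeds(random_state: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(random_state if random_state is not None else 0)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def mdgi_zscores(matrix, n_trees: int = N_TREES, repetitions: int = 10,
                 seed: int | None = None) -> pd.DataFrame:
    """Importance table (mean MDGI, Z-score, rank) for a FeatureMatrix."""
    sel = MDGIZScoreSelector(top_k=matrix.X.shape[1], n_estimators=n_trees,
                             repetitions=repetitions, random_state=seed)
    sel.fit(matrix.X, matrix.y.to_numpy())
    return sel.importance_table_


def select_ofc(importance_table: pd.DataFrame, k: int = OFC_SIZE) -> list[str]:
    """Top-k features by Z-score (ties keep the lexicographically smaller name)."""
    ranked = importance_table.sort_values("rank")
    return list(ranked.index[:k])


# ---------------------------------------------------------------------------
# step two: stepwise elimination

@dataclass
class SelectionTrace:
    repetitions: int
    cv: int
    seed: int | None
    reduced_cost: bool
    initial_features: list[str]
    initial_score: float
    rounds: list[dict] = field(default_factory=list)

    @property
    def final_features(self) -> list[str]:
        for rec in reversed(self.rounds):
            if rec["removed"] is not None:
                return list(rec["surviving"])
        return list(self.initial_features)

    @property
    def final_score(self) -> float:
        for rec in reversed(self.rounds):
            if rec["removed"] is not None:
                return rec["score_after"]
        return self.initial_score

    def to_json_lines(self) -> str:
        header = {"repetitions": self.repetitions, "cv": self.cv, "seed": self.seed,
                  "reduced_cost": self.reduced_cost,
                  "initial_features": self.initial_features,
                  "initial_score": self.initial_score}
        lines = [json.dumps({"header": header})]
        lines += [json.dumps(rec) for rec in self.rounds]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_json_lines(cls, text: str) -> "SelectionTrace":
        lines = [json.loads(ln) for ln in text.splitlines() if ln.strip()]
        header = lines[0]["header"]
        trace = cls(repetitions=header["repetitions"], cv=header["cv"],
                    seed=header["seed"], reduced_cost=header["reduced_cost"],
                    initial_features=header["initial_features"],
                    initial_score=header["initial_score"])
        trace.rounds = lines[1:]
        return trace


class StepwiseEliminator(SelectorMixin, BaseEstimator):
    """Backward stepwise elimination by the combined AUC*REC*PRE score.

    ``mode="greedy"`` (default) evaluates every remaining feature each round
    and removes the one whose removal gives the largest strict improvement.
    ``mode="ranked"`` walks the features once in ascending-importance order
    (by MDGI Z-score computed at fit) and removes each feature whose removal
    improves the score.

    ``repetitions`` below 100 marks the trace as reduced-cost: the combined
    score is averaged over fewer refits than the full protocol.
    """

    def __init__(self, repetitions: int = FULL_REPETITIONS, cv: int = 5,
                 n_estimators: int = N_TREES,
                 target_precision: float = TARGET_PRECISION,
                 mode: str = "greedy", min_features: int = 1,
                 random_state: int | None = None):
        self.repetitions = repetitions
        self.cv = cv
        self.n_estimators = n_estimators
        self.target_precision = target_precision
        self.mode = mode
        self.min_features = min_features
        self.random_state = random_state

    def fit(self, X, y):
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.cv < 2:
            raise ValueError("cv must be >= 2")
        if self.mode not in ("greedy", "ranked"):
            raise ValueError(f"unknown mode {self.mode!r}")
        frame = _as_frame(X)
        names = np.array([str(c) for c in frame.columns])
        Xa = frame.to_numpy(dtype=float)
        y = np.asarray(y)
        rep_seeds = _spawn_seeds(self.random_state, self.repetitions)

        def score(cols: list[int]) -> float:
            return _combined_cv_score(Xa, y, np.array(cols), rep_seeds, self.cv,
                                      self.n_estimators, self.target_precision)

        remaining = list(range(len(names)))
        current = score(remaining)
        trace = SelectionTrace(
            repetitions=self.repetitions, cv=self.cv, seed=self.random_state,
            reduced_cost=self.repetitions < FULL_REPETITIONS,
            initial_features=list(names), initial_score=current)

        if self.mode == "greedy":
            round_no = 0
            while len(remaining) > self.min_features:
                round_no += 1
                candidate_scores = {}
                for col in remaining:
                    trial = [c for c in remaining if c != col]
                    candidate_scores[names[col]] = score(trial)
                best_name = max(sorted(candidate_scores), key=lambda n: candidate_scores[n])
                best_score = candidate_scores[best_name]
                if best_score > current:
                    remaining = [c for c in remaining if names[c] != best_name]
                    trace.rounds.append({
                        "round": round_no, "removed": best_name,
                        "score_before": current, "score_after": best_score,
                        "candidate_scores": candidate_scores,
                        "surviving": [names[c] for c in remaining]})
                    current = best_score
                else:
                    trace.rounds.append({
                        "round": round_no, "removed": None,
                        "score_before": current, "score_after": current,
                        "candidate_scores": candidate_scores,
                        "surviving": [names[c] for c in remaining]})
                    break
        else:  # ranked: one pass in ascending-importance order
            ranker = MDGIZScoreSelector(top_k=len(names), n_estimators=self.n_estimators,
                                        repetitions=min(self.repetitions, 10),
                                        random_state=self.random_state)
            ranker.fit(Xa, y)
            order = np.argsort(ranker.zscores_, kind="stable")  # least important first
            round_no = 0
            for col in order:
                if len(remaining) <= self.min_features:
                    break
                if col not in remaining:
                    continue
                round_no += 1
                trial = [c for c in remaining if c != col]
                trial_score = score(trial)
                removed = trial_score > current
                if removed:
                    remaining = trial
                trace.rounds.append({
                    "round": round_no, "removed": names[col] if removed else None,
                    "score_before": current,
                    "score_after": trial_score if removed else current,
                    "candidate_scores": {names[col]: trial_score},
                    "surviving": [names[c] for c in remaining]})
                if removed:
                    current = trial_score

        self.feature_names_in_ = names
        self.n_features_in_ = len(names)
        self.support_ = np.zeros(len(names), dtype=bool)
        self.support_[remaining] = True
        self.trace_ = trace
        self.final_score_ = current
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def stepwise_select(matrix, ofc_features: list[str], repetitions: int = FULL_REPETITIONS,
                    cv: int = 5, n_trees: int = N_TREES, seed: int | None = None,
                    mode: str = "greedy",
                    target_precision: float = TARGET_PRECISION) -> SelectionTrace:
    """Run stepwise elimination on the OFC columns of a FeatureMatrix."""
    missing = set(ofc_features) - set(matrix.feature_names)
    if missing:
        raise ValueError(f"OFC features not in matrix: {sorted(missing)[:5]}")
    sel = StepwiseEliminator(repetitions=repetitions, cv=cv, n_estimators=n_trees,
                             target_precision=target_precision, mode=mode,
                             random_state=seed)
    sel.fit(matrix.X[ofc_features], matrix.y.to_numpy())
    return sel.trace_
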
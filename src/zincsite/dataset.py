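"""Feature-matrix assembly, negative subsampling and dataset splits.

The classification substrate is one row per CHED residue, keyed
``chain_id:seq_index``, with labels +1 (coordinates a functional zinc) and
-1 otherwise. Zinc-binding benchmarks are heavily imbalanced, so negatives
are subsampled to a fixed ratio (6:1 by default) before selection and
training; an independent test split takes one of six random parts of the
positives, with the rest feeding 5-fold cross-validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import Residue

log = logging.getLogger(__name__)

NEGATIVE_RATIO = 6
N_SPLIT_PARTS = 6
N_CV_FOLDS = 5
DEFAULT_SEED = 20120
_ONE_TO_TYPE = {"C": "C", "H": "H", "E": "E", "D": "D"}


@dataclass
class FeatureMatrix:
    """Samples x named feature columns with labels and per-sample metadata."""
    X: pd.DataFrame                      # index = sample keys
    y: pd.Series                         # +1 / -1
    residue_type: pd.Series              # C/H/E/D
    chain_id: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)  # column -> native|passthrough

    def __post_init__(self) -> None:
        if self.X.index.has_duplicates:
            raise ValueError("duplicate sample keys in feature matrix")
        if self.X.columns.has_duplicates:
            raise ValueError("duplicate feature column names")
        bad = set(self.y.unique()) - {1, -1}
        if bad:
            raise ValueError(f"labels must be +1/-1, found {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, keys) -> "FeatureMatrix":
        keys = list(keys)
        return FeatureMatrix(self.X.loc[keys], self.y.loc[keys],
                             self.residue_type.loc[keys], self.chain_id.loc[keys],
                             dict(self.provenance))

    def select_columns(self, columns) -> "FeatureMatrix":
        columns = list(columns)
        return FeatureMatrix(self.X[columns], self.y, self.residue_type,
                             self.chain_id,
                             {c: self.provenance.get(c, "native") for c in columns})

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path, metadata: dict | None = None) -> None:
        """Tab-delimited matrix plus a JSON sidecar with provenance/params."""
        path = Path(path)
        df = self.X.copy()
        df.insert(0, "label", self.y)
        df.insert(1, "residue_type", self.residue_type)
        df.insert(2, "chain_id", self.chain_id)
        df.to_csv(path, sep="\t", index_label="sample_key", float_format="%.6g")
        meta = {"provenance": self.provenance, "n_samples": self.n_samples,
                "n_features": len(self.feature_names)}
        if metadata:
            meta.update(metadata)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def read_tsv(cls, path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="sample_key")
        for col in ("label", "residue_type", "chain_id"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        provenance = {}
        if meta_path.exists():
            provenance = json.loads(meta_path.read_text()).get("provenance", {})
        return cls(df.drop(columns=["label", "residue_type", "chain_id"]),
                   df["label"].astype(int), df["residue_type"].astype(str),
                   df["chain_id"].astype(str), provenance)


def assemble_matrix(
    samples: list[tuple[Residue, int]],
    feature_frames: list[pd.DataFrame],
    passthrough: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Join provider feature frames (indexed by sample key) over CHED samples.

    Column order is provider registration order, then the provider's own
    column order. ``passthrough`` columns (externally computed features) are
    joined on sample key and tagged in provenance.
    """
    keys = [res.key for res, _ in samples]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate sample keys in sample set")
    idx = pd.Index(keys, name="sample_key")
    provenance: dict[str, str] = {}
    parts: list[pd.DataFrame] = []
    for frame in feature_frames:
        missing = idx.difference(frame.index)
        if len(missing):
            chains = sorted({k.split(":")[0] for k in missing})
            raise ValueError(
                f"feature provider missing {len(missing)} samples "
                f"(chains {chains}); first missing keys: {list(missing[:5])}")
        sub = frame.loc[idx]
        for col in sub.columns:
            if col in provenance:
                raise ValueError(f"duplicate feature column {col!r} across providers")
            provenance[col] = "native"
        parts.append(sub)
    if passthrough is not None:
        missing = idx.difference(passthrough.index)
        if len(missing):
            raise ValueError(
                f"passthrough table missing keys, e.g. {list(missing[:5])}")
        sub = passthrough.loc[idx]
        for col in sub.columns:
            if col in provenance:
                raise ValueError(f"passthrough column {col!r} collides with a native column")
            provenance[col] = "passthrough"
        parts.append(sub)
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=idx)
    y = pd.Series([lab for _, lab in samples], index=idx, name="label")
    rtype = pd.Series([res.one_letter for res, _ in samples], index=idx, name="residue_type")
    chain = pd.Series([res.chain_id for res, _ in samples], index=idx, name="chain_id")
    return FeatureMatrix(X, y, rtype, chain, provenance)


def impute_median(matrix: FeatureMatrix, training_keys=None) -> FeatureMatrix:
    """Fill missing values with column medians computed on training rows only."""
    ref = matrix.X.loc[list(training_keys)] if training_keys is not None else matrix.X
    medians = ref.median()
    X = matrix.X.fillna(medians).fillna(0.0)
    return FeatureMatrix(X, matrix.y, matrix.residue_type, matrix.chain_id,
                         dict(matrix.provenance))


def subsample_negatives(
    matrix: FeatureMatrix, ratio: float = NEGATIVE_RATIO, seed: int = DEFAULT_SEED,
) -> FeatureMatrix:
    """Keep all positives; draw negatives uniformly to ratio x positives."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    rng = np.random.default_rng(seed)
    pos_keys = matrix.y.index[matrix.y == 1]
    neg_keys = matrix.y.index[matrix.y == -1]
    n_wanted = int(round(ratio * len(pos_keys)))
    if len(neg_keys) <= n_wanted:
        if len(neg_keys) < n_wanted:
            log.warning("only %d negatives available for target %d; keeping all",
                        len(neg_keys), n_wanted)
        chosen = list(neg_keys)
    else:
        chosen = list(rng.choice(neg_keys, size=n_wanted, replace=False))
    keys = list(pos_keys) + sorted(chosen)
    return matrix.subset(keys)


@dataclass
class SplitPlan:
    independent_test: list[str]
    training: list[str]
    cv_folds: list[list[str]]
    seed: int

    def __post_init__(self) -> None:
        test, train = set(self.independent_test), set(self.training)
        if test & train:
            raise ValueError("independent test and training keys overlap")
        covered: set[str] = set()
        for fold in self.cv_folds:
            fold_set = set(fold)
            if fold_set & covered:
                raise ValueError("cross-validation folds overlap")
            covered |= fold_set
        if covered != train:
            raise ValueError("cross-validation folds do not partition the training set")


def make_split(
    matrix: FeatureMatrix,
    n_parts: int = N_SPLIT_PARTS,
    ratio: float = NEGATIVE_RATIO,
    n_folds: int = N_CV_FOLDS,
    seed: int = DEFAULT_SEED,
) -> SplitPlan:
    """Independent-test / training split with CV folds.

    Positives are shuffled and cut into ``n_parts`` near-equal parts; the
    first part becomes the independent test positives and the rest the
    training positives. Negatives are drawn at ``ratio``:1 independently for
    the two pools, and ``n_folds`` folds partition the training rows at
    random.
    """
    rng = np.random.default_rng(seed)
    pos = list(matrix.y.index[matrix.y == 1])
    neg = list(matrix.y.index[matrix.y == -1])
    if len(pos) < n_parts:
        raise ValueError(f"need at least {n_parts} positives, have {len(pos)}")
    rng.shuffle(pos)
    part_sizes = [len(pos) // n_parts + (1 if i < len(pos) % n_parts else 0)
                  for i in range(n_parts)]
    test_pos = pos[:part_sizes[0]]
    train_pos = pos[part_sizes[0]:]

    rng.shuffle(neg)
    n_test_neg = min(int(round(ratio * len(test_pos))), len(neg))
    test_neg = neg[:n_test_neg]
    remaining = neg[n_test_neg:]
    n_train_neg = min(int(round(ratio * len(train_pos))), len(remaining))
    train_neg = remaining[:n_train_neg]

    training = train_pos + train_neg
    rng.shuffle(training)
    folds = [sorted(training[i::n_folds]) for i in range(n_folds)]
    return SplitPlan(independent_test=sorted(test_pos + test_neg),
                     training=sorted(training), cv_folds=folds, seed=seed)
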
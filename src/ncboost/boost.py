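"""The leakage-free gradient-tree-boosting bundle.

Training fits k independent XGBoost models, each excluding one genome
partition from its training rows; a variant is then scored by the single
model that never saw any variant of its gene's partition, so every score is
free of gene-level contamination.  Each model stores the medians of its own
training rows for imputation at scoring time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import spearmanr
from sklearn.model_selection import train_test_split

from .cohort import GenomePartition
from .features import feature_category, training_medians, impute

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoostingParams:
    """Gradient-tree-boosting hyperparameters.

    The learning rate, tree depth and minimum split-loss reduction follow
    the published configuration (eta=0.01, max_depth=25, gamma=10); the
    round budget is controlled by early stopping on an internal stratified
    validation split.
    """

    eta: float = 0.01
    max_depth: int = 25
    gamma: float = 10.0
    n_rounds: int = 1000
    early_stopping_rounds: Optional[int] = 50
    objective: str = "binary:logistic"

    def validate(self) -> None:
        if not (0 < self.eta <= 1):
            raise ValueError("eta must be in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    def to_xgb(self, seed: int) -> dict:
        return {
            "eta": self.eta,
            "max_depth": self.max_depth,
            "gamma": self.gamma,
            "objective": self.objective,
            "eval_metric": "logloss",
            "tree_method": "exact",
            "nthread": 1,
            "seed": int(seed),
        }


@dataclass
class NCBoostBundle:
    """k fitted boosters plus the partition map, feature schema, per-model
    training medians and training manifests (gene sets) for leakage audits."""

    boosters: List[xgb.Booster]
    partition: GenomePartition
    feature_names: List[str]
    medians: List[pd.Series]  # per model
    best_iterations: List[int]
    manifests: List[Set[str]]  # per model: genes present in its training rows
    params: BoostingParams
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.boosters)


def train_bundle(
    X: pd.DataFrame,
    y: Sequence[int],
    genes: Sequence[str],
    partition: GenomePartition,
    params: BoostingParams = BoostingParams(),
    seed: int = 0,
    config: str = "",
) -> NCBoostBundle:
    """Fit the k-model bundle; model i trains on every cohort row whose gene
    is outside partition i."""
    params.validate()
    y = np.asarray(y, dtype=int)
    genes = list(genes)
    if len(X) != len(y) or len(X) != len(genes):
        raise ValueError("X, y and genes must be aligned")
    part_of = np.array([partition.of(g) if partition.of(g) is not None else -1 for g in genes])
    if (part_of == -1).any():
        missing = sorted({g for g, p in zip(genes, part_of) if p == -1})
        raise ValueError(f"cohort genes absent from partition: {missing[:5]}")

    boosters, medians, best_iters, manifests = [], [], [], []
    for i in range(1, partition.k + 1):
        mask = part_of != i
        yi = y[mask]
        if yi.sum() == 0:
            raise ValueError(f"model {i}: no positives outside partition {i}")
        if yi.sum() == len(yi):
            raise ValueError(f"model {i}: no negatives outside partition {i}")
        med = training_medians(X.loc[mask])
        Xi = impute(X.loc[mask], med)
        rs = (seed * 1009 + i) % (2**31)
        idx = np.arange(len(Xi))
        evals = []
        if params.early_stopping_rounds is not None and len(Xi) >= 20 and yi.sum() >= 2:
            tr, va = train_test_split(
                idx, test_size=0.1, stratify=yi, random_state=rs % (2**31 - 1)
            )
            dtrain = xgb.DMatrix(
                Xi.iloc[tr], label=yi[tr], feature_names=list(X.columns)
            )
            dval = xgb.DMatrix(Xi.iloc[va], label=yi[va], feature_names=list(X.columns))
            evals = [(dval, "val")]
        else:
            dtrain = xgb.DMatrix(Xi, label=yi, feature_names=list(X.columns))
        booster = xgb.train(
            params.to_xgb(rs),
            dtrain,
            num_boost_round=params.n_rounds,
            evals=evals,
            early_stopping_rounds=params.early_stopping_rounds if evals else None,
            verbose_eval=False,
        )
        best = getattr(booster, "best_iteration", None)
        if best is None:
            best = booster.num_boosted_rounds() - 1
        boosters.append(booster)
        medians.append(med)
        best_iters.append(int(best))
        manifests.append(set(np.array(genes)[mask].tolist()))

    return NCBoostBundle(
        boosters=boosters,
        partition=partition,
        feature_names=list(X.columns),
        medians=medians,
        best_iterations=best_iters,
        manifests=manifests,
        params=params,
        provenance={
            "seed": int(seed),
            "config": config,
            "eta": params.eta,
            "max_depth": params.max_depth,
            "gamma": params.gamma,
            "n_rounds": params.n_rounds,
            "early_stopping_rounds": params.early_stopping_rounds,
        },
    )


def _predict(bundle: NCBoostBundle, model_idx: int, X: pd.DataFrame) -> np.ndarray:
    """Predict with one bundle member after imputing with its own medians."""
    Xi = impute(X[bundle.feature_names], bundle.medians[model_idx])
    dm = xgb.DMatrix(Xi, feature_names=bundle.feature_names)
    return bundle.boosters[model_idx].predict(
        dm, iteration_range=(0, bundle.best_iterations[model_idx] + 1)
    )


def score_variants(
    bundle: NCBoostBundle,
    X: pd.DataFrame,
    genes: Sequence[str],
) -> pd.DataFrame:
    """Score a batch with the single-score contract.

    Each variant is scored by the model excluding its gene's partition;
    variants of genes absent from the partition map fall back to the mean of
    all k models and are flagged (``model_index`` -1).  Input order is
    preserved.
    """
    genes = list(genes)
    if len(genes) != len(X):
        raise ValueError("X and genes must be aligned")
    scores = np.full(len(X), np.nan)
    model_index = np.zeros(len(X), dtype=int)
    fallback = np.zeros(len(X), dtype=bool)
    parts = np.array(
        [bundle.partition.of(g) if bundle.partition.of(g) is not None else -1 for g in genes]
    )
    for p in np.unique(parts):
        rows = np.flatnonzero(parts == p)
        sub = X.iloc[rows]
        if p == -1:
            logger.warning("%d variants with genes outside the partition map; "
                           "scored with the bundle mean", len(rows))
            preds = np.mean([_predict(bundle, m, sub) for m in range(bundle.k)], axis=0)
            fallback[rows] = True
            model_index[rows] = -1
        else:
            preds = _predict(bundle, int(p) - 1, sub)
            model_index[rows] = int(p)
        scores[rows] = preds
    return pd.DataFrame(
        {
            "variant_id": list(X.index),
            "gene_id": genes,
            "score": scores,
            "model_index": model_index,
            "fallback": fallback,
        }
    )


def audit_leakage(bundle: NCBoostBundle, scored: pd.DataFrame) -> int:
    """Count scored rows whose gene appears in the training manifest of the
    model that scored them (must be 0 for a sound bundle)."""
    violations = 0
    for _, row in scored.iterrows():
        mi = int(row["model_index"])
        if mi < 1:
            continue
        if row["gene_id"] in bundle.manifests[mi - 1]:
            violations += 1
    return violations


def feature_importance(
    bundle: NCBoostBundle,
) -> Tuple[pd.Series, pd.Series]:
    """Gain-based importance shares, averaged across the k models, together
    with cumulative per-category shares."""
    per_model = []
    for booster in bundle.boosters:
        gains = booster.get_score(importance_type="total_gain")
        s = pd.Series(
            {f: gains.get(f, 0.0) for f in bundle.feature_names},
            index=bundle.feature_names,
            dtype=float,
        )
        tot = s.sum()
        if tot > 0:
            s = s / tot
        else:  # a model that grew no splits contributes a flat profile
            s = pd.Series(1.0 / len(s), index=s.index)
        per_model.append(s)
    shares = pd.concat(per_model, axis=1).mean(axis=1)
    shares = shares / shares.sum()
    cats = pd.Series({f: feature_category(f) for f in shares.index})
    per_category = shares.groupby(cats).sum()
    return shares, per_category


def cross_model_correlation(
    bundle: NCBoostBundle,
    X_holdout: pd.DataFrame,
    genes_holdout: Sequence[str],
) -> Tuple[np.ndarray, float, float]:
    """Diagnostic consistency check: every bundle member scores the same
    held-out rows (genes disjoint from all training manifests) and the
    pairwise Spearman correlation of the k score vectors is reported.

    This is the one context where a variant receives k scores.
    """
    holdout_genes = set(genes_holdout)
    for i, manifest in enumerate(bundle.manifests, start=1):
        overlap = holdout_genes & manifest
        if overlap:
            raise ValueError(
                f"holdout genes overlap model {i} training genes: {sorted(overlap)[:5]}"
            )
    S = np.vstack([_predict(bundle, m, X_holdout) for m in range(bundle.k)])
    rho = spearmanr(S.T).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if rho.shape != (bundle.k, bundle.k):  # k == 2 returns a scalar
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    off = rho[np.triu_indices(bundle.k, k=1)]
    return rho, float(np.mean(off)), float(np.std(off))


def _json_default(o):
    if isinstance(o, np.generic):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_bundle(bundle: NCBoostBundle, path: str | Path) -> None:
    """Persist the bundle as a directory of model files plus JSON metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, booster in enumerate(bundle.boosters, start=1):
        booster.save_model(str(path / f"model_{i}.json"))
    meta = {
        "feature_names": bundle.feature_names,
        "medians": [m.to_dict() for m in bundle.medians],
        "best_iterations": bundle.best_iterations,
        "params": asdict(bundle.params),
        "provenance": bundle.provenance,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, default=_json_default))
    (path / "partition.json").write_text(
        json.dumps(bundle.partition.to_dict(), indent=1, default=_json_default)
    )
    (path / "manifest.json").write_text(
        json.dumps([sorted(m) for m in bundle.manifests], indent=1)
    )


def load_bundle(path: str | Path) -> NCBoostBundle:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    partition = GenomePartition.from_dict(json.loads((path / "partition.json").read_text()))
    manifests = [set(m) for m in json.loads((path / "manifest.json").read_text())]
    boosters = []
    for i in range(1, partition.k + 1):
        b = xgb.Booster()
        b.load_model(str(path / f"model_{i}.json"))
        boosters.append(b)
    fn = meta["feature_names"]
    return NCBoostBundle(
        boosters=boosters,
        partition=partition,
        feature_names=fn,
        medians=[pd.Series(m).reindex(fn) for m in meta["medians"]],
        best_iterations=[int(b) for b in meta["best_iterations"]],
        manifests=manifests,
        params=BoostingParams(**meta["params"]),
        provenance=meta["provenance"],
    )
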
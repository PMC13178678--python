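"""Membership-inference audit of model output vectors.

The attacker never sees waveforms — only the model's per-label output
probabilities.  Each of ten rounds draws a balanced member/non-member sample
(majority class downsampled), splits it 80/20, fits a 50-tree random forest
on the 80% and scores accuracy and AUROC on the held-out 20%.  Mean attack
accuracy near 0.5 indicates exchangeability (privacy preserved); accuracies
approaching 1 indicate the outputs betray training membership.  Per-feature
forest importances, averaged over rounds, identify which output dimensions
are most revealing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .exceptions import InsufficientDataError, ParameterError


@dataclass
class MIAConfig:
    """Attack protocol parameters (defaults follow the audit design)."""

    n_folds: int = 10
    n_trees: int = 50
    train_fraction: float = 0.8
    seed: int = 0
    balance: str = "downsample"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ParameterError("n_folds must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ParameterError("train_fraction must lie in (0, 1)")
        if self.balance != "downsample":
            raise ParameterError("only 'downsample' balancing is supported")


@dataclass
class MIAResult:
    fold_accuracies: np.ndarray
    fold_aurocs: np.ndarray
    mean_accuracy: float
    sd_accuracy: float
    mean_auroc: float
    importances: np.ndarray  # (L,) mean over folds, sums to 1
    n_members: int
    n_nonmembers: int
    config: MIAConfig = field(repr=False, default=None)


def run_mia(
    member_outputs: np.ndarray,
    nonmember_outputs: np.ndarray,
    config: MIAConfig | None = None,
) -> MIAResult:
    """Tenfold balanced membership-inference attack on output vectors.

    Each fold independently draws a balanced sample (equal classes, the
    majority downsampled without replacement), splits it
    ``train_fraction``/rest stratified, fits the forest, and scores the
    held-out part.  Deterministic under ``config.seed``.
    """
    config = config or MIAConfig()
    members = np.asarray(member_outputs, dtype=float)
    nonmembers = np.asarray(nonmember_outputs, dtype=float)
    if members.ndim != 2 or nonmembers.ndim != 2 or members.shape[1] != nonmembers.shape[1]:
        raise ParameterError("member/non-member matrices must be 2-D with equal L")
    n1, n2 = members.shape[0], nonmembers.shape[0]
    if min(n1, n2) < 10 * config.n_folds:
        raise InsufficientDataError(
            f"need >= {10 * config.n_folds} records per class, got {min(n1, n2)}"
        )
    n_bal = min(n1, n2)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 211]))
    accs, aucs, imps = [], [], []
    for fold in range(config.n_folds):
        idx1 = rng.choice(n1, size=n_bal, replace=False)
        idx2 = rng.choice(n2, size=n_bal, replace=False)
        X = np.vstack([members[idx1], nonmembers[idx2]])
        y = np.concatenate([np.ones(n_bal), np.zeros(n_bal)])
        split_seed = int(rng.integers(2**31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=config.train_fraction, stratify=y,
            random_state=split_seed,
        )
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features="sqrt",
            random_state=split_seed,
            n_jobs=1,
        )
        forest.fit(X_tr, y_tr)
        accs.append(forest.score(X_te, y_te))
        aucs.append(roc_auc_score(y_te, forest.predict_proba(X_te)[:, 1]))
        imps.append(forest.feature_importances_)
    accs = np.asarray(accs)
    aucs = np.asarray(aucs)
    return MIAResult(
        fold_accuracies=accs,
        fold_aurocs=aucs,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)),
        mean_auroc=float(aucs.mean()),
        importances=np.mean(imps, axis=0),
        n_members=n_bal,
        n_nonmembers=n_bal,
        config=config,
    )


def separation_summary(
    member_outputs: np.ndarray,
    nonmember_outputs: np.ndarray,
    seed: int = 0,
    embed: bool = False,
) -> tuple[float, np.ndarray | None]:
    """Between/within mean-pairwise-distance ratio, with optional 2-D embedding.

    Index ~= 1 for identical distributions and grows with class separation in
    the L-dimensional output space.  The embedding (PCA) is a plotting
    convenience only; it is deterministic under ``seed``.
    """
    members = np.asarray(member_outputs, dtype=float)
    nonmembers = np.asarray(nonmember_outputs, dtype=float)
    if members.shape[0] < 2 or nonmembers.shape[0] < 2:
        raise InsufficientDataError("need >= 2 records per class")
    between = cdist(members, nonmembers).mean()
    within = np.concatenate([pdist(members), pdist(nonmembers)]).mean()
    index = float(between / within) if within > 0 else float("inf")
    coords = None
    if embed:
        stacked = np.vstack([members, nonmembers])
        coords = PCA(n_components=2, random_state=seed).fit_transform(stacked)
    return index, coords
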
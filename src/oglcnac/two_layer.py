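"""Two-layered predictor assembly.

Layer 1: one profile HMM per MDD motif subgroup; a candidate window is
described by its vector of bit scores against all subgroup models (in
fixed leaf order). Layer 2: an RBF-kernel SVM over that vector, with a
logistic (Platt-style) map from decision values to probabilities; a site
is called positive when the probability exceeds 0.5.

Training negatives are balanced to the positive count by k-means
undersampling: the negatives are clustered into as many clusters as
there are positives and the member nearest each centroid is kept.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import mdd, phmm
from .alphabet import HMM_ALPHABET, HMM_INDEX
from .seq_windows import CENTER_RESIDUES, PeptideWindow, extract_windows

FORMAT_VERSION = "1"

DEFAULT_C_GRID = tuple(2.0 ** e for e in (-5, -1, 3, 7, 11, 15))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in (-15, -11, -7, -3, 1, 3))


def encode_windows(fragments: Sequence, encoding: str = "onehot") -> np.ndarray:
    """Numeric encoding of fragments for k-means.

    "onehot": per-position indicator over the 21 HMM symbols ('X' rows
    stay zero). "group-onehot": per-position indicator over the five
    physicochemical groups (null symbols stay zero).
    """
    frags = [f if isinstance(f, str) else f.fragment for f in fragments]
    length = len(frags[0])
    if encoding == "onehot":
        out = np.zeros((len(frags), length * len(HMM_ALPHABET)))
        for r, f in enumerate(frags):
            for p, c in enumerate(f):
                k = HMM_INDEX.get(c)
                if k is not None:
                    out[r, p * len(HMM_ALPHABET) + k] = 1.0
        return out
    if encoding == "group-onehot":
        gidx = {g: i for i, g in enumerate(mdd.GROUPS)}
        out = np.zeros((len(frags), length * len(mdd.GROUPS)))
        for r, f in enumerate(frags):
            for p, g in enumerate(mdd.group_encode(f)):
                if g is not None:
                    out[r, p * len(mdd.GROUPS) + gidx[g]] = 1.0
        return out
    raise ValueError(f"unknown encoding {encoding!r}")


def kmeans_balance(
    negatives: Sequence[PeptideWindow],
    n_target: int,
    encoding: str = "onehot",
    seed: int = 0,
) -> list[PeptideWindow]:
    """Select ``n_target`` representative negatives, one per k-means cluster.

    Each cluster contributes the member nearest its centroid; clusters
    that end up empty are backfilled with the unchosen fragments nearest
    their own centroids. The result is a duplicate-free subset of the
    input of size exactly ``n_target``.
    """
    if n_target > len(negatives):
        raise ValueError(
            f"cannot select {n_target} negatives from {len(negatives)}"
        )
    if n_target == len(negatives):
        return list(negatives)
    X = encode_windows(negatives, encoding)
    km = KMeans(n_clusters=n_target, random_state=seed, n_init=1, max_iter=50)
    labels = km.fit_predict(X)
    centroids = km.cluster_centers_

    chosen: list[int] = []
    chosen_set: set[int] = set()
    for c in range(n_target):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue
        d = np.linalg.norm(X[members] - centroids[c], axis=1)
        chosen.append(int(members[np.argmin(d)]))
    chosen_set = set(chosen)
    if len(chosen) < n_target:  # backfill from empty clusters
        rest = np.array([i for i in range(len(negatives)) if i not in chosen_set])
        d_own = np.linalg.norm(X[rest] - centroids[labels[rest]], axis=1)
        for i in rest[np.argsort(d_own, kind="stable")]:
            chosen.append(int(i))
            if len(chosen) == n_target:
                break
    return [negatives[i] for i in chosen]


@dataclass
class SecondLayer:
    """RBF-SVM decision rule with a logistic probability map.

    The support expansion is stored explicitly so that the model
    round-trips through plain text and predicts without sklearn state:
    f(x) = sum_i a_i K(x, sv_i) + b, p(x) = sigmoid(platt_a * f + platt_b).
    """

    gamma: float
    C: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    decision_threshold: float = 0.5
    grid_results: list = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision threshold must lie in (0, 1)")
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_coef = np.asarray(self.dual_coef, dtype=float).ravel()

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sq = (
            (X ** 2).sum(axis=1)[:, None]
            + (self.support_vectors ** 2).sum(axis=1)[None, :]
            - 2.0 * X @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return K @ self.dual_coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        f = self.decision_function(X)
        return 1.0 / (1.0 + np.exp(-(self.platt_a * f + self.platt_b)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X) > self.decision_threshold


def train_second_layer(
    pos_features: np.ndarray,
    neg_features: np.ndarray,
    grid: Sequence[tuple[float, float]] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> SecondLayer:
    """Grid-search (C, gamma) by cross-validated accuracy and fit the SVM.

    Ties prefer the smaller C, then the smaller gamma. The probability
    map is a logistic regression fit on out-of-fold decision values, so
    it is not tuned on resubstitution scores.
    """
    pos_features = np.atleast_2d(pos_features)
    neg_features = np.atleast_2d(neg_features)
    if len(pos_features) == 0 or len(neg_features) == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([pos_features, neg_features])
    y = np.concatenate([np.ones(len(pos_features)), np.zeros(len(neg_features))])
    if grid is None:
        grid = [(c, g) for c in DEFAULT_C_GRID for g in DEFAULT_GAMMA_GRID]
    grid = sorted(grid)  # ascending C then gamma -> tie rule by strict improvement

    n_splits = min(cv_folds, int(min(y.sum(), len(y) - y.sum())))
    skf = StratifiedKFold(n_splits=max(n_splits, 2), shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    grid_results = []
    best: Optional[tuple[float, float]] = None
    best_acc = -1.0
    for C, gamma in grid:
        accs = []
        for tr, te in folds:
            clf = SVC(C=C, gamma=gamma, kernel="rbf")
            clf.fit(X[tr], y[tr])
            accs.append(float((clf.predict(X[te]) == y[te]).mean()))
        mean_acc = float(np.mean(accs))
        grid_results.append({"C": C, "gamma": gamma, "cv_accuracy": mean_acc})
        if mean_acc > best_acc:
            best, best_acc = (C, gamma), mean_acc
    C, gamma = best

    # out-of-fold decision values for the Platt map
    oof = np.empty(len(y))
    for tr, te in folds:
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(X[tr], y[tr])
        oof[te] = clf.decision_function(X[te])
    lr = LogisticRegression(C=1e6)
    lr.fit(oof[:, None], y)

    final = SVC(C=C, gamma=gamma, kernel="rbf")
    final.fit(X, y)
    # sklearn orders classes [0, 1]; dual_coef is for the positive class
    return SecondLayer(
        gamma=gamma,
        C=C,
        support_vectors=final.support_vectors_,
        dual_coef=final.dual_coef_.ravel(),
        intercept=float(final.intercept_[0]),
        platt_a=float(lr.coef_[0, 0]),
        platt_b=float(lr.intercept_[0]),
        grid_results=grid_results,
    )


@dataclass
class TrainConfig:
    """All tunables of the training pipeline, serialized with the model."""

    w: int = 5
    scheme: dict = field(default_factory=lambda: dict(mdd.DEFAULT_GROUP_SCHEME))
    chi2_cutoff: float = mdd.CHI2_CUTOFF
    min_size: int = mdd.DEFAULT_MIN_SIZE
    pseudocount: float = 1.0
    null: str = "uniform"
    leak: float = 0.0
    threshold_objective: str = "accuracy"
    encoding: str = "onehot"
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    cv_folds: int = 5
    seed: int = 0
    decision_threshold: float = 0.5
    refit_mdd_per_fold: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["c_grid"] = list(self.c_grid)
        d["gamma_grid"] = list(self.gamma_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["c_grid"] = tuple(d.get("c_grid", DEFAULT_C_GRID))
        d["gamma_grid"] = tuple(d.get("gamma_grid", DEFAULT_GAMMA_GRID))
        return cls(**d)


@dataclass(frozen=True)
class SitePrediction:
    protein_id: str
    position: int
    residue: str
    fragment: str
    probability: float
    label: str  # "positive" / "negative"
    matched_motif: str
    sub_threshold: bool
    bit_scores: tuple


@dataclass
class TwoLayerModel:
    """Ordered motif HMMs with calibrated thresholds plus the SVM layer."""

    config: TrainConfig
    leaves: list  # of (leaf_id, ProfileHMM, threshold)
    second_layer: SecondLayer
    tree: Optional[mdd.MDDNode] = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_motifs(self) -> int:
        return len(self.leaves)

    @property
    def leaf_ids(self) -> list[str]:
        return [lid for lid, _, _ in self.leaves]

    def featureize(self, fragments: Sequence) -> np.ndarray:
        """Bit-score matrix (n, k) in fixed leaf order."""
        frags = [f if isinstance(f, str) else f.fragment for f in fragments]
        expected = 2 * self.config.w + 1
        for f in frags:
            if len(f) != expected:
                raise ValueError(f"fragment length {len(f)} != {expected}")
        if not frags:
            return np.zeros((0, self.n_motifs))
        return np.column_stack(
            [model.score_many(frags) for _, model, _ in self.leaves]
        )

    def predict_proba(self, fragments: Sequence) -> np.ndarray:
        return self.second_layer.predict_proba(self.featureize(fragments))

    def predict_windows(self, fragments: Sequence) -> np.ndarray:
        """Boolean positive calls for a batch of windows."""
        return self.predict_proba(fragments) > self.config.decision_threshold

    def matched_motif(self, scores: np.ndarray) -> tuple[str, bool]:
        """Best motif for one score vector.

        Prefers the highest-scoring HMM among those exceeding their
        calibrated thresholds; otherwise the overall argmax, flagged
        sub-threshold.
        """
        above = [
            (s, lid)
            for s, (lid, _, th) in zip(scores, self.leaves)
            if s > th
        ]
        if above:
            return max(above)[1], False
        k = int(np.argmax(scores))
        return self.leaves[k][0], True


def train_two_layer(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    config: TrainConfig | None = None,
) -> TwoLayerModel:
    """Full training pipeline: MDD → per-leaf HMMs + thresholds →
    k-means-balanced negatives → bit-score features → RBF-SVM."""
    config = config or TrainConfig()
    if len(negatives) < len(positives):
        raise ValueError("need at least as many negatives as positives")

    tree = mdd.mdd_cluster(
        positives,
        scheme=config.scheme,
        w=config.w,
        chi2_cutoff=config.chi2_cutoff,
        min_size=config.min_size,
    )
    balanced = kmeans_balance(
        list(negatives), len(positives), encoding=config.encoding, seed=config.seed
    )
    leaves = []
    for leaf in tree.leaves():
        model = phmm.build_phmm(
            leaf.members,
            pseudocount=config.pseudocount,
            null=config.null,
            leak=config.leak,
        )
        th = phmm.calibrate_threshold(
            model, leaf.members, balanced, objective=config.threshold_objective
        )
        leaves.append((leaf.leaf_id, model, th))

    partial = TwoLayerModel(
        config=config,
        leaves=leaves,
        second_layer=None,  # type: ignore[arg-type]
        tree=tree,
    )
    pos_feat = partial.featureize(positives)
    neg_feat = partial.featureize(balanced)
    grid = [(c, g) for c in config.c_grid for g in config.gamma_grid]
    second = train_second_layer(
        pos_feat, neg_feat, grid=grid, cv_folds=config.cv_folds, seed=config.seed
    )
    second.decision_threshold = config.decision_threshold
    partial.second_layer = second
    partial.metadata = {
        "format_version": FORMAT_VERSION,
        "n_positives": len(positives),
        "n_negatives_pool": len(negatives),
        "n_negatives_balanced": len(balanced),
        "leaf_sizes": {lf.leaf_id: lf.size for lf in tree.leaves()},
        "chi2_cutoff": config.chi2_cutoff,
        "min_size": config.min_size,
        "seed": config.seed,
        "svm_C": second.C,
        "svm_gamma": second.gamma,
    }
    return partial


def predict(model: TwoLayerModel, record) -> list[SitePrediction]:
    """Score every S/T site of a protein and call positives above 0.5."""
    windows = extract_windows(record, w=model.config.w, center_residues=CENTER_RESIDUES)
    if not windows:
        return []
    feats = model.featureize(windows)
    probs = model.second_layer.predict_proba(feats)
    out = []
    for wd, scores, p in zip(windows, feats, probs):
        motif, sub = model.matched_motif(scores)
        out.append(
            SitePrediction(
                protein_id=wd.protein_id,
                position=wd.position,
                residue=wd.center_residue,
                fragment=wd.fragment,
                probability=float(p),
                label="positive"
                if p > model.config.decision_threshold
                else "negative",
                matched_motif=motif,
                sub_threshold=sub,
                bit_scores=tuple(float(s) for s in scores),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Baseline layer-1-only classifiers (for ablation and evaluation)

@dataclass
class HMMClassifier:
    """Threshold rule over one or more profile HMMs.

    With one model this is the single-HMM baseline; with several, a
    window is positive when any model exceeds its calibrated threshold.
    """

    models: list  # of (leaf_id, ProfileHMM, threshold)

    def predict_windows(self, fragments: Sequence) -> np.ndarray:
        frags = [f if isinstance(f, str) else f.fragment for f in fragments]
        calls = np.zeros(len(frags), dtype=bool)
        for _, model, th in self.models:
            calls |= model.score_many(frags) > th
        return calls


def train_single_hmm(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    config: TrainConfig | None = None,
) -> HMMClassifier:
    """One profile HMM over all positives with a calibrated threshold."""
    config = config or TrainConfig()
    balanced = (
        kmeans_balance(list(negatives), len(positives),
                       encoding=config.encoding, seed=config.seed)
        if len(negatives) > len(positives)
        else list(negatives)
    )
    model = phmm.build_phmm(
        positives, pseudocount=config.pseudocount, null=config.null,
        leak=config.leak,
    )
    th = phmm.calibrate_threshold(
        model, positives, balanced, objective=config.threshold_objective
    )
    return HMMClassifier(models=[("ALL", model, th)])


def train_mdd_hmms(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    config: TrainConfig | None = None,
) -> HMMClassifier:
    """MDD-clustered HMMs combined by an any-model-over-threshold rule."""
    config = config or TrainConfig()
    tree = mdd.mdd_cluster(
        positives, scheme=config.scheme, w=config.w,
        chi2_cutoff=config.chi2_cutoff, min_size=config.min_size,
    )
    balanced = (
        kmeans_balance(list(negatives), len(positives),
                       encoding=config.encoding, seed=config.seed)
        if len(negatives) > len(positives)
        else list(negatives)
    )
    models = []
    for leaf in tree.leaves():
        m = phmm.build_phmm(
            leaf.members, pseudocount=config.pseudocount, null=config.null,
            leak=config.leak,
        )
        th = phmm.calibrate_threshold(
            m, leaf.members, balanced, objective=config.threshold_objective
        )
        models.append((leaf.leaf_id, m, th))
    return HMMClassifier(models=models)


# ---------------------------------------------------------------------------
# Model bundle IO (plain-text directory)

def save_model(model: TwoLayerModel, path) -> None:
    """Write the model bundle (manifest, tree, per-leaf HMMs, SVM) as text.

    The bundle is written to a temporary directory and renamed into
    place, so a failed save never leaves a partial bundle.
    """
    path = str(path)
    parent = os.path.dirname(os.path.abspath(path)) or "."
    tmp = tempfile.mkdtemp(dir=parent, prefix=".bundle-")
    try:
        manifest = {
            "format_version": FORMAT_VERSION,
            "config": model.config.to_dict(),
            "leaf_ids": model.leaf_ids,
            "metadata": model.metadata,
        }
        with open(os.path.join(tmp, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)
            fh.write("\n")
        if model.tree is not None:
            mdd.write_tree(model.tree, os.path.join(tmp, "tree.json"))
        for lid, m, th in model.leaves:
            phmm.save_phmm(m, os.path.join(tmp, f"hmm_{lid}.json"), threshold=th)
        sl = model.second_layer
        svm = {
            "gamma": sl.gamma,
            "C": sl.C,
            "support_vectors": sl.support_vectors.tolist(),
            "dual_coef": sl.dual_coef.tolist(),
            "intercept": sl.intercept,
            "platt_a": sl.platt_a,
            "platt_b": sl.platt_b,
            "decision_threshold": sl.decision_threshold,
            "grid_results": sl.grid_results,
        }
        with open(os.path.join(tmp, "svm.json"), "w") as fh:
            json.dump(svm, fh, sort_keys=True)
            fh.write("\n")
        if os.path.exists(path):
            raise FileExistsError(f"refusing to overwrite {path}")
        os.rename(tmp, path)
    except Exception:
        import shutil

        shutil.rmtree(tmp, ignore_errors=True)
        raise


def load_model(path) -> TwoLayerModel:
    path = str(path)
    with open(os.path.join(path, "manifest.json")) as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"model bundle format {manifest.get('format_version')!r} "
            f"not supported (expected {FORMAT_VERSION!r})"
        )
    config = TrainConfig.from_dict(manifest["config"])
    leaves = []
    for lid in manifest["leaf_ids"]:
        m, th = phmm.load_phmm(os.path.join(path, f"hmm_{lid}.json"))
        leaves.append((lid, m, th))
    with open(os.path.join(path, "svm.json")) as fh:
        svm = json.load(fh)
    second = SecondLayer(
        gamma=svm["gamma"],
        C=svm["C"],
        support_vectors=np.array(svm["support_vectors"]),
        dual_coef=np.array(svm["dual_coef"]),
        intercept=svm["intercept"],
        platt_a=svm["platt_a"],
        platt_b=svm["platt_b"],
        decision_threshold=svm["decision_threshold"],
        grid_results=svm.get("grid_results", []),
    )
    return TwoLayerModel(
        config=config, leaves=leaves, second_layer=second,
        metadata=manifest.get("metadata", {}),
    )
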
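"""Three-stage coarse -> fine -> accurate activity classifier.

Stage 1 splits windows into moving {walking, upstairs, downstairs} and
stationary {sitting, standing, laying} on the forest-selected feature subset.
Stage 2 refines each group (walking vs up/downstairs; laying vs
sitting/standing) on the same subset.  Stage 3 resolves the two remaining
pairs with specialised features: sitting vs standing on a sparse-LPP
embedding of the selected subset, upstairs vs downstairs on the gyroscope
channels of the original feature space (stair direction lives in rotation,
not acceleration).

Each decision node holds one Gaussian-mixture CHMM per branch; a window's
(transformed) feature vector is reshaped into frames of length O and routed
down the branch whose model assigns it the highest forward log-likelihood.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .feature_selection import RFImportanceSelector
from .hmm import GaussianMixtureHMM, ModelBank
from .projection import SparseLPP

__all__ = [
    "frame_sequence",
    "frame_matrix",
    "gyro_mask",
    "ThreeStageClassifier",
    "train_three_stage",
    "predict_three_stage",
    "DEFAULT_STAGES",
]

#: Activity codes: 1 Walking, 2 Upstairs, 3 Downstairs, 4 Sitting,
#: 5 Standing, 6 Laying.
DEFAULT_STAGES = {
    "root": ({1, 2, 3}, {4, 5, 6}),        # moving vs stationary
    "moving": ({1}, {2, 3}),               # walking vs up/down
    "stationary": ({6}, {4, 5}),           # laying vs sit/stand
    "updown": ({2}, {3}),                  # upstairs vs downstairs
    "sitstand": ({4}, {5}),                # sitting vs standing
}


def frame_sequence(vector: np.ndarray, O: int) -> np.ndarray:
    """Reshape a length-p feature vector into ceil(p/O) frames of length O.

    The final frame is zero-padded when O does not divide p.  O > p yields a
    single zero-padded frame (with a warning).
    """
    vector = np.asarray(vector, dtype=float).ravel()
    if O < 1:
        raise ValueError("O must be >= 1")
    p = vector.size
    if O > p:
        warnings.warn(
            f"frame length O={O} exceeds vector length p={p}; "
            "emitting one zero-padded frame",
            RuntimeWarning,
        )
    T = max(1, int(np.ceil(p / O)))
    padded = np.zeros(T * O)
    padded[:p] = vector
    return padded.reshape(T, O)


def frame_matrix(X: np.ndarray, O: int) -> np.ndarray:
    """Vectorised :func:`frame_sequence` over rows: (N, p) -> (N, T, O)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    T = max(1, int(np.ceil(p / O)))
    padded = np.zeros((n, T * O))
    padded[:, :p] = X
    return padded.reshape(n, T, O)


def gyro_mask(feature_names, pattern: str = "Gyro") -> np.ndarray:
    """Indices of features whose name contains ``pattern`` (case-sensitive)."""
    names = list(feature_names)
    if not names:
        raise ValueError("feature name list is empty")
    idx = np.array([i for i, n in enumerate(names) if pattern in n], dtype=int)
    if idx.size == 0:
        raise ValueError(
            f"no feature name contains {pattern!r}; the gyroscope stage "
            "cannot run without features"
        )
    return idx


@dataclasses.dataclass
class _Node:
    """One decision node: a feature transform and a two-branch model bank."""

    name: str
    branches: tuple[frozenset, frozenset]
    transform: str  # {"rfim_subset", "splpp_embed", "gyro_mask", "identity"}
    frame_len: int
    bank: ModelBank | None = None

    def branch_label(self, branch: frozenset) -> int:
        # each branch is scored by one CHMM keyed on its smallest label code
        return min(branch)


class ThreeStageClassifier(ClassifierMixin, BaseEstimator):
    """Hierarchical model-bank classifier for six-activity feature windows.

    Parameters
    ----------
    frame_len : int, default=8
        Frame length O used to reshape each (transformed) feature vector into
        an observation sequence.
    stage1_states, stage1_mix : int
        CHMM size at the coarse node (defaults Q=4, M=2).
    stage2_states, stage2_mix : int
        CHMM size at the two fine nodes (defaults Q=4, M=3).
    stage3_states, stage3_mix : int
        CHMM size at the two accurate nodes (defaults Q=2, M=2; two states
        at this stage are part of the method).
    n_estimators, n_repeats : int
        Forest size and number of averaged repeats for the feature selector.
    splpp_components : int, default=13
        Embedding dimension of the sparse-LPP stage (clipped to the number of
        available columns).
    splpp_lambda, splpp_ridge : float
        Sparse-graph penalty and eigenproblem ridge.
    gyro_pattern : str, default="Gyro"
        Substring identifying gyroscope channels in the feature names.
    swap_stage3 : bool, default=False
        Swap the stage-3 feature transforms (sparse-LPP on up/down, gyro
        mask on sit/stand).
    run_selection : bool, default=True
        Fit the forest selector; when False all 1-2 stage nodes see the full
        feature space.
    em_max_iter, em_tol :
        Baum-Welch stopping parameters for every node model.
    random_state : int or None
        Master seed; per-node seeds are spawned from it.
    """

    def __init__(
        self,
        frame_len: int = 8,
        stage1_states: int = 4,
        stage1_mix: int = 2,
        stage2_states: int = 4,
        stage2_mix: int = 3,
        stage3_states: int = 2,
        stage3_mix: int = 2,
        n_estimators: int = 500,
        n_repeats: int = 1,
        splpp_components: int = 13,
        splpp_lambda: float = 0.1,
        splpp_ridge: float = 1e-6,
        gyro_pattern: str = "Gyro",
        swap_stage3: bool = False,
        run_selection: bool = True,
        em_max_iter: int = 100,
        em_tol: float = 1e-5,
        variance_floor: float = 1e-3,
        random_state: int | None = None,
    ):
        self.frame_len = frame_len
        self.stage1_states = stage1_states
        self.stage1_mix = stage1_mix
        self.stage2_states = stage2_states
        self.stage2_mix = stage2_mix
        self.stage3_states = stage3_states
        self.stage3_mix = stage3_mix
        self.n_estimators = n_estimators
        self.n_repeats = n_repeats
        self.splpp_components = splpp_components
        self.splpp_lambda = splpp_lambda
        self.splpp_ridge = splpp_ridge
        self.gyro_pattern = gyro_pattern
        self.swap_stage3 = swap_stage3
        self.run_selection = run_selection
        self.em_max_iter = em_max_iter
        self.em_tol = em_tol
        self.variance_floor = variance_floor
        self.random_state = random_state

    # ------------------------------------------------------------------- fit

    def _node_plan(self):
        t_sitstand = "gyro_mask" if self.swap_stage3 else "splpp_embed"
        t_updown = "splpp_embed" if self.swap_stage3 else "gyro_mask"
        qm = {
            "root": (self.stage1_states, self.stage1_mix),
            "moving": (self.stage2_states, self.stage2_mix),
            "stationary": (self.stage2_states, self.stage2_mix),
            "updown": (self.stage3_states, self.stage3_mix),
            "sitstand": (self.stage3_states, self.stage3_mix),
        }
        transforms = {
            "root": "rfim_subset",
            "moving": "rfim_subset",
            "stationary": "rfim_subset",
            "updown": t_updown,
            "sitstand": t_sitstand,
        }
        return qm, transforms

    def fit(self, X, y, feature_names=None):
        X, y = validate_data(self, X, y)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        missing = set(range(1, 7)) - set(self.classes_)
        if missing:
            raise ValueError(
                f"training data is missing activity label(s) {sorted(missing)}"
            )
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X.shape[1])]
        if len(feature_names) != X.shape[1]:
            raise ValueError("feature_names length must equal n_features")
        self.feature_names_ = list(feature_names)

        seeds = np.random.SeedSequence(self.random_state).spawn(8)
        node_seed = {
            name: int(ss.generate_state(1)[0] % (2**31 - 1))
            for name, ss in zip(
                ["selector", "root", "moving", "stationary", "updown",
                 "sitstand", "splpp", "spare"],
                seeds,
            )
        }

        # --- stage 1-2 feature subset (forest importance, above-mean rule)
        if self.run_selection:
            self.selector_ = RFImportanceSelector(
                n_estimators=self.n_estimators,
                n_repeats=self.n_repeats,
                random_state=node_seed["selector"],
            ).fit(X, y)
            self.selected_idx_ = np.flatnonzero(self.selector_.support_)
        else:
            self.selector_ = None
            self.selected_idx_ = np.arange(X.shape[1])

        # --- stage-3 transforms
        try:
            self.gyro_idx_ = gyro_mask(self.feature_names_, self.gyro_pattern)
        except ValueError:
            if "gyro_mask" in self._node_plan()[1].values():
                raise
            self.gyro_idx_ = None

        qm, transforms = self._node_plan()
        self.nodes_ = {}
        self.training_log_ = {}
        for name, branches in DEFAULT_STAGES.items():
            node = _Node(
                name=name,
                branches=tuple(frozenset(b) for b in branches),
                transform=transforms[name],
                frame_len=self.frame_len,
            )
            rows = np.isin(y, sorted(branches[0] | branches[1]))
            Xn, yn = X[rows], y[rows]
            feats = self._fit_node_features(node, Xn, yn, node_seed)
            Q, M = qm[name]
            models = {}
            log = {}
            rng = np.random.default_rng(node_seed[name])
            for branch in node.branches:
                in_branch = np.isin(yn, sorted(branch))
                if not in_branch.any():
                    raise ValueError(
                        f"node {name}: no training rows for labels "
                        f"{sorted(branch)}"
                    )
                obs = frame_matrix(feats[in_branch], node.frame_len)
                model = GaussianMixtureHMM(
                    Q, M, obs.shape[-1], variance_floor=self.variance_floor
                )
                seed = int(rng.integers(0, 2**31 - 1))
                model.initialize(obs, seed=seed)
                model.fit(
                    obs, max_iter=self.em_max_iter, tol=self.em_tol, seed=seed
                )
                label = node.branch_label(branch)
                models[label] = model
                log[label] = list(model.history_)
            node.bank = ModelBank(models)
            self.nodes_[name] = node
            self.training_log_[name] = log
        return self

    def _fit_node_features(self, node: _Node, Xn, yn, node_seed) -> np.ndarray:
        """Fit (if needed) and apply the node's feature transform."""
        if node.transform == "rfim_subset":
            return Xn[:, self.selected_idx_]
        if node.transform == "gyro_mask":
            return Xn[:, self.gyro_idx_]
        if node.transform == "splpp_embed":
            base = Xn[:, self.selected_idx_]
            d = min(self.splpp_components, base.shape[1])
            splpp = SparseLPP(
                n_components=d,
                lambda_l1=self.splpp_lambda,
                ridge=self.splpp_ridge,
            ).fit(base)
            self.splpp_ = splpp
            return splpp.transform(base)
        if node.transform == "identity":
            return Xn
        raise ValueError(f"unknown transform {node.transform!r}")

    def _apply_node_features(self, node: _Node, X) -> np.ndarray:
        if node.transform == "rfim_subset":
            return X[:, self.selected_idx_]
        if node.transform == "gyro_mask":
            return X[:, self.gyro_idx_]
        if node.transform == "splpp_embed":
            return self.splpp_.transform(X[:, self.selected_idx_])
        return X

    # --------------------------------------------------------------- predict

    def _route(self, node_name: str, X, out: np.ndarray, rows: np.ndarray):
        """Score the rows at one node and recurse into the two branches."""
        node = self.nodes_[node_name]
        feats = self._apply_node_features(node, X[rows])
        obs = frame_matrix(feats, node.frame_len)
        winners, _ = node.bank.classify_batch(obs)
        for branch in node.branches:
            label = node.branch_label(branch)
            sub = rows[winners == label]
            if sub.size == 0:
                continue
            if len(branch) == 1:
                out[sub] = label
            else:
                child = {
                    frozenset({2, 3}): "updown",
                    frozenset({4, 5}): "sitstand",
                    frozenset({1, 2, 3}): "moving",
                    frozenset({4, 5, 6}): "stationary",
                }[branch]
                self._route(child, X, out, sub)

    def predict(self, X) -> np.ndarray:
        """Route every window root -> leaf; returns activity codes 1-6."""
        check_is_fitted(self, "nodes_")
        X = validate_data(self, X, reset=False)
        out = np.zeros(X.shape[0], dtype=int)
        self._route("root", X, out, np.arange(X.shape[0]))
        if np.any(out == 0):  # pragma: no cover - routing is exhaustive
            raise RuntimeError("some windows were not routed to a leaf")
        return out

    def predict_stage1(self, X) -> np.ndarray:
        """Coarse moving(1)/stationary(4) group decision only."""
        check_is_fitted(self, "nodes_")
        X = validate_data(self, X, reset=False)
        node = self.nodes_["root"]
        obs = frame_matrix(self._apply_node_features(node, X), node.frame_len)
        winners, _ = node.bank.classify_batch(obs)
        return winners


# ----------------------------------------------------------------- functional


def train_three_stage(train, seed: int | None = 0, **params) -> ThreeStageClassifier:
    """Fit the three-stage classifier on a :class:`~harhmm.io.FeatureDataset`."""
    clf = ThreeStageClassifier(random_state=seed, **params)
    return clf.fit(train.X, train.y, feature_names=train.feature_names)


def predict_three_stage(model: ThreeStageClassifier, test) -> np.ndarray:
    if list(test.feature_names) != list(model.feature_names_):
        raise ValueError("test feature names incompatible with training names")
    return model.predict(test.X)
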
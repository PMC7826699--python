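"""Comparator classifiers behind one uniform fit/predict interface.

Five methods with a track record in machine olfaction: linear discriminant
analysis (LDA), a 4-hidden-layer ReLU multilayer perceptron, a Gini
decision tree capped at depth 10, PCA followed by LDA with the component
count chosen by cross-validated grid search, and a small 1-D convolutional
feature extractor feeding a support vector machine.  The underlying
estimators come from scikit-learn; the CNN feature extractor reuses the
package's own numpy layers.  All consume zero-centered datasets — flattened
to S*T features except for the CNN-SVM, which keeps the S x T matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.decomposition import PCA
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import nn
from .data import OdorDataset

VALID_BASELINES = ("lda", "mlp", "dt", "pca_lda", "cnn_svm")

#: PCA component grid for pca_lda; cross-validated accuracy picks one.
PCA_GRID = (2, 5, 10, 20, 30, 40, 49, 60, 80, 100)


class BaselineConfigError(ValueError):
    pass


@dataclass
class BaselineSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in VALID_BASELINES:
            raise BaselineConfigError(
                f"unknown baseline {self.name!r}; valid names: {list(VALID_BASELINES)}"
            )


def flatten_features(dataset: OdorDataset) -> tuple[np.ndarray, np.ndarray]:
    """(n_samples, S*T) feature table plus integer label vector.

    Flattening is row-major over the S x T matrix (sensor-major, then
    time), so sample i, sensor s, time t maps to column s*T + t.
    """
    x = dataset.values_array()
    return x.reshape(x.shape[0], -1), dataset.labels()


class BaselineClassifier:
    """Uniform wrapper: ``fit(dataset) -> self``, ``predict(dataset) -> labels``."""

    def __init__(self, spec: BaselineSpec) -> None:
        self.spec = spec
        self._est = None

    # subclasses fill these two
    def _features(self, dataset: OdorDataset) -> np.ndarray:
        return flatten_features(dataset)[0]

    def _build(self, n_train: int, n_classes: int):
        raise NotImplementedError

    def fit(self, dataset: OdorDataset) -> "BaselineClassifier":
        x = self._features(dataset)
        y = dataset.labels()
        self._est = self._build(len(dataset), len(dataset.class_names))
        self._est.fit(x, y)
        return self

    def predict(self, dataset: OdorDataset) -> np.ndarray:
        if self._est is None:
            raise RuntimeError("fit before predict")
        return self._est.predict(self._features(dataset))


class _Lda(BaselineClassifier):
    def _build(self, n_train, n_classes):
        return LinearDiscriminantAnalysis(**self.spec.hyperparameters)


class _Mlp(BaselineClassifier):
    """Four ReLU hidden layers; widths default to a 256-128-64-32 funnel."""

    def _build(self, n_train, n_classes):
        hp = dict(self.spec.hyperparameters)
        hidden = tuple(hp.pop("hidden_layer_sizes", (256, 128, 64, 32)))
        if len(hidden) != 4:
            raise BaselineConfigError("mlp requires exactly 4 hidden layers")
        return MLPClassifier(
            hidden_layer_sizes=hidden,
            activation="relu",
            max_iter=hp.pop("max_iter", 400),
            random_state=self.spec.seed,
            **hp,
        )


class _Dt(BaselineClassifier):
    def _build(self, n_train, n_classes):
        hp = dict(self.spec.hyperparameters)
        return DecisionTreeClassifier(
            criterion="gini",
            max_depth=hp.pop("max_depth", 10),
            random_state=self.spec.seed,
            **hp,
        )


class _PcaLda(BaselineClassifier):
    """Grid search over PCA dimensionality, scored by 5-fold CV accuracy on
    the training split; infeasible component counts are dropped."""

    def _build(self, n_train, n_classes):
        hp = dict(self.spec.hyperparameters)
        grid = hp.pop("pca_grid", PCA_GRID)
        cv = hp.pop("cv", 5)
        # stratified CV needs at least cv members per class
        cv = max(2, min(cv, n_train // max(n_classes, 1)))
        cap = n_train - n_train // cv  # samples in the smallest CV train fold
        feasible = [c for c in grid if c < cap]
        if not feasible:
            feasible = [min(2, cap - 1)]
        pipe = Pipeline(
            [("pca", PCA(svd_solver="full")), ("lda", LinearDiscriminantAnalysis())]
        )
        return GridSearchCV(
            pipe, {"pca__n_components": feasible}, cv=cv, scoring="accuracy"
        )


class _CnnSvm(BaselineClassifier):
    """1-D CNN feature extractor (2 conv+pool stages, FC to 64 features)
    trained briefly with a temporary softmax head, then frozen; an RBF
    support vector machine classifies the extracted features."""

    def _features(self, dataset: OdorDataset) -> np.ndarray:
        return dataset.values_array()  # keep S x T

    def _build(self, n_train, n_classes):
        return _CnnSvmEstimator(self.spec, n_classes)


class _CnnSvmEstimator:
    def __init__(self, spec: BaselineSpec, n_classes: int) -> None:
        hp = dict(spec.hyperparameters)
        self.channels = tuple(hp.pop("channels", (8, 16)))
        self.kernels = tuple(hp.pop("kernels", (5, 3)))
        self.feature_dim = hp.pop("feature_dim", 64)
        self.epochs = hp.pop("epochs", 30)
        self.lr = hp.pop("learning_rate", 1e-3)
        self.batch_size = hp.pop("batch_size", 32)
        self.kernel = hp.pop("svm_kernel", "rbf")
        self.C = hp.pop("svm_C", 1.0)
        self.seed = spec.seed
        self.n_classes = n_classes

    def _extract(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.feat_layers:
            h = layer.forward(h)
        return h

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_CnnSvmEstimator":
        n, s, t = x.shape
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 2**22]))
        c1, c2 = self.channels
        k1, k2 = self.kernels
        l1 = t - k1 + 1
        p1 = l1 // 2
        l2 = p1 - k2 + 1
        p2 = l2 // 2
        self.feat_layers = [
            nn.Conv1d(s, c1, k1, rng),
            nn.ReLU(),
            nn.MaxPool1d(),
            nn.Conv1d(c1, c2, k2, rng),
            nn.ReLU(),
            nn.MaxPool1d(),
            nn.Flatten(),
            nn.Linear(c2 * p2, self.feature_dim, rng),
            nn.ReLU(),
        ]
        head = nn.Linear(self.feature_dim, self.n_classes, rng)
        opt = nn.Adam(self.feat_layers + [head], lr=self.lr)
        onehot = np.eye(self.n_classes)
        order_rng = np.random.default_rng(np.random.SeedSequence([self.seed, 2**23]))
        for _ in range(self.epochs):
            order = order_rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                feats = self._extract(x[idx])
                p = nn.softmax(head.forward(feats))
                g = (p - onehot[y[idx]]) / len(idx)
                g = head.backward(g)
                for layer in reversed(self.feat_layers):
                    g = layer.backward(g)
                opt.step()
        feats = self._extract(x)
        self.svm = SVC(kernel=self.kernel, C=self.C, random_state=self.seed)
        self.svm.fit(feats, y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.svm.predict(self._extract(x))


_REGISTRY = {
    "lda": _Lda,
    "mlp": _Mlp,
    "dt": _Dt,
    "pca_lda": _PcaLda,
    "cnn_svm": _CnnSvm,
}


def build_baseline(spec: BaselineSpec) -> BaselineClassifier:
    """Instantiate the comparator named in ``spec`` (one of
    lda, mlp, dt, pca_lda, cnn_svm)."""
    return _REGISTRY[spec.name](spec)
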
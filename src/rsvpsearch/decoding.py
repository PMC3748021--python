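"""Single-trial target/distractor ERP decoding.

Feature scoring uses a canonical-variate (two-class: Fisher/LDA direction)
discriminant-power measure: each feature is scored by its squared Pearson
correlation with the trial projections onto the discriminant direction,
normalized to percent.  Features are kept only when their score exceeds a
threshold on *every* fold of a cross-fold split (stability selection).
Classification uses a Gaussian prototype classifier -- per class, a mixture
of Gaussian prototypes generalizing LDA/QDA -- whose output is the posterior
class probability.  An ensemble of per-time-window LDA classifiers is
provided as a comparator for higher-dimensional channel sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "DpScores",
    "GaussianClassifier",
    "LdaEnsemble",
    "discriminant_power",
    "stable_select",
    "harden",
    "cv_decoding_auc",
]


def _lda_direction(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fisher discriminant direction w ~ Sw^-1 (m1 - m0), pooled within-class
    scatter with a small ridge for rank-deficient cases."""
    X0, X1 = X[y == 0], X[y == 1]
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    R0, R1 = X0 - m0, X1 - m1
    sw = R0.T @ R0 + R1.T @ R1
    ridge = 1e-8 * np.trace(sw) / max(sw.shape[0], 1) + 1e-12
    w = np.linalg.solve(sw + ridge * np.eye(sw.shape[0]), m1 - m0)
    return w


def discriminant_power(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature discriminant power, in percent (sums to 100).

    DP_j is proportional to the squared Pearson correlation between feature
    j and the projection of all trials onto the two-class canonical
    discriminant direction.  Zero-variance features get DP 0.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("discriminant power needs exactly two classes present")
    if len(y) <= 2:
        raise ValueError("too few trials")
    t = X @ _lda_direction(X, y)
    t_c = t - t.mean()
    t_ss = float(t_c @ t_c)
    Xc = X - X.mean(axis=0)
    x_ss = np.einsum("ij,ij->j", Xc, Xc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (Xc.T @ t_c) ** 2 / (x_ss * t_ss)
    r2[~np.isfinite(r2)] = 0.0
    # constant features: correlation is undefined, scored 0 (guard against
    # float residue in the centered column)
    tiny = 1e-12 * (x_ss.max() if x_ss.size and x_ss.max() > 0 else 1.0)
    r2[x_ss <= tiny] = 0.0
    total = r2.sum()
    if total == 0.0:
        return np.zeros_like(r2)
    return 100.0 * r2 / total


@dataclass
class DpScores:
    """Fold-wise discriminant-power scores and the stable feature mask."""

    dp_per_fold: np.ndarray      # (n_folds, n_features), percent per fold
    fold_masks: np.ndarray       # (n_folds, n_features) bool
    stable_mask: np.ndarray      # (n_features,) bool, AND over folds

    @property
    def n_selected(self) -> int:
        return int(self.stable_mask.sum())


def _contiguous_folds(y: np.ndarray, n_folds: int) -> list[np.ndarray] | None:
    """Contiguous-in-time trial blocks, or None if a block misses a class."""
    idx = np.array_split(np.arange(len(y)), n_folds)
    for fold in idx:
        if len(np.unique(y[fold])) < 2:
            return None
    return idx


def stable_select(X: np.ndarray, y: np.ndarray, n_folds: int = 3,
                  threshold: float = 1.0, seed: int = 0) -> DpScores:
    """Keep features whose DP exceeds ``threshold`` (percent) in every fold.

    Folds are contiguous-in-time trial blocks (respecting the presentation
    order); when a block would miss a class, a stratified split is used
    instead.  Raises when no split can place both classes in every fold.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if np.bincount(y, minlength=2).min() < n_folds:
        raise ValueError(
            f"need at least {n_folds} trials of each class for {n_folds} folds"
        )
    folds = _contiguous_folds(y, n_folds)
    if folds is None:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [test for _, test in skf.split(X, y)]
    dp = np.stack([discriminant_power(X[f], y[f]) for f in folds])
    masks = dp > threshold
    return DpScores(dp_per_fold=dp, fold_masks=masks,
                    stable_mask=masks.all(axis=0))


def harden(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize soft target scores: 1 if score > threshold else 0.

    The inequality is strict, so a score exactly at the threshold counts as
    distractor (the conservative choice for a rare-target stream).
    """
    return (np.asarray(scores) > threshold).astype(np.int64)


@dataclass
class GaussianClassifier:
    """Gaussian prototype classifier: per-class mixture of Gaussians.

    Each class is represented by ``n_prototypes`` Gaussian prototypes; with
    one prototype per class and a shared pooled covariance the model reduces
    to LDA, with per-class covariances to QDA.  Two covariance structures
    are offered:

    * ``"diag"`` (default): per-prototype diagonal covariances, fitted by
      expectation-maximization with k-means initialization (tolerance 1e-6,
      at most 200 sweeps).
    * ``"pooled"``: a single full covariance shared by all prototypes and
      classes, estimated from the pooled within-prototype scatter;
      prototype means come from per-class k-means.

    Posteriors follow Bayes' rule over the summed prototype likelihoods with
    class priors set to the training class frequencies.
    """

    n_prototypes: int = 4
    covariance: str = "diag"
    reg: float | None = None
    seed: int = 0

    classes_: np.ndarray = field(default=None, repr=False)
    means_: dict = field(default=None, repr=False)        # class -> (P, d)
    variances_: dict = field(default=None, repr=False)    # class -> (P, d) diag
    weights_: dict = field(default=None, repr=False)      # class -> (P,)
    priors_: np.ndarray = field(default=None, repr=False)
    pooled_cov_: np.ndarray = field(default=None, repr=False)  # (d, d) or None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        counts = np.array([(y == c).sum() for c in self.classes_])
        if counts.min() < self.n_prototypes:
            raise ValueError(
                f"smallest class has {counts.min()} trials, fewer than "
                f"{self.n_prototypes} prototypes"
            )
        reg = self.reg
        if reg is None:
            reg = 1e-6 * float(np.mean(X.var(axis=0))) + 1e-12
        self.priors_ = counts / counts.sum()
        self.means_, self.variances_, self.weights_ = {}, {}, {}
        if self.covariance == "diag":
            for c in self.classes_:
                Xc = X[y == c]
                gm = GaussianMixture(
                    n_components=self.n_prototypes, covariance_type="diag",
                    reg_covar=reg, tol=1e-6, max_iter=200,
                    init_params="kmeans", random_state=self.seed,
                )
                gm.fit(Xc)
                self.means_[int(c)] = gm.means_
                self.variances_[int(c)] = gm.covariances_
                self.weights_[int(c)] = gm.weights_
            self.pooled_cov_ = None
        elif self.covariance == "pooled":
            resid_scatter = np.zeros((X.shape[1], X.shape[1]))
            n_total = 0
            for c in self.classes_:
                Xc = X[y == c]
                if self.n_prototypes == 1:
                    means = Xc.mean(axis=0, keepdims=True)
                    assign = np.zeros(len(Xc), dtype=int)
                else:
                    km = KMeans(n_clusters=self.n_prototypes, n_init=10,
                                random_state=self.seed).fit(Xc)
                    means = km.cluster_centers_
                    assign = km.labels_
                self.means_[int(c)] = means
                self.weights_[int(c)] = np.bincount(
                    assign, minlength=self.n_prototypes) / len(Xc)
                R = Xc - means[assign]
                resid_scatter += R.T @ R
                n_total += len(Xc)
            dof = max(n_total - self.n_prototypes * len(self.classes_), 1)
            cov = resid_scatter / dof
            cov[np.diag_indices_from(cov)] += reg
            self.pooled_cov_ = cov
            for c in self.classes_:
                self.variances_[int(c)] = None
        else:
            raise ValueError(f"unknown covariance structure {self.covariance!r}")
        return self

    def _class_log_likelihood(self, X: np.ndarray, c: int) -> np.ndarray:
        means = self.means_[c]
        w = self.weights_[c]
        if self.covariance == "pooled":
            cov = self.pooled_cov_
            chol = np.linalg.cholesky(cov)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            parts = []
            for p in range(means.shape[0]):
                d = X - means[p]
                sol = np.linalg.solve(chol, d.T)
                maha = np.einsum("ij,ij->j", sol, sol)
                parts.append(-0.5 * (maha + logdet
                                     + X.shape[1] * np.log(2 * np.pi)))
            ll = np.stack(parts, axis=1)
        else:
            var = self.variances_[c]
            X3 = X[:, None, :]
            ll = -0.5 * (((X3 - means[None]) ** 2 / var[None]).sum(-1)
                         + np.log(var).sum(-1)[None]
                         + X.shape[1] * np.log(2 * np.pi))
        return logsumexp(ll + np.log(np.maximum(w, 1e-300))[None, :], axis=1)

    def predict_log_joint(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != next(iter(self.means_.values())).shape[1]:
            raise ValueError("feature dimension does not match the fitted model")
        cols = [self._class_log_likelihood(X, int(c)) + np.log(self.priors_[k])
                for k, c in enumerate(self.classes_)]
        return np.stack(cols, axis=1)

    def predict_posterior(self, X: np.ndarray) -> np.ndarray:
        """Posterior class probabilities, one row per trial (rows sum to 1)."""
        lj = self.predict_log_joint(X)
        return np.exp(lj - logsumexp(lj, axis=1, keepdims=True))

    def predict_target_score(self, X: np.ndarray, target_class: int = 1
                             ) -> np.ndarray:
        """Posterior probability of the target class, in [0, 1]."""
        k = int(np.flatnonzero(self.classes_ == target_class)[0])
        return self.predict_posterior(X)[:, k]

    # -- JSON serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_prototypes": self.n_prototypes,
            "covariance": self.covariance,
            "seed": self.seed,
            "classes": self.classes_.tolist(),
            "priors": self.priors_.tolist(),
            "means": {str(c): self.means_[int(c)].tolist() for c in self.classes_},
            "weights": {str(c): self.weights_[int(c)].tolist()
                        for c in self.classes_},
        }
        if self.covariance == "diag":
            d["variances"] = {str(c): self.variances_[int(c)].tolist()
                              for c in self.classes_}
        else:
            d["pooled_cov"] = self.pooled_cov_.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianClassifier":
        model = cls(n_prototypes=d["n_prototypes"], covariance=d["covariance"],
                    seed=d["seed"])
        model.classes_ = np.asarray(d["classes"])
        model.priors_ = np.asarray(d["priors"])
        model.means_ = {int(c): np.asarray(v) for c, v in d["means"].items()}
        model.weights_ = {int(c): np.asarray(v) for c, v in d["weights"].items()}
        if model.covariance == "diag":
            model.variances_ = {int(c): np.asarray(v)
                                for c, v in d["variances"].items()}
            model.pooled_cov_ = None
        else:
            model.variances_ = {int(c): None for c in model.classes_}
            model.pooled_cov_ = np.asarray(d["pooled_cov"])
        return model

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        payload = self.to_dict()
        if extra:
            payload["extra"] = extra
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GaussianClassifier":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class LdaEnsemble:
    """Ensemble of per-time-window LDA classifiers over an epoch.

    The epoch is split into consecutive windows (100 ms each by default);
    one LDA is trained on each window's flattened channel x sample block.
    The epoch duration must be a whole multiple of the window length
    (200--700 ms with 100 ms windows gives 5 classifiers); window sample
    counts may differ by one when the window length is not a whole number
    of samples.  The fused score is the mean of the per-window discriminant
    outputs after z-standardization on the training set, so every window
    contributes on a common scale.
    """

    window_ms: float = 100.0

    models_: list = field(default=None, repr=False)
    norms_: list = field(default=None, repr=False)
    edges_: np.ndarray = field(default=None, repr=False)

    @property
    def n_windows_(self) -> int:
        return 0 if self.edges_ is None else len(self.edges_) - 1

    def _blocks(self, X_tc: np.ndarray):
        for a, b in zip(self.edges_[:-1], self.edges_[1:]):
            yield X_tc[:, :, a:b].reshape(X_tc.shape[0], -1)

    def fit(self, X_tc: np.ndarray, y: np.ndarray, sample_rate: float
            ) -> "LdaEnsemble":
        X_tc = np.asarray(X_tc, dtype=np.float64)
        n_samples = X_tc.shape[2]
        epoch_ms = n_samples / sample_rate * 1000.0
        n_win_f = epoch_ms / self.window_ms
        n_win = int(round(n_win_f))
        if n_win < 1 or abs(n_win_f - n_win) > 1e-6:
            raise ValueError(
                f"epoch of {epoch_ms:g} ms is not divisible into "
                f"{self.window_ms:g} ms windows"
            )
        self.edges_ = np.round(np.linspace(0, n_samples, n_win + 1)).astype(int)
        if np.any(np.diff(self.edges_) < 1):
            raise ValueError("window shorter than one sample")
        self.models_, self.norms_ = [], []
        for block in self._blocks(X_tc):
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            lda.fit(block, y)
            out = lda.decision_function(block)
            sd = out.std()
            self.norms_.append((out.mean(), sd if sd > 0 else 1.0))
            self.models_.append(lda)
        return self

    def predict_target_score(self, X_tc: np.ndarray) -> np.ndarray:
        """Alias for :meth:`decision_scores` (ensemble outputs are monotone
        target scores, not posteriors)."""
        return self.decision_scores(X_tc)

    def decision_scores(self, X_tc: np.ndarray) -> np.ndarray:
        """Fused score per trial: mean of standardized per-window outputs."""
        X_tc = np.asarray(X_tc, dtype=np.float64)
        z = np.zeros((X_tc.shape[0], self.n_windows_))
        for w, (block, lda, (mu, sd)) in enumerate(
                zip(self._blocks(X_tc), self.models_, self.norms_)):
            z[:, w] = (lda.decision_function(block) - mu) / sd
        return z.mean(axis=1)


def cv_decoding_auc(X: np.ndarray, y: np.ndarray, n_folds: int = 3,
                    n_prototypes: int = 4, dp_threshold: float = 1.0,
                    seed: int = 0) -> float:
    """Cross-validated single-trial decoding AUC of the standard pipeline.

    Within each stratified fold: stability feature selection on the
    training split (falling back to all features when no feature is stable
    in every sub-fold), a Gaussian prototype classifier on the selected
    features, posterior target scores on the held-out split.  Returns the
    ROC AUC of the pooled held-out scores.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(y))
    for train, test in skf.split(X, y):
        sel = stable_select(X[train], y[train], threshold=dp_threshold,
                            seed=seed)
        mask = (sel.stable_mask if sel.stable_mask.any()
                else np.ones(X.shape[1], dtype=bool))
        clf = GaussianClassifier(n_prototypes=n_prototypes, seed=seed)
        clf.fit(X[train][:, mask], y[train])
        scores[test] = clf.predict_target_score(X[test][:, mask])
    return float(roc_auc_score(y, scores))
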
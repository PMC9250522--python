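"""Population decoding of stimulus conditions.

Single-trial population vectors are dF/F averages in 1-s time bins (one
feature per cell per bin).  Decoders are a nearest-centroid classifier
(Euclidean) and linear / RBF support-vector machines, evaluated with
seeded stratified k-fold cross-validation (k = 10 by default).
Significance comes from locating the real accuracy in the distribution of
accuracies over label shuffles (one-sided exceedance, floored at
1/n_shuffles).  Cross-condition transfer tests train a decoder in one
stimulus context and score it on unseen trials from another, probing
whether the coding dimensions are shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import NearestCentroid
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .preprocess import DffTensor
from .protocol import StimulusProtocol, parse_mixture
from .synth import FacialMotion

__all__ = [
    "PopulationVectors",
    "DecodeResult",
    "TransferResult",
    "build_features",
    "centroid_cv",
    "permutation_pvalue",
    "transfer_test",
    "svm_decode",
    "mixture_categorize",
    "facial_decode",
]


# --------------------------------------------------------------------------
# features
# --------------------------------------------------------------------------


@dataclass
class PopulationVectors:
    """Trial-by-feature tensor for decoding.

    ``X`` is trials x features x bins; ``y`` the per-trial labels being
    decoded.  ``bin_edges_s`` are absolute times within the trial.
    """

    X: np.ndarray
    y: np.ndarray
    bin_edges_s: np.ndarray
    protocol: StimulusProtocol
    pooled: bool = False

    @property
    def n_bins(self) -> int:
        return self.X.shape[2]

    def bin_matrix(self, b: int) -> np.ndarray:
        return self.X[:, :, b]

    def bins_in(self, window: tuple[float, float]) -> np.ndarray:
        """Indices of bins whose center falls in an onset-relative window."""
        centers = 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:]) - self.protocol.stim_onset_s
        return np.flatnonzero((centers >= window[0]) & (centers < window[1]))

    @property
    def stim_bins(self) -> np.ndarray:
        return self.bins_in(self.protocol.stim_epoch_s)

    @property
    def baseline_bins(self) -> np.ndarray:
        return self.bins_in((-self.protocol.stim_onset_s, 0.0))

    def window_matrix(self, bins: np.ndarray) -> np.ndarray:
        """Trials x features matrix averaged over the given bins."""
        return self.X[:, :, bins].mean(axis=2)

    def restrict(
        self,
        trials: np.ndarray | None = None,
        bins: np.ndarray | None = None,
        y: np.ndarray | None = None,
    ) -> "PopulationVectors":
        """Sub-view over trials and/or a contiguous bin range."""
        X, yy, edges = self.X, self.y, self.bin_edges_s
        if trials is not None:
            trials = np.asarray(trials, dtype=int)
            X, yy = X[trials], yy[trials]
        if bins is not None:
            bins = np.asarray(bins, dtype=int)
            if bins.size and np.any(np.diff(bins) != 1):
                raise ValueError("bins must be contiguous")
            X = X[:, :, bins]
            edges = edges[bins[0] : bins[-1] + 2]
        if y is not None:
            yy = np.asarray(y)
        return PopulationVectors(
            X=X, y=yy, bin_edges_s=edges, protocol=self.protocol, pooled=self.pooled
        )


def _binned(dff: DffTensor, bin_s: float) -> tuple[np.ndarray, np.ndarray]:
    proto = dff.protocol
    n_bins = int(round(proto.trial_duration_s / bin_s))
    if n_bins < 1 or abs(n_bins * bin_s - proto.trial_duration_s) > 1e-9:
        raise ValueError(f"bins of {bin_s}s do not tile the {proto.trial_duration_s}s trial")
    edges = np.arange(n_bins + 1) * bin_s
    keep = dff.valid.all(axis=1)
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} cell(s) with invalid F0 dropped from the features",
            stacklevel=3,
        )
    traces = dff.dff[keep]
    t = proto.frame_times() + proto.stim_onset_s  # absolute trial time
    X = np.empty((proto.n_trials, traces.shape[0], n_bins))
    for b in range(n_bins):
        m = (t >= edges[b]) & (t < edges[b + 1])
        X[:, :, b] = traces[:, :, m].mean(axis=-1).T
    return X, edges


def _repetition_index(protocol: StimulusProtocol) -> np.ndarray:
    """Occurrence number of each trial within its condition."""
    counts: dict[int, int] = {}
    rep = np.empty(protocol.n_trials, dtype=int)
    for t, ci in enumerate(protocol.trial_order):
        rep[t] = counts.get(ci, 0)
        counts[ci] = rep[t] + 1
    return rep


def build_features(
    dff: DffTensor | list[DffTensor],
    bin_s: float = 1.0,
    z_score: bool = False,
    labels: np.ndarray | None = None,
) -> PopulationVectors:
    """Population vectors from one session or a pooled pseudo-population.

    With a list of sessions (identical protocols up to trial order), cells
    are concatenated across sessions after matching trials by (condition,
    repetition index) — the pseudo-population used when decoding from all
    recorded neurons at once.  ``z_score`` standardises each feature to
    mean 0 / sd 1 across trials.  ``labels`` defaults to the condition
    index per trial.
    """
    many = isinstance(dff, (list, tuple))
    sessions = list(dff) if many else [dff]
    ref = sessions[0].protocol

    mats = []
    for s in sessions:
        p = s.protocol
        if p.conditions != ref.conditions or p.reps_per_condition != ref.reps_per_condition:
            raise ValueError("pooled sessions must share the condition set and repetitions")
        X, edges = _binned(s, bin_s)
        if many:
            # canonical trial order: sort by (condition, repetition index)
            order = np.lexsort((_repetition_index(p), p.condition_labels()))
            X = X[order]
        mats.append(X)

    proto = ref
    if many:
        X = np.concatenate(mats, axis=1)
        ref_order = np.lexsort((_repetition_index(ref), ref.condition_labels()))
        y = ref.condition_labels()[ref_order]
    else:
        # a single session keeps its native trial order
        X = mats[0]
        y = ref.condition_labels()

    if labels is not None:
        labels = np.asarray(labels)
        if labels.size != X.shape[0]:
            raise ValueError("labels must align with trials")
        y = labels
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values (excluded cells?)")
    if z_score:
        sd = X.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0, keepdims=True)) / sd
    return PopulationVectors(X=X, y=np.asarray(y), bin_edges_s=edges, protocol=proto, pooled=many)


# --------------------------------------------------------------------------
# cross-validated decoding
# --------------------------------------------------------------------------


@dataclass
class DecodeResult:
    """Per-time-bin decoding accuracy with optional shuffle calibration."""

    accuracy: np.ndarray  # % per bin
    fold_scores: np.ndarray  # bins x k, fractions
    k: int
    classes: np.ndarray
    bin_edges_s: np.ndarray
    shuffle_accuracies: np.ndarray | None = None  # bins x n_shuffles, %
    pvalues: np.ndarray | None = None  # per bin, >= 1/n_shuffles
    confusion: np.ndarray | None = None  # at `confusion_bin`
    confusion_bin: int | None = None

    @property
    def chance(self) -> float:
        return 100.0 / self.classes.size


def _make_estimator(decoder: str, standardize: bool = False, **kw):
    if decoder == "centroid":
        est = NearestCentroid(metric="euclidean")
    elif decoder == "svm":
        est = LinearSVC(C=kw.get("C", 1.0))
    elif decoder == "rbf":
        est = SVC(kernel="rbf", C=kw.get("C", 1.0), gamma=kw.get("gamma", "scale"))
    else:
        raise ValueError(f"unknown decoder {decoder!r}")
    return make_pipeline(StandardScaler(), est) if standardize else est


def _check_fold_support(y: np.ndarray, k: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} trials < k={k} folds; use a smaller k"
        )


def _cv_accuracy(X: np.ndarray, y: np.ndarray, est, k: int, seed: int) -> np.ndarray:
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return cross_val_score(clone(est), X, y, cv=cv)


def _cv_over_bins(
    pv: PopulationVectors, y: np.ndarray, est, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    folds = np.stack([_cv_accuracy(pv.bin_matrix(b), y, est, k, seed) for b in range(pv.n_bins)])
    return 100.0 * folds.mean(axis=1), folds


def centroid_cv(
    pv: PopulationVectors,
    y: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
    standardize: bool = False,
) -> DecodeResult:
    """Nearest-centroid decoding with stratified k-fold CV, per time bin.

    Per fold, class centroids are computed from the training trials and
    test trials are assigned to the nearest centroid (Euclidean distance);
    accuracy is the mean over folds.
    """
    y = pv.y if y is None else np.asarray(y)
    _check_fold_support(y, k)
    est = _make_estimator("centroid", standardize)
    acc, folds = _cv_over_bins(pv, y, est, k, seed)
    return DecodeResult(
        accuracy=acc, fold_scores=folds, k=k, classes=np.unique(y), bin_edges_s=pv.bin_edges_s
    )


def permutation_pvalue(
    pv: PopulationVectors,
    y: np.ndarray | None = None,
    decoder: str = "centroid",
    k: int = 10,
    n_shuffles: int = 1000,
    seed: int = 0,
    standardize: bool = False,
    alternative: str = "greater",
    **est_kw,
) -> DecodeResult:
    """Shuffle-calibrated decoding: real accuracy located in the shuffle distribution.

    The full cross-validation is repeated for ``n_shuffles`` label
    permutations; per bin, p = (number of shuffled accuracies >= real) /
    n_shuffles, floored at 1/n_shuffles (one-sided exceedance, the default).
    ``alternative='two-sided'`` instead counts shuffles whose deviation from
    the shuffle mean is at least as large as the real one's.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    y = pv.y if y is None else np.asarray(y)
    _check_fold_support(y, k)
    est = _make_estimator(decoder, standardize, **est_kw)
    acc, folds = _cv_over_bins(pv, y, est, k, seed)

    rng = np.random.default_rng(seed)
    shuf = np.empty((pv.n_bins, n_shuffles))
    for s in range(n_shuffles):
        ys = rng.permutation(y)
        shuf[:, s], _ = _cv_over_bins(pv, ys, est, k, seed)
    if alternative == "greater":
        exceed = (shuf >= acc[:, None]).sum(axis=1)
    else:
        center = shuf.mean(axis=1, keepdims=True)
        exceed = (np.abs(shuf - center) >= np.abs(acc[:, None] - center)).sum(axis=1)
    p = np.maximum(exceed, 1) / n_shuffles

    return DecodeResult(
        accuracy=acc,
        fold_scores=folds,
        k=k,
        classes=np.unique(y),
        bin_edges_s=pv.bin_edges_s,
        shuffle_accuracies=shuf,
        pvalues=p,
    )


# --------------------------------------------------------------------------
# cross-condition transfer
# --------------------------------------------------------------------------


@dataclass
class TransferResult:
    """In-domain (cross-validated) vs out-of-domain accuracy of one decoder."""

    in_domain_accuracy: float  # %
    out_domain_accuracy: float  # %
    n_train: int
    n_test: int
    classes: np.ndarray


def transfer_test(
    pv: PopulationVectors,
    y_target: np.ndarray,
    train_trials: np.ndarray,
    test_trials: np.ndarray,
    decoder: str = "centroid",
    k: int = 10,
    seed: int = 0,
    bins: np.ndarray | None = None,
    **est_kw,
) -> TransferResult:
    """Train in one stimulus context, test in another.

    The in-domain score is stratified k-fold CV within ``train_trials``;
    the out-of-domain score comes from a decoder fit on all training trials
    and applied to the disjoint ``test_trials``.  Features are dF/F means
    over ``bins`` (default: the stimulation-epoch bins).
    """
    train_trials = np.asarray(train_trials, dtype=int)
    test_trials = np.asarray(test_trials, dtype=int)
    if train_trials.size == 0 or test_trials.size == 0:
        raise ValueError("empty trial filter")
    if np.intersect1d(train_trials, test_trials).size:
        raise ValueError("train and out-of-domain test trials must be disjoint")
    y_target = np.asarray(y_target)
    bins = pv.stim_bins if bins is None else np.asarray(bins, dtype=int)
    M = pv.window_matrix(bins)

    y_tr = y_target[train_trials]
    _check_fold_support(y_tr, k)
    est = _make_estimator(decoder, **est_kw)
    in_acc = 100.0 * _cv_accuracy(M[train_trials], y_tr, est, k, seed).mean()
    fitted = clone(est).fit(M[train_trials], y_tr)
    out_acc = 100.0 * np.mean(fitted.predict(M[test_trials]) == y_target[test_trials])
    return TransferResult(
        in_domain_accuracy=in_acc,
        out_domain_accuracy=out_acc,
        n_train=train_trials.size,
        n_test=test_trials.size,
        classes=np.unique(y_tr),
    )


# --------------------------------------------------------------------------
# SVM decoding with regularization selection
# --------------------------------------------------------------------------


def _select_C(
    pv: PopulationVectors,
    y: np.ndarray,
    k: int,
    seed: int,
    C_grid: np.ndarray,
    standardize: bool,
) -> float:
    """Regularization rule: maximize stimulus-bin accuracy subject to
    baseline-bin accuracy staying within the binomial CI of chance."""
    stim_b, base_b = pv.stim_bins, pv.baseline_bins
    chance = 1.0 / np.unique(y).size
    n = y.size
    half = 1.96 * np.sqrt(chance * (1 - chance) / n)

    best_C, best_acc = None, -np.inf
    for C in C_grid:
        est = _make_estimator("svm", standardize, C=C)
        stim_acc = np.mean(
            [_cv_accuracy(pv.bin_matrix(b), y, est, k, seed).mean() for b in stim_b]
        )
        base_acc = np.mean(
            [_cv_accuracy(pv.bin_matrix(b), y, est, k, seed).mean() for b in base_b]
        )
        if abs(base_acc - chance) <= half and stim_acc > best_acc:
            best_C, best_acc = C, stim_acc
    if best_C is None:
        warnings.warn(
            "no regularization value kept baseline accuracy at chance; "
            "falling back to the smallest C",
            stacklevel=3,
        )
        best_C = float(C_grid.min())
    return float(best_C)


def svm_decode(
    pv: PopulationVectors,
    y: np.ndarray | None = None,
    k: int = 10,
    n_shuffles: int = 0,
    seed: int = 0,
    C: float | None = None,
    C_grid: np.ndarray | None = None,
    standardize: bool = False,
    confusion_bin: int | None = None,
) -> DecodeResult:
    """Multi-class (one-vs-rest) linear SVM decoding per time bin.

    When ``C`` is not given it is selected on a grid by maximizing accuracy
    during the stimulation epoch while requiring baseline-epoch accuracy to
    stay within the binomial 95% CI of chance.  With ``n_shuffles > 0``
    shuffle p-values are attached; the confusion matrix is computed by CV
    at ``confusion_bin`` (default: the best stimulation bin).
    """
    y = pv.y if y is None else np.asarray(y)
    _check_fold_support(y, k)
    if C is None:
        grid = np.logspace(-3, 2, 6) if C_grid is None else np.asarray(C_grid, dtype=float)
        C = _select_C(pv, y, k, seed, grid, standardize)

    if n_shuffles > 0:
        res = permutation_pvalue(
            pv, y, decoder="svm", k=k, n_shuffles=n_shuffles, seed=seed,
            standardize=standardize, C=C,
        )
    else:
        est = _make_estimator("svm", standardize, C=C)
        acc, folds = _cv_over_bins(pv, y, est, k, seed)
        res = DecodeResult(
            accuracy=acc, fold_scores=folds, k=k, classes=np.unique(y),
            bin_edges_s=pv.bin_edges_s,
        )

    if confusion_bin is None:
        stim = pv.stim_bins
        confusion_bin = int(stim[np.argmax(res.accuracy[stim])]) if stim.size else 0
    res.confusion = _cv_confusion(
        pv.bin_matrix(confusion_bin), y, _make_estimator("svm", standardize, C=C), k, seed
    )
    res.confusion_bin = confusion_bin
    return res


def _cv_confusion(X: np.ndarray, y: np.ndarray, est, k: int, seed: int) -> np.ndarray:
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    classes = np.unique(y)
    cm = np.zeros((classes.size, classes.size), dtype=int)
    for tr, te in cv.split(X, y):
        fitted = clone(est).fit(X[tr], y[tr])
        cm += confusion_matrix(y[te], fitted.predict(X[te]), labels=classes)
    return cm


# --------------------------------------------------------------------------
# odor-mixture categorization
# --------------------------------------------------------------------------


def mixture_categorize(
    pv: PopulationVectors,
    pure: tuple[str, str] = ("AA", "EB"),
    C: float = 1.0,
    gamma: str | float = "scale",
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Categorize binary-mixture trials with an RBF-kernel SVM trained on pure odors.

    The classifier sees only pure-odor trials of the two components; every
    mixture condition's trials are then assigned to one of the two pure
    classes.  Returns, per mixture label, the fraction of its trials
    assigned to each pure odor.
    """
    proto = pv.protocol
    odors = [c.odor for c in proto.trial_conditions()]
    pure_mask = np.array([o in pure for o in odors])
    if not all(any(o == p for o in odors) for p in pure):
        raise ValueError(f"pure-odor classes {pure} not all present in the protocol")
    mix_labels = sorted(
        {o for o in odors if o is not None and parse_mixture(o) is not None}
    )
    if not mix_labels:
        raise ValueError("protocol contains no mixture conditions")

    M = pv.window_matrix(pv.stim_bins)
    y = np.asarray(odors, dtype=object)
    est = SVC(kernel="rbf", C=C, gamma=gamma)
    est.fit(M[pure_mask], y[pure_mask])

    out: dict[str, dict[str, float]] = {}
    for m in mix_labels:
        sel = np.array([o == m for o in odors])
        pred = est.predict(M[sel])
        out[m] = {p: float(np.mean(pred == p)) for p in pure}
    return out


# --------------------------------------------------------------------------
# facial-motion decoding
# --------------------------------------------------------------------------


def facial_decode(
    motion: FacialMotion,
    protocol: StimulusProtocol,
    n_pcs: int = 500,
    trials: np.ndarray | None = None,
    y: np.ndarray | None = None,
    k: int = 10,
    n_shuffles: int = 0,
    seed: int = 0,
) -> DecodeResult:
    """Decode odor identity from facial motion energy.

    The (time x pixels) motion matrix is reduced by truncated SVD; the
    temporal principal components, averaged per trial in 1-s bins, are the
    features of a linear multi-class SVM.  By default the decoded trials
    are the odor-bearing ones and ``y`` their odor labels.
    """
    M = motion.motion
    max_rank = min(M.shape)
    if n_pcs > max_rank:
        warnings.warn(f"n_pcs={n_pcs} exceeds matrix rank bound {max_rank}; truncated",
                      stacklevel=2)
        n_pcs = max_rank
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    pcs = (U[:, :n_pcs] * s[:n_pcs]).reshape(motion.n_trials, motion.frames_per_trial, n_pcs)

    fs = motion.fs_hz
    bin_s = 1.0
    n_bins = int(round(protocol.trial_duration_s / bin_s))
    fpb = int(round(fs * bin_s))
    X = pcs[:, : n_bins * fpb].reshape(motion.n_trials, n_bins, fpb, n_pcs).mean(axis=2)
    X = np.transpose(X, (0, 2, 1))  # trials x features x bins

    if trials is None:
        trials = protocol.trials_where(category=("odor_only", "bimodal"))
    trials = np.asarray(trials, dtype=int)
    if y is None:
        conds = protocol.trial_conditions()
        y = np.asarray([conds[t].odor for t in trials], dtype=object)
    edges = np.arange(n_bins + 1) * bin_s
    pv = PopulationVectors(
        X=X[trials], y=np.asarray(y), bin_edges_s=edges, protocol=protocol
    )
    if n_shuffles > 0:
        return permutation_pvalue(pv, decoder="svm", k=k, n_shuffles=n_shuffles, seed=seed)
    y_arr = pv.y
    _check_fold_support(y_arr, k)
    est = _make_estimator("svm")
    acc, folds = _cv_over_bins(pv, y_arr, est, k, seed)
    return DecodeResult(
        accuracy=acc, fold_scores=folds, k=k, classes=np.unique(y_arr), bin_edges_s=edges
    )
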
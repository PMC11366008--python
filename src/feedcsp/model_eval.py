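"""Classifier training, repeated cross-validation, and model comparison.

One "model" is a full pipeline from subject-level inputs to a class label:
for the delta/theta components, per-fold CSP feature extraction (fit on
training subjects only) feeding a support-vector classifier; for the ERP
component, the single FCz mean-amplitude feature feeding the same classifier.
Hyperparameters (CSP component count and shrinkage, SVC kernel and C) are
selected by threefold cross-validated balanced accuracy; selected models are
scored with 10-repeated tenfold CV, tested against label permutations, and
compared pairwise with the Nadeau-Bengio corrected resampled t-test, whose
variance term ``(1/(r k) + n_test/n_train) var(d)`` corrects the optimism of
naively treating overlapping CV folds as independent.

Every data-dependent fitting step — covariance averaging, the CSP
eigendecomposition, feature standardisation, the SVC — sees only
training-fold subjects.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata, t as t_dist
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import band_separation as bs
from . import csp_features as csp
from .data_model import (Cutoffs, EpochSet, SubjectMeta, assign_groups,
                         select_contrast)

logger = logging.getLogger("feedcsp")

COMPONENTS = ("delta", "theta", "erp")
DEFAULT_B = 999  # resolves p to 0.001


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def balanced_accuracy_from_counts(tp: int, fn: int, tn: int, fp: int) -> float:
    """(sensitivity + specificity) / 2 from a 2x2 confusion table."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both truth classes must be present")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def confusion_counts(y_true: np.ndarray,
                     y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    return tp, fn, tn, fp


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return balanced_accuracy_from_counts(*confusion_counts(y_true, y_pred))


def precision_score(tp: int, fn: int, tn: int, fp: int) -> float:
    """TP / (TP + FP); 0 when no positive predictions were made."""
    if tp + fp == 0:
        logger.debug("precision undefined (no positive predictions); using 0")
        return 0.0
    return tp / (tp + fp)


def recall_score(tp: int, fn: int, tn: int, fp: int) -> float:
    if tp + fn == 0:
        raise ValueError("recall undefined: no positive-class truths")
    return tp / (tp + fn)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperGrid:
    """The hyperparameter grid searched during selection.

    CSP components 1-4 and shrinkage over [1e-3, 1e-1]; SVC kernel linear or
    radial with C over [1e-5, 1e1].  The radial bandwidth uses the solver's
    variance-scaled default (sklearn ``gamma='scale'``), recorded in reports.
    """

    csp_components: tuple[int, ...] = (1, 2, 3, 4)
    csp_lambda: tuple[float, ...] = (1e-3, 1e-2, 1e-1)
    kernel: tuple[str, ...] = ("linear", "rbf")
    C: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0)

    def __post_init__(self):
        if not (self.csp_components and self.csp_lambda and self.kernel
                and self.C):
            raise ValueError("all grid axes must be non-empty")
        if any(l < csp.MIN_LAMBDA for l in self.csp_lambda):
            raise ValueError(f"csp_lambda below {csp.MIN_LAMBDA} is unstable "
                             "for rank-deficient window covariances")

    def points(self, kind: str) -> list[dict]:
        """Grid points ordered so the selection tie-break (fewer components,
        smaller C, linear kernel first) is the iteration order."""
        kernels = sorted(self.kernel, key=lambda s: s != "linear")
        if kind == "direct":
            return [{"kind": kind, "kernel": kern, "C": c}
                    for c in sorted(self.C) for kern in kernels]
        return [{"kind": kind, "m": m, "lam": lam, "kernel": kern, "C": c}
                for m in sorted(self.csp_components)
                for c in sorted(self.C)
                for kern in kernels
                for lam in sorted(self.csp_lambda)]


SMALL_GRID = HyperGrid(csp_components=(2,), csp_lambda=(1e-2,),
                       kernel=("linear",), C=(1.0,))


class ModelData:
    """Subject-level inputs for one model configuration.

    ``kind='csp'``: windowed band matrices (n x channels x samples), with
    per-lambda covariance caching so grid search does not recompute them.
    ``kind='direct'``: a ready feature matrix (n x f), e.g. FCz amplitudes.
    """

    def __init__(self, X: np.ndarray, kind: str):
        if kind not in ("csp", "direct"):
            raise ValueError("kind must be 'csp' or 'direct'")
        self.X = np.asarray(X, dtype=float)
        self.kind = kind
        if kind == "csp" and self.X.ndim != 3:
            raise ValueError("CSP input must be subjects x channels x samples")
        if kind == "direct" and self.X.ndim != 2:
            raise ValueError("direct input must be subjects x features")
        self._covs: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.X)

    def covs(self) -> np.ndarray:
        # raw (unshrunk, non-trace-normalised) covariances: group differences
        # in absolute band power are the signal of interest, not a nuisance
        # scale, and regularisation is applied per training fold via pooled
        # diagonal loading in csp_fit_loaded
        if self._covs is None:
            self._covs = np.stack(
                [csp.subject_covariance(x, 0.0, trace_norm=False)
                 for x in self.X])
        return self._covs


@dataclass
class FittedPipeline:
    params: dict
    csp_model: csp.CSPModel | None
    scaler: StandardScaler
    svc: SVC

    def _features(self, data: ModelData, idx: np.ndarray) -> np.ndarray:
        if self.csp_model is not None:
            return csp.csp_transform_many(self.csp_model, data.X[idx],
                                          normalize=False)
        return data.X[idx]

    def predict(self, data: ModelData, idx: np.ndarray) -> np.ndarray:
        return self.svc.predict(self.scaler.transform(self._features(data, idx)))

    def decision(self, data: ModelData, idx: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(
            self.scaler.transform(self._features(data, idx)))


def fit_pipeline(data: ModelData, y: np.ndarray, train_idx: np.ndarray,
                 params: dict, leak_csp: csp.CSPModel | None = None
                 ) -> FittedPipeline:
    """Fit CSP (training subjects only) + scaler + SVC on one training set.

    ``leak_csp`` deliberately injects a CSP model fitted elsewhere; it exists
    only so tests can demonstrate the inflation caused by fitting CSP outside
    the CV loop.
    """
    y = np.asarray(y).astype(int)
    model = None
    if params["kind"] == "csp":
        if leak_csp is not None:
            model = leak_csp
        else:
            covs = data.covs()[train_idx]
            ytr = y[train_idx]
            model = csp.csp_fit_loaded(covs[ytr == 1], covs[ytr == 0],
                                       lam=params["lam"], m=params["m"])
        feats = csp.csp_transform_many(model, data.X[train_idx],
                                       normalize=False)
    else:
        feats = data.X[train_idx]
    scaler = StandardScaler().fit(feats)
    svc = SVC(kernel=params["kernel"], C=params["C"], gamma="scale")
    svc.fit(scaler.transform(feats), y[train_idx])
    return FittedPipeline(params=params, csp_model=model, scaler=scaler,
                          svc=svc)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Per-split scores of one model configuration."""

    scores: dict[str, np.ndarray]  # metric -> r*k values
    r: int
    k: int
    seed: int
    params: dict
    train_acc: float | None = None
    notes: list[str] = field(default_factory=list)

    def mean(self, metric: str = "balanced_accuracy") -> float:
        return float(self.scores[metric].mean())


def _effective_k(y: np.ndarray, k: int, notes: list[str]) -> int:
    smallest = int(np.bincount(np.asarray(y).astype(int)).min())
    if smallest < 2:
        raise ValueError("stratified CV needs >= 2 subjects per class")
    if smallest < k:
        notes.append(f"k reduced from {k} to {smallest} (smallest class)")
        logger.warning("class smaller than k=%d; using k=%d", k, smallest)
        return smallest
    return k


def _split_seeds(seed: int, r: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(r)]


def cv_scores(data: ModelData, y: np.ndarray, params: dict,
              r: int, k: int, seed: int,
              leak_csp: csp.CSPModel | None = None) -> CVReport:
    """r repeats of stratified k-fold CV, full pipeline refit per split."""
    y = np.asarray(y).astype(int)
    notes: list[str] = []
    k_eff = _effective_k(y, k, notes)
    seeds = _split_seeds(seed, r)
    metrics = {m: [] for m in ("balanced_accuracy", "roc_auc",
                               "precision", "recall")}
    for rs in seeds:
        skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=rs)
        for tr, te in skf.split(np.zeros(len(y)), y):
            pipe = fit_pipeline(data, y, tr, params, leak_csp=leak_csp)
            pred = pipe.predict(data, te)
            dec = pipe.decision(data, te)
            tp, fn, tn, fp = confusion_counts(y[te], pred)
            metrics["balanced_accuracy"].append(
                balanced_accuracy_from_counts(tp, fn, tn, fp))
            metrics["roc_auc"].append(roc_auc(dec, y[te]))
            metrics["precision"].append(precision_score(tp, fn, tn, fp))
            metrics["recall"].append(recall_score(tp, fn, tn, fp))
    return CVReport(scores={m: np.array(v) for m, v in metrics.items()},
                    r=r, k=k_eff, seed=seed, params=params, notes=notes)


def fit_select(data: ModelData, y: np.ndarray,
               grid: HyperGrid = HyperGrid(), k: int = 3,
               seed: int = 0) -> tuple[dict, CVReport]:
    """Grid selection by mean threefold-CV balanced accuracy.

    All grid points are scored on identical splits; the first point (in
    tie-break order: fewer CSP components, smaller C, linear kernel) of the
    best mean wins.  Returns the winning params and its selection report.
    """
    y = np.asarray(y).astype(int)
    best_params, best_report, best_score = None, None, -np.inf
    for params in grid.points(data.kind):
        report = cv_scores(data, y, params, r=1, k=k, seed=seed)
        score = report.mean("balanced_accuracy")
        if score > best_score + 1e-12:
            best_params, best_report, best_score = params, report, score
    assert best_params is not None
    return best_params, best_report


def repeated_cv_score(data: ModelData, y: np.ndarray, params: dict,
                      r: int = 10, k: int = 10, seed: int = 0) -> CVReport:
    """10x10 (by default) repeated stratified CV of a fixed configuration.

    Also reports ``train_acc``: balanced accuracy of the pipeline refit and
    scored on the full dataset, a deliberately optimistic overfitting gauge.
    """
    report = cv_scores(data, y, params, r=r, k=k, seed=seed)
    full = np.arange(len(y))
    pipe = fit_pipeline(data, y, full, params)
    report.train_acc = balanced_accuracy(y, pipe.predict(data, full))
    return report


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    t: float
    df: int
    p: float
    mean_diff: float
    rho: float
    flag: str | None = None


def corrected_paired_ttest(scores_a: np.ndarray, scores_b: np.ndarray,
                           k: int, r: int,
                           train_frac: float | None = None
                           ) -> ComparisonResult:
    """Nadeau-Bengio corrected resampled t-test on paired CV scores.

    t = mean(d) / sqrt((1/(r k) + rho) var(d)) with rho = n_test / n_train
    (1/(k-1) for k-fold CV), var the unbiased sample variance, and a
    two-sided p from Student's t with r*k - 1 degrees of freedom.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must share one shape")
    n = a.size
    if n != r * k:
        raise ValueError(f"{n} scores but r*k = {r * k}")
    rho = (1.0 - train_frac) / train_frac if train_frac is not None \
        else 1.0 / (k - 1)
    d = a - b
    mean = float(d.mean())
    var = float(d.var(ddof=1))
    df = n - 1
    if var == 0.0:
        if mean == 0.0:
            return ComparisonResult(t=0.0, df=df, p=1.0, mean_diff=0.0,
                                    rho=rho)
        return ComparisonResult(t=float(np.sign(mean)) * np.inf, df=df,
                                p=0.0, mean_diff=mean, rho=rho,
                                flag="zero variance, nonzero mean")
    t = mean / np.sqrt((1.0 / n + rho) * var)
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return ComparisonResult(t=float(t), df=df, p=p, mean_diff=mean, rho=rho)


@dataclass
class PermutationResult:
    observed: float
    perm_scores: np.ndarray
    p: float
    seed: int
    B: int


def permutation_test(data: ModelData, y: np.ndarray,
                     grid: HyperGrid | None = None,
                     params: dict | None = None,
                     B: int = DEFAULT_B, seed: int = 0,
                     k: int = 3, r: int = 1,
                     alpha: float = 0.05) -> PermutationResult:
    """Label-permutation significance of the cross-validated score.

    The full procedure — hyperparameter selection (when ``grid`` is given)
    followed by r x k-fold CV scoring — is re-run on each of B permuted label
    vectors; p = (1 + #{perm >= observed}) / (B + 1).  With ``params`` given
    and no grid, the configuration is held fixed.
    """
    if B < 99:
        raise ValueError("B >= 99 required for a usable permutation p-value")
    if 1.0 / (B + 1) > alpha:
        logger.warning("B=%d cannot resolve p below alpha=%.3f", B, alpha)
    y = np.asarray(y).astype(int)

    def score(labels: np.ndarray, split_seed: int) -> float:
        if grid is not None:
            chosen, _ = fit_select(data, labels, grid, k=k, seed=split_seed)
        else:
            if params is None:
                raise ValueError("need either grid or params")
            chosen = params
        return cv_scores(data, labels, chosen, r=r, k=k,
                         seed=split_seed).mean("balanced_accuracy")

    observed = score(y, seed)
    rng = np.random.default_rng(seed)
    perm_scores = np.empty(B)
    for b in range(B):
        perm_scores[b] = score(rng.permutation(y), seed)
    p = (1.0 + np.sum(perm_scores >= observed)) / (B + 1.0)
    return PermutationResult(observed=float(observed),
                             perm_scores=perm_scores, p=float(p),
                             seed=seed, B=B)


# ---------------------------------------------------------------------------
# end-to-end model runs
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    component: str
    valence: str
    contrast: str
    params: dict
    selection: CVReport
    cv: CVReport
    permutation: PermutationResult
    csp_model: csp.CSPModel | None
    subject_ids: list[str]
    excluded: list[str]

    def table_row(self) -> dict:
        """One Table-2-shaped summary row."""
        return {
            "component": self.component,
            "valence": self.valence,
            "contrast": self.contrast,
            "train_acc": round(self.cv.train_acc, 3),
            "acc": round(self.cv.mean("balanced_accuracy"), 3),
            "p_acc": round(self.permutation.p, 4),
            "roc_auc": round(self.cv.mean("roc_auc"), 3),
            "recall": round(self.cv.mean("recall"), 3),
            "precision": round(self.cv.mean("precision"), 3),
            "n_components": self.params.get("m", ""),
            "csp_lambda": self.params.get("lam", ""),
            "kernel": self.params["kernel"],
            "C": self.params["C"],
        }


def prepare_model_data(epochsets: Sequence[EpochSet],
                       metas: Sequence[SubjectMeta],
                       component: str, valence: str, contrast: str,
                       cutoffs: Cutoffs = Cutoffs(),
                       window: bs.AnalysisWindow = bs.AnalysisWindow(),
                       erp_channel: str = "FCz"
                       ) -> tuple[ModelData, np.ndarray, list[str], list[str]]:
    """Subject ERPs -> model inputs for one component/valence/contrast.

    Epochs are baseline-corrected and averaged per valence; delta/theta
    components are band-filtered on the full-length ERP and then windowed;
    the erp component is the single FCz mean amplitude.  Subjects with fewer
    than five trials of the requested valence are excluded and reported.
    """
    if component not in COMPONENTS:
        raise ValueError(f"component must be one of {COMPONENTS}")
    labels = dict(select_contrast(assign_groups(metas, cutoffs), contrast))
    by_id = {e.subject_id: e for e in epochsets}
    xs, ys, kept, excluded = [], [], [], []
    for sid, label in labels.items():
        if sid not in by_id:
            excluded.append(sid)
            logger.warning("subject %s in metadata but has no epochs", sid)
            continue
        try:
            erps = bs.average_by_condition(bs.baseline_correct(by_id[sid]))
        except bs.InsufficientTrialsError as err:
            excluded.append(sid)
            logger.warning("excluding %s: %s", sid, err)
            continue
        erp = erps[valence]
        if component == "erp":
            xs.append([bs.erp_amplitude_feature(erp, erp_channel, window)])
        else:
            spec = bs.delta_spec(erp.srate) if component == "delta" \
                else bs.theta_spec(erp.srate)
            xs.append(bs.extract_window(bs.apply_filter(erp, spec), window))
        ys.append(label)
        kept.append(sid)
    kind = "direct" if component == "erp" else "csp"
    return ModelData(np.stack(xs), kind), np.array(ys), kept, excluded


def run_model(epochsets: Sequence[EpochSet], metas: Sequence[SubjectMeta],
              component: str, valence: str, contrast: str,
              cutoffs: Cutoffs = Cutoffs(),
              grid: HyperGrid = HyperGrid(),
              r: int = 10, k: int = 10, B: int = DEFAULT_B,
              select_k: int = 3, seed: int = 0,
              window: bs.AnalysisWindow = bs.AnalysisWindow()) -> ModelResult:
    """Full evaluation of one component x valence x contrast cell."""
    data, y, kept, excluded = prepare_model_data(
        epochsets, metas, component, valence, contrast, cutoffs, window)
    params, selection = fit_select(data, y, grid, k=select_k, seed=seed)
    cv = repeated_cv_score(data, y, params, r=r, k=k, seed=seed)
    perm = permutation_test(data, y, grid=None, params=params, B=B,
                            seed=seed, k=select_k, r=1)
    model = None
    if data.kind == "csp":
        pipe = fit_pipeline(data, y, np.arange(len(y)), params)
        model = pipe.csp_model
        model.meta = {"component": component, "valence": valence,
                      "contrast": contrast}
    return ModelResult(component=component, valence=valence,
                       contrast=contrast, params=params, selection=selection,
                       cv=cv, permutation=perm, csp_model=model,
                       subject_ids=kept, excluded=excluded)


def compare_models(res_a: ModelResult, res_b: ModelResult,
                   metric: str = "balanced_accuracy") -> ComparisonResult:
    """Paired corrected t-test between two models' repeated-CV scores.

    Both models must have been scored with the same seed and fold layout so
    the score vectors are paired split-by-split.
    """
    a, b = res_a.cv, res_b.cv
    if (a.r, a.k, a.seed) != (b.r, b.k, b.seed):
        raise ValueError("models were not scored on identical splits")
    return corrected_paired_ttest(a.scores[metric], b.scores[metric],
                                  k=a.k, r=a.r)


def leakage_comparison(data: ModelData, y: np.ndarray, params: dict,
                       r: int = 10, k: int = 10,
                       seed: int = 0) -> tuple[float, float]:
    """Mean CV balanced accuracy with CSP fit inside vs outside the folds.

    The "leaky" variant fits CSP once on all subjects and only cross-validates
    the classifier — the classic information leak this module's contracts
    forbid.  Returns (leaky_mean, clean_mean).
    """
    y = np.asarray(y).astype(int)
    clean = cv_scores(data, y, params, r=r, k=k, seed=seed)
    covs = data.covs()
    leak_model = csp.csp_fit_loaded(covs[y == 1], covs[y == 0],
                                    lam=params["lam"], m=params["m"])
    leaky = cv_scores(data, y, params, r=r, k=k, seed=seed,
                      leak_csp=leak_model)
    return leaky.mean("balanced_accuracy"), clean.mean("balanced_accuracy")


def enumerate_configs(components: Sequence[str] = COMPONENTS,
                      valences: Sequence[str] = ("positive", "negative"),
                      contrasts: Sequence[str] = ("depression", "anxiety")
                      ) -> list[tuple[str, str, str]]:
    """The component x valence x contrast grid (12 cells by default)."""
    return list(itertools.product(components, valences, contrasts))
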
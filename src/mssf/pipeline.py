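"""Cross-validation protocols, training orchestration, metrics and the
KDE-based regression-to-class conversion.

Three evaluation protocols are supported:

* ``pairwise``    — the known (drug, side effect) pairs are shuffled and
  dealt into k near-equal folds; by default the frequency-profile
  similarities (DIPA/DIPF) are recomputed per fold from training
  entries only, so the test fold never leaks into the features;
* ``cold_drug``   — the *drugs* are partitioned into k folds; a fold's
  test pairs are all known pairs of its drugs, and the DSA-derived
  similarity matrices are removed (9 drug + 2 side-effect remain);
* ``independent`` — train/test drug id lists are supplied explicitly;
  the planner verifies drug-disjointness; the bank is masked.

Eight metrics are reported: accuracy, weighted and macro F1, Cohen's κ,
multiclass MCC, macro precision and recall (zero-division → 0), and
macro one-vs-rest area under the precision-recall curve (trapezoidal).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde, norm
from sklearn import metrics as skm

from . import features, network
from .config import RunConfig
from .similarity import FrequencyMatrix, SimilarityBank, refit_dsa_similarities

logger = logging.getLogger("mssf")

CLASSES = np.arange(1, 6)
METRIC_NAMES = (
    "acc",
    "weighted_f1",
    "macro_f1",
    "kappa",
    "mcc",
    "macro_precision",
    "macro_recall",
    "macro_aupr",
)


# ---------------------------------------------------------------------------
# split planning
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    mode: str                      # pairwise | cold_drug | independent
    k: int
    seed: int
    #: pairwise/cold_drug: list of k arrays of test (drug, se) index pairs
    fold_pairs: list = field(default_factory=list)
    #: cold_drug: list of k arrays of test drug indices
    fold_drugs: list = field(default_factory=list)

    def test_pairs(self, fold: int) -> np.ndarray:
        if not 0 <= fold < self.k:
            raise IndexError(f"fold {fold} out of range for k={self.k}")
        return self.fold_pairs[fold]

    def train_pairs(self, fold: int) -> np.ndarray:
        others = [p for f, p in enumerate(self.fold_pairs) if f != fold]
        return np.concatenate(others) if others else np.empty((0, 2), dtype=int)


def make_pairwise_folds(dsa: FrequencyMatrix, k: int = 10, seed: int = 0) -> SplitPlan:
    """Shuffle the known pairs and deal them into k near-equal folds."""
    if k < 2:
        raise ValueError("k must be at least 2")
    pairs = dsa.known_pairs
    if len(pairs) < k:
        raise ValueError(f"need at least {k} known pairs, have {len(pairs)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    folds = [pairs[idx] for idx in np.array_split(order, k)]
    return SplitPlan("pairwise", k, seed, fold_pairs=folds)


def make_cold_start_folds(dsa: FrequencyMatrix, k: int = 10, seed: int = 0) -> SplitPlan:
    """Partition drugs into k folds; test pairs are the drugs' known pairs."""
    n_drugs = len(dsa.drug_ids)
    if k > n_drugs:
        raise ValueError(f"k={k} exceeds the number of drugs ({n_drugs})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_drugs)
    drug_folds = [np.sort(idx) for idx in np.array_split(order, k)]
    all_pairs = dsa.known_pairs
    fold_pairs = [
        all_pairs[np.isin(all_pairs[:, 0], drugs)] for drugs in drug_folds
    ]
    return SplitPlan("cold_drug", k, seed, fold_pairs=fold_pairs, fold_drugs=drug_folds)


def make_independent_split(
    dsa: FrequencyMatrix, train_drug_ids: list, test_drug_ids: list, seed: int = 0
) -> SplitPlan:
    """Train/test split from explicit drug id lists (verified disjoint)."""
    overlap = set(train_drug_ids) & set(test_drug_ids)
    if overlap:
        raise ValueError(f"train and test drug sets overlap: {sorted(overlap)[:5]}")
    index = {d: i for i, d in enumerate(dsa.drug_ids)}
    missing = [d for d in (*train_drug_ids, *test_drug_ids) if d not in index]
    if missing:
        raise ValueError(f"unknown drug ids: {missing[:5]}")
    tr = np.sort([index[d] for d in train_drug_ids])
    te = np.sort([index[d] for d in test_drug_ids])
    pairs = dsa.known_pairs
    fold_pairs = [
        pairs[np.isin(pairs[:, 0], te)],   # fold 0 = test
        pairs[np.isin(pairs[:, 0], tr)],   # fold 1 = train pool
    ]
    return SplitPlan("independent", 2, seed, fold_pairs=fold_pairs, fold_drugs=[te, tr])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _one_hot(classes: np.ndarray) -> np.ndarray:
    out = np.zeros((len(classes), 5))
    out[np.arange(len(classes)), np.asarray(classes) - 1] = 1.0
    return out


def train_model(
    model: network.MSSFModel,
    bank: SimilarityBank,
    train_pairs: np.ndarray,
    train_classes: np.ndarray,
    config: RunConfig,
    rng: np.random.Generator,
) -> dict:
    """Minibatch Adam training with early stopping on a held-out slice.

    A seeded ``val_fraction`` of the training pairs is carved off; the
    classification (BCE) loss on it is monitored and the best parameter
    set is restored when ``patience`` epochs pass without improvement.
    Returns a history dictionary (per-epoch losses).
    """
    n = len(train_pairs)
    n_val = int(round(config.val_fraction * n)) if n >= 10 else 0
    order = rng.permutation(n)
    val_idx, fit_idx = order[:n_val], order[n_val:]

    opt = network.Adam(model.parameters(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state, wait = np.inf, None, 0

    val_batch = None
    if n_val:
        val_batch = features.assemble_batch(bank, train_pairs[val_idx])
        val_onehot = _one_hot(train_classes[val_idx])

    for epoch in range(config.epochs):
        model.train()
        perm = rng.permutation(fit_idx)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            batch = features.assemble_batch(bank, train_pairs[idx])
            out = model(batch, rng)
            loss, _ = network.total_loss(
                out, _one_hot(train_classes[idx]), config, model.parameters()
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        history["train_loss"].append(epoch_loss / max(n_batches, 1))

        if n_val:
            model.eval()
            out = model(val_batch, rng)
            val_loss = network.bce_loss(out["scores"], val_onehot).item()
            history["val_loss"].append(val_loss)
            logger.debug(
                "epoch %d train_loss %.4f val_loss %.4f",
                epoch, history["train_loss"][-1], val_loss,
            )
            if val_loss < best_val - 1e-6:
                best_val, wait = val_loss, 0
                best_state = [a.copy() for a in model.state_arrays()]
            else:
                wait += 1
                if wait >= config.patience:
                    logger.debug("early stop at epoch %d", epoch)
                    break

    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return history


def score_pairs(
    model: network.MSSFModel,
    bank: SimilarityBank,
    pairs: np.ndarray,
    rng: np.random.Generator,
    batch_size: int = 512,
) -> np.ndarray:
    """Five-class sigmoid scores for each pair (evaluation mode, ε = 0)."""
    model.eval()
    chunks = []
    for start in range(0, len(pairs), batch_size):
        batch = features.assemble_batch(bank, pairs[start : start + batch_size])
        chunks.append(model(batch, rng)["scores"].data)
    return np.concatenate(chunks) if chunks else np.empty((0, 5))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _aupr(y_bin: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal area under the precision-recall curve.

    One PR point per distinct score threshold (ties grouped), with the
    conventional (recall 0, precision 1) anchor prepended.
    """
    order = np.argsort(-scores, kind="mergesort")
    y = y_bin[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    last = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]  # last index per threshold
    pos = y_bin.sum()
    precision = tp[last] / (tp[last] + fp[last])
    recall = tp[last] / pos
    precision = np.r_[1.0, precision]
    recall = np.r_[0.0, recall]
    return float(np.trapezoid(precision, recall))


def compute_metrics(true_classes: np.ndarray, score_matrix: np.ndarray) -> dict:
    """The eight-metric report from per-pair five-class scores."""
    true_classes = np.asarray(true_classes)
    score_matrix = np.asarray(score_matrix)
    if len(true_classes) != len(score_matrix):
        raise ValueError("true classes and scores have different lengths")
    if not np.isfinite(score_matrix).all():
        raise ValueError("scores must be finite")
    preds = np.argmax(score_matrix, axis=1) + 1  # argmax ties break low

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = {
            "acc": skm.accuracy_score(true_classes, preds),
            "weighted_f1": skm.f1_score(
                true_classes, preds, labels=CLASSES, average="weighted", zero_division=0
            ),
            "macro_f1": skm.f1_score(
                true_classes, preds, labels=CLASSES, average="macro", zero_division=0
            ),
            "kappa": skm.cohen_kappa_score(true_classes, preds, labels=CLASSES),
            "mcc": skm.matthews_corrcoef(true_classes, preds),
            "macro_precision": skm.precision_score(
                true_classes, preds, labels=CLASSES, average="macro", zero_division=0
            ),
            "macro_recall": skm.recall_score(
                true_classes, preds, labels=CLASSES, average="macro", zero_division=0
            ),
        }

    auprs = []
    for c in CLASSES:
        y_bin = (true_classes == c).astype(int)
        if y_bin.sum() == 0:
            warnings.warn(f"class {c} absent from the test set; skipped in macro AUPR",
                          stacklevel=2)
            continue
        auprs.append(_aupr(y_bin, score_matrix[:, c - 1]))
    report["macro_aupr"] = float(np.mean(auprs)) if auprs else 0.0
    return {k: float(report[k]) for k in METRIC_NAMES}


# ---------------------------------------------------------------------------
# fold execution
# ---------------------------------------------------------------------------


def prepare_fold_bank(
    bank: SimilarityBank,
    dsa: FrequencyMatrix,
    plan: SplitPlan,
    fold: int,
    config: RunConfig,
) -> SimilarityBank:
    """The similarity bank a fold trains on.

    Cold-start and independent folds mask the DSA-derived matrices;
    pairwise folds refit them from training entries only (leakage
    control, switchable via ``config.refit_dsa``).
    """
    if plan.mode in ("cold_drug", "independent"):
        return bank.apply_mask()
    if config.refit_dsa and not bank.masked:
        return refit_dsa_similarities(bank, dsa.mask_pairs(plan.test_pairs(fold)))
    return bank


def run_fold(
    bank: SimilarityBank,
    dsa: FrequencyMatrix,
    plan: SplitPlan,
    fold: int,
    config: RunConfig,
) -> tuple:
    """Train on a fold's training pairs and score its test pairs.

    Cold-start and independent folds use the masked bank (9 + 2
    matrices); pairwise folds recompute the DSA-derived similarities
    from training entries when ``config.refit_dsa`` is set.  Returns
    (metrics dict, test pairs, test score matrix).
    """
    test_pairs = plan.test_pairs(fold)
    train_pairs = plan.train_pairs(fold)
    train_classes = dsa.values[train_pairs[:, 0], train_pairs[:, 1]]
    test_classes = dsa.values[test_pairs[:, 0], test_pairs[:, 1]]

    present = set(np.unique(train_classes))
    absent = [int(c) for c in CLASSES if c not in present]
    if absent:
        warnings.warn(f"classes {absent} absent from training; still scored",
                      stacklevel=2)

    fold_bank = prepare_fold_bank(bank, dsa, plan, fold, config)

    seed = (config.seed * 100003 + fold * 7919) % (2**31 - 1)
    rng = np.random.default_rng(seed)
    model = network.MSSFModel(
        len(dsa.drug_ids), len(dsa.se_ids),
        fold_bank.n_drug_matrices, fold_bank.n_se_matrices,
        config, rng,
    )
    train_model(model, fold_bank, train_pairs, train_classes, config, rng)
    scores = score_pairs(model, fold_bank, test_pairs, rng)
    report = compute_metrics(test_classes, scores)
    logger.info("fold %d (%s): acc=%.4f kappa=%.4f", fold, plan.mode,
                report["acc"], report["kappa"])
    return report, test_pairs, scores


def cross_validate(
    bank: SimilarityBank, dsa: FrequencyMatrix, config: RunConfig, folds=None
) -> list:
    """Run the configured protocol over all (or selected) folds."""
    if config.mode == "pairwise":
        plan = make_pairwise_folds(dsa, config.k, config.seed)
    elif config.mode == "cold_drug":
        plan = make_cold_start_folds(dsa, config.k, config.seed)
    else:
        raise ValueError("independent mode needs make_independent_split + run_fold")
    fold_ids = range(plan.k) if folds is None else folds
    return [run_fold(bank, dsa, plan, f, config) for f in fold_ids]


# ---------------------------------------------------------------------------
# KDE regression-to-class conversion
# ---------------------------------------------------------------------------


class KDEClassifier:
    """Maximum-likelihood class assignment for continuous scores.

    One Gaussian kernel density (Scott bandwidth) is fitted per class on
    the training scores of regression baselines; a new score is assigned
    the class with the highest density (ties → lower class).  Classes
    absent from training are never predicted.  A class whose scores are
    (nearly) degenerate falls back to a Gaussian at the class mean with
    a small fixed bandwidth (0.05).
    """

    FALLBACK_BW = 0.05

    def __init__(self, use_priors: bool = False):
        self.use_priors = use_priors
        self.densities: dict = {}
        self.priors: dict = {}

    def fit(self, scores: np.ndarray, classes: np.ndarray) -> "KDEClassifier":
        scores = np.asarray(scores, dtype=float)
        classes = np.asarray(classes)
        if len(scores) < 2:
            raise ValueError("need at least two training scores")
        for c in np.unique(classes):
            vals = scores[classes == c]
            self.priors[int(c)] = len(vals) / len(scores)
            if len(np.unique(vals)) < 2:
                warnings.warn(
                    f"class {c}: degenerate scores; Gaussian fallback", stacklevel=2
                )
                loc = float(vals.mean())
                self.densities[int(c)] = norm(loc=loc, scale=self.FALLBACK_BW).pdf
            else:
                self.densities[int(c)] = gaussian_kde(vals, bw_method="scott")
        return self

    def density_matrix(self, x: np.ndarray) -> tuple:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        cls = sorted(self.densities)
        dens = np.stack([np.asarray(self.densities[c](x)) for c in cls], axis=1)
        if self.use_priors:
            dens = dens * np.array([self.priors[c] for c in cls])
        return np.array(cls), dens

    def predict(self, x) -> np.ndarray:
        cls, dens = self.density_matrix(x)
        return cls[np.argmax(dens, axis=1)]  # argmax ties break to lower class


def fit_kde_classifier(
    train_scores, train_classes, use_priors: bool = False
) -> KDEClassifier:
    return KDEClassifier(use_priors=use_priors).fit(
        np.asarray(train_scores), np.asarray(train_classes)
    )


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

#: the published search ranges
GRID_RANGES = {
    "learning_rate": [1e-3, 5e-4, 1e-4, 5e-5, 1e-5],
    "dropout": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
    "batch_size": [32, 64, 128, 256],
    "d": [16, 32, 64, 128, 256],
    "gamma": [1e-1, 1e-2, 1e-3, 1e-4, 1e-5],
}


def grid_search(
    config_space: dict,
    dsa: FrequencyMatrix,
    bank: SimilarityBank,
    base_config: RunConfig,
    k: int = 10,
    seed: int = 0,
) -> tuple:
    """Exhaustive search over a finite grid by k-fold CV mean accuracy.

    Returns (best config, table); the table has one row per combination
    with its parameter values and mean accuracy.
    """
    if not config_space or any(len(v) == 0 for v in config_space.values()):
        raise ValueError("empty grid")
    keys = sorted(config_space)
    table = []
    best = None
    for combo in itertools.product(*(config_space[k_] for k_ in keys)):
        overrides = dict(zip(keys, combo))
        cfg = base_config.replace(seed=seed, k=k, **overrides)
        results = cross_validate(bank, dsa, cfg)
        mean_acc = float(np.mean([r[0]["acc"] for r in results]))
        row = {**overrides, "mean_acc": mean_acc}
        table.append(row)
        if best is None or mean_acc > best[1]["mean_acc"]:
            best = (cfg, row)
    return best[0], table
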
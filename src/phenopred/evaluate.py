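"""Cross-validation, prediction accuracy, selection accuracy and population
structure summaries.

Two cross-validation schemes: *random* (repeated 80/20 splits of the hybrid
population, 200 runs by default) and *familywise* (each of the subfamilies
serves as the test set exactly once, training on the remaining families).
Prediction accuracy is the Pearson correlation between adjusted means and
predictions on the masked test set; selection accuracy compares the top-k
sets chosen by predicted versus observed performance through the
Czekanowski similarity CZ = 2a / (2a + b + c).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EvaluationResult

__all__ = [
    "CVScheme",
    "make_splits",
    "run_cv",
    "pearson_accuracy",
    "select_top_k",
    "SelectionOutcome",
    "classify_selection",
    "selection_accuracy",
    "czekanowski",
    "pca_structure",
]


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation layout.

    ``random``: ``n_runs`` independent splits with ``floor(train_fraction*n)``
    training individuals.  ``familywise``: one fold per family label, ignoring
    ``n_runs``/``train_fraction``.
    """

    kind: str = "random"
    n_runs: int = 200
    train_fraction: float = 0.8
    families: pd.Series | None = None  # per-individual family labels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random", "familywise"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "familywise" and self.families is None:
            raise ValueError("familywise scheme needs family labels")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train fraction must be in (0, 1)")


def make_splits(ids: list[str], scheme: CVScheme) -> list[tuple[list[str], list[str]]]:
    """Reproducible (train, test) id splits under the scheme's master seed."""
    ids = list(ids)
    if scheme.kind == "random":
        rng = np.random.default_rng(scheme.seed)
        n_train = int(np.floor(scheme.train_fraction * len(ids)))
        splits = []
        for _ in range(scheme.n_runs):
            perm = rng.permutation(len(ids))
            train = [ids[i] for i in sorted(perm[:n_train])]
            test = [ids[i] for i in sorted(perm[n_train:])]
            splits.append((train, test))
        return splits
    fam = scheme.families
    missing = [i for i in ids if i not in fam.index]
    if missing:
        raise ValueError(f"family label missing for: {missing[:5]}")
    labels = fam.loc[ids]
    splits = []
    for family in sorted(labels.unique()):
        test = [i for i in ids if labels[i] == family]
        train = [i for i in ids if labels[i] != family]
        splits.append((train, test))
    return splits


def pearson_accuracy(observed, predicted) -> float:
    """Pearson r between observed and predicted values on a test set.

    Returns NaN (missing, not zero) when either vector has no variance.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.size != pred.size:
        raise ValueError("observed and predicted lengths differ")
    if obs.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("non-finite values in accuracy computation")
    if obs.std() == 0 or pred.std() == 0:
        return float("nan")
    return float(stats.pearsonr(obs, pred).statistic)


#: fitter signature: (training values indexed by id, test ids) -> predictions
Fitter = Callable[[pd.Series, list[str]], np.ndarray]


def run_cv(
    fitters: dict[str, Fitter] | dict[tuple[str, str], Fitter],
    adjusted: pd.Series | pd.DataFrame,
    scheme: CVScheme,
) -> EvaluationResult:
    """Run every model over every split; collect accuracies and predictions.

    ``fitters`` maps a model tag — either ``name`` or ``(model,
    predictor_set)`` — to a callable that trains on the supplied values
    (hyperparameter tuning included, inside the training split) and predicts
    the masked test ids.  ``adjusted`` holds per-genotype adjusted means, one
    column per trait.
    """
    if isinstance(adjusted, pd.Series):
        adjusted = adjusted.to_frame()
    ids = list(adjusted.index)
    splits = make_splits(ids, scheme)
    acc_rows = []
    pred_sum = {key: pd.Series(0.0, index=ids) for key in fitters}
    pred_cnt = {key: pd.Series(0, index=ids) for key in fitters}
    for run, (train, test) in enumerate(splits):
        for trait in adjusted.columns:
            y_train = adjusted.loc[train, trait]
            y_test = adjusted.loc[test, trait]
            for key, fitter in fitters.items():
                pred = np.asarray(fitter(y_train, list(test)), float)
                if pred.shape != (len(test),):
                    raise ValueError(f"fitter {key!r} returned a misshaped prediction")
                model, pset = key if isinstance(key, tuple) else (key, "")
                acc_rows.append(
                    {
                        "run": run,
                        "model": model,
                        "predictor_set": pset,
                        "trait": trait,
                        "r": pearson_accuracy(y_test.to_numpy(), pred),
                    }
                )
                pred_sum[key].loc[test] += pred
                pred_cnt[key].loc[test] += 1
    mean_rows = []
    for key in fitters:
        model, pset = key if isinstance(key, tuple) else (key, "")
        cnt = pred_cnt[key]
        mean = pred_sum[key] / cnt.replace(0, np.nan)
        for gid in ids:
            if cnt[gid] > 0:
                mean_rows.append(
                    {
                        "genotype": gid,
                        "model": model,
                        "predictor_set": pset,
                        "prediction": mean[gid],
                        "n_runs": int(cnt[gid]),
                    }
                )
    return EvaluationResult(
        accuracies=pd.DataFrame(acc_rows),
        mean_predictions=pd.DataFrame(mean_rows),
        scheme=scheme.kind,
    )


def select_top_k(values: pd.Series, k: int) -> set[str]:
    """Ids of the ``k`` largest values; ties broken by lexicographic id."""
    if k <= 0:
        raise ValueError("selection size must be positive")
    if k > len(values):
        raise ValueError("selection size exceeds population size")
    order = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    return {gid for gid, _ in order[:k]}


@dataclass(frozen=True)
class SelectionOutcome:
    """Counts of the four selection categories plus CZ.

    a: correctly selected, b: wrongly selected, c: wrongly discarded,
    d: correctly discarded.  With fixed-size selections b = c and
    CZ = a / k.
    """

    k: int
    a: int
    b: int
    c: int
    d: int
    cz: float

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def percentages(self) -> dict[str, float]:
        return {
            "correctly_selected": 100.0 * self.a / self.n,
            "wrongly_selected": 100.0 * self.b / self.n,
            "wrongly_discarded": 100.0 * self.c / self.n,
            "correctly_discarded": 100.0 * self.d / self.n,
        }


def czekanowski(a: int, b: int, c: int) -> float:
    """Czekanowski similarity CZ = 2a / (2a + b + c)."""
    if min(a, b, c) < 0:
        raise ValueError("category counts must be non-negative")
    denom = 2 * a + b + c
    if denom == 0:
        raise ValueError("CZ undefined for all-zero counts")
    return 2.0 * a / denom


def classify_selection(
    predicted_top: set[str], actual_top: set[str], all_ids: list[str]
) -> SelectionOutcome:
    """Partition the population into the four selection categories."""
    if len(predicted_top) != len(actual_top):
        raise ValueError("predicted and actual selections must have equal size")
    universe = set(all_ids)
    if not (predicted_top <= universe and actual_top <= universe):
        raise ValueError("selection sets contain unknown ids")
    a = len(predicted_top & actual_top)
    b = len(predicted_top - actual_top)
    c = len(actual_top - predicted_top)
    d = len(universe) - a - b - c
    return SelectionOutcome(
        k=len(predicted_top), a=a, b=b, c=c, d=d, cz=czekanowski(a, b, c)
    )


def selection_accuracy(
    observed: pd.Series, predicted: pd.Series, k: int
) -> SelectionOutcome:
    """Top-k selection on predictions vs. on observed adjusted means."""
    common = observed.index.intersection(predicted.index)
    obs, pred = observed.loc[common], predicted.loc[common]
    return classify_selection(
        select_top_k(pred, k), select_top_k(obs, k), list(common)
    )


def pca_structure(
    matrix: np.ndarray | pd.DataFrame, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centred PCA of dosages or adjusted spectra.

    Returns per-individual scores for the leading components and the
    explained-variance fractions (non-increasing).
    """
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index)
        X = matrix.to_numpy(float)
    else:
        X = np.asarray(matrix, float)
        ids = [str(i) for i in range(X.shape[0])]
    if X.shape[0] < n_components:
        raise ValueError("fewer individuals than requested components")
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return (
        pd.DataFrame(scores, index=ids, columns=[f"PC{i + 1}" for i in range(n_components)]),
        pca.explained_variance_ratio_,
    )
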
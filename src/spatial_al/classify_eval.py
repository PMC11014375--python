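"""Random-forest classification scenarios and thematic accuracy metrics.

The evaluation protocol compares four ways of building the training set:

1. all available training samples;
2. the samples selected by spectral-only active learning;
3. the samples selected by spatially explicit active learning;
4. a uniform random draw of the same size as scenario 3 (redrawn each
   repeat), the matched-size baseline that isolates the value of informed
   selection.

Each scenario trains ``n_repeats`` random forests with distinct seeds and
reports mean overall accuracy (OA), Cohen's Kappa and per-class user's
(UA, precision on predictions) and producer's (PA, recall on reference)
accuracies on a parcel-disjoint test set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .samples_io import SampleSet
from .active_learning import ALResult


@dataclass
class RFConfig:
    """Final-classifier configuration: ``ntree`` trees, ``mtry`` features
    per split (default ⌊√p⌋) and ``n_repeats`` independently seeded fits
    whose metrics are averaged."""

    ntree: int = 1000
    mtry: int | None = None  # default floor(sqrt(n_features))
    n_repeats: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def resolved_mtry(self, n_features: int) -> int:
        m = self.mtry if self.mtry is not None else int(math.isqrt(n_features))
        if not (1 <= m <= n_features):
            raise ValueError(f"mtry={m} outside 1..{n_features}")
        return m


def train_classifier(
    labeled: SampleSet, config: RFConfig, repeat_index: int = 0
) -> RandomForestClassifier:
    """One random forest fit on the labeled samples, seeded by
    (config.seed, repeat_index); out-of-bag accuracy is retrievable via
    ``model.oob_score_``."""
    if len(labeled.classes()) < 2:
        raise ValueError("training set must contain at least 2 classes")
    X = labeled.feature_matrix()
    y = labeled.labels()
    seed = int(np.random.default_rng((config.seed, repeat_index)).integers(2**31))
    model = RandomForestClassifier(
        n_estimators=config.ntree,
        max_features=config.resolved_mtry(X.shape[1]),
        bootstrap=True,
        oob_score=True,
        random_state=seed,
    )
    model.fit(X, y)
    return model


@dataclass
class ConfusionMatrix:
    """K×K counts with rows = predicted class, columns = reference class."""

    classes: tuple
    counts: np.ndarray

    def __post_init__(self):
        self.classes = tuple(self.classes)
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise ValueError("counts must be a K×K non-negative matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def evaluate(model, test: SampleSet) -> ConfusionMatrix:
    """Confusion matrix of a trained model on a labeled test set."""
    if not len(test):
        raise ValueError("test set is empty")
    y_true = test.labels()
    y_pred = model.predict(test.feature_matrix())
    classes = tuple(sorted(set(y_true) | set(y_pred)))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, t in zip(y_pred, y_true):
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(classes, counts)


def metrics(cm: ConfusionMatrix) -> dict:
    """OA, Kappa and per-class UA/PA of a confusion matrix.

    OA = trace/total; UA_k = diag_k / row-sum_k (precision on predicted
    class k); PA_k = diag_k / column-sum_k (recall on reference class k);
    Kappa = (p_o − p_e)/(1 − p_e) with p_e = Σ_k row_k·col_k / total².
    A class with an empty row (never predicted) or column (absent from the
    reference) gets NaN for the corresponding rate and is excluded from any
    averaging done by callers.
    """
    total = cm.total
    if total == 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    oa = diag.sum() / total
    p_e = float(np.sum(rows * cols)) / total**2
    kappa = (oa - p_e) / (1 - p_e) if p_e < 1 else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(rows > 0, diag / np.where(rows > 0, rows, 1), np.nan)
        pa = np.where(cols > 0, diag / np.where(cols > 0, cols, 1), np.nan)
    return {
        "oa": float(oa),
        "kappa": float(kappa),
        "ua": {c: float(v) for c, v in zip(cm.classes, ua)},
        "pa": {c: float(v) for c, v in zip(cm.classes, pa)},
    }


@dataclass
class ScenarioResult:
    name: str
    n_samples: int
    mean_oa: float
    mean_kappa: float
    mean_ua: dict
    mean_pa: dict
    per_repeat_oa: list
    per_repeat_kappa: list
    class_counts: dict  # training samples per class


@dataclass
class ScenarioReport:
    """Mean metrics per scenario plus per-class selected-sample counts."""

    scenarios: list

    def summary_frame(self) -> pd.DataFrame:
        """Rows (scenario, n samples, Kappa, OA%) — the headline table."""
        return pd.DataFrame(
            {
                "scenario": [s.name for s in self.scenarios],
                "n_samples": [s.n_samples for s in self.scenarios],
                "kappa": [round(s.mean_kappa, 2) for s in self.scenarios],
                "overall_accuracy_pct": [round(100 * s.mean_oa) for s in self.scenarios],
            }
        )

    def class_count_frame(self) -> pd.DataFrame:
        """Per-class training-sample counts per scenario, with a Total row.

        This is the selection-bookkeeping table: for the AL scenarios the
        column sums must reproduce the scenario's total sample count.
        """
        classes = sorted({c for s in self.scenarios for c in s.class_counts})
        data = {
            s.name: [s.class_counts.get(c, 0) for c in classes] for s in self.scenarios
        }
        df = pd.DataFrame(data, index=classes)
        df.loc["Total"] = df.sum()
        return df


def class_counts(sample_set: SampleSet) -> dict:
    counts: dict = {}
    for s in sample_set:
        counts[s.label] = counts.get(s.label, 0) + 1
    return counts


def _run_one_scenario(
    name: str,
    train_sets,  # callable repeat_index -> SampleSet, or a fixed SampleSet
    test: SampleSet,
    config: RFConfig,
) -> ScenarioResult:
    oas, kappas, uas, pas = [], [], [], []
    fixed = isinstance(train_sets, SampleSet)
    last_train = None
    for r in range(config.n_repeats):
        train_r = train_sets if fixed else train_sets(r)
        last_train = train_r
        model = train_classifier(train_r, config, repeat_index=r)
        m = metrics(evaluate(model, test))
        oas.append(m["oa"])
        kappas.append(m["kappa"])
        uas.append(m["ua"])
        pas.append(m["pa"])

    def nanmean_over(dicts):
        keys = sorted({k for d in dicts for k in d})
        out = {}
        for k in keys:
            vals = [d[k] for d in dicts if k in d and not math.isnan(d[k])]
            out[k] = float(np.mean(vals)) if vals else float("nan")
        return out

    return ScenarioResult(
        name=name,
        n_samples=len(last_train),
        mean_oa=float(np.mean(oas)),
        mean_kappa=float(np.mean(kappas)),
        mean_ua=nanmean_over(uas),
        mean_pa=nanmean_over(pas),
        per_repeat_oa=oas,
        per_repeat_kappa=kappas,
        class_counts=class_counts(last_train),
    )


def run_scenarios(
    train: SampleSet,
    test: SampleSet,
    spectral_al: ALResult | None,
    spatial_al: ALResult | None,
    config: RFConfig,
) -> ScenarioReport:
    """Run the four training-set scenarios and aggregate their metrics.

    Scenario 4 redraws its random subset (of the scenario-3 size)
    independently on every repeat, so its mean is an average over draws as
    well as over forests.
    """
    scenarios = []
    scenarios.append(_run_one_scenario("scenario_1_all", train, test, config))
    if spectral_al is not None:
        scenarios.append(
            _run_one_scenario(
                "scenario_2_spectral_al", train.subset(spectral_al.labeled_ids), test, config
            )
        )
    if spatial_al is not None:
        n3 = len(spatial_al.labeled_ids)
        if n3 > len(train):
            raise ValueError("spatial AL selection is larger than the training pool")
        scenarios.append(
            _run_one_scenario(
                "scenario_3_spatial_al", train.subset(spatial_al.labeled_ids), test, config
            )
        )
        ids = train.ids

        def random_subset(repeat_index: int) -> SampleSet:
            rng = np.random.default_rng((config.seed, 4, repeat_index))
            chosen = rng.choice(len(ids), size=n3, replace=False)
            return train.subset(ids[i] for i in chosen)

        scenarios.append(_run_one_scenario("scenario_4_random", random_subset, test, config))
    return ScenarioReport(scenarios)
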
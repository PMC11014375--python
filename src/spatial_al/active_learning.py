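"""Pool-based query-by-committee active learning with a spatial filter.

The learner keeps a labeled pool L, an unlabeled pool U and (in the spatial
mode) a discarded pool. Each iteration the committee — C random forests, each
trained on its own bootstrap resample of L — votes on every candidate in U,
candidates are ranked by vote entropy

    VE(x) = −Σ_y (V(y)/C) · ln(V(y)/C),

and the top candidate is queried. In ``spectral`` mode the query is always
accepted. In ``spatial`` mode a queried candidate is accepted only if its
Euclidean distance to *every* member of L is at least the semi-variogram
range threshold; candidates below the threshold are spatially redundant and
are discarded permanently (L only grows, so a once-inadmissible candidate
can never become admissible). Accepted samples receive their oracle label,
join L, and the committee is retrained. The loop stops when the committee's
prediction accuracy plateaus, when U is exhausted, or when no admissible
candidate remains.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier

from .samples_io import SampleSet


@dataclass
class ALConfig:
    """Parameters of the active-learning loop.

    ``range_threshold_m`` (required in spatial mode) is the minimum distance
    selected from the monthly semi-variograms; a queried sample closer than
    this to any labeled sample is considered spatially redundant.
    """

    committee_size: int = 2
    n_initial: int = 40
    mode: str = "spectral"  # or "spatial"
    range_threshold_m: float | None = None
    stop_window: int = 10
    stop_epsilon: float = 0.001
    committee_trees: int = 100
    stratified_initial: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.committee_size < 2:
            raise ValueError("committee_size must be at least 2")
        if self.n_initial < self.committee_size:
            raise ValueError("n_initial must be at least committee_size")
        if self.mode not in ("spectral", "spatial"):
            raise ValueError("mode must be 'spectral' or 'spatial'")
        if self.mode == "spatial" and not (
            self.range_threshold_m and self.range_threshold_m > 0
        ):
            raise ValueError("spatial mode requires a positive range_threshold_m")


@dataclass
class IterationRecord:
    iteration: int
    queried_id: str
    accepted: bool
    committee_accuracy: float | None  # None for discard records
    n_labeled: int
    entropy: float


@dataclass
class ALState:
    """Mutable audit state of one active-learning run."""

    labeled_ids: list
    unlabeled_ids: list
    discarded_ids: list
    committee: list
    history: list = field(default_factory=list)
    exhausted: bool = False
    _pool_size: int = 0

    def __post_init__(self):
        if not self._pool_size:
            self._pool_size = (
                len(self.labeled_ids) + len(self.unlabeled_ids) + len(self.discarded_ids)
            )

    def check_conservation(self):
        groups = (set(self.labeled_ids), set(self.unlabeled_ids), set(self.discarded_ids))
        total = sum(len(g) for g in groups)
        union = set().union(*groups)
        if total != self._pool_size or len(union) != self._pool_size:
            raise AssertionError("pool conservation violated: L, U, discarded must partition the pool")


def vote_entropy(votes: Sequence, committee_size: int) -> float:
    """Vote entropy −Σ_y (V(y)/C)·ln(V(y)/C) of one candidate's label votes.

    Zero when the committee is unanimous, maximal (ln C) when every member
    votes differently.
    """
    if committee_size <= 0:
        raise ValueError("committee size must be positive")
    votes = list(votes)
    if len(votes) != committee_size:
        raise ValueError(f"expected exactly {committee_size} votes, got {len(votes)}")
    ent = 0.0
    for count in Counter(votes).values():
        p = count / committee_size
        ent -= p * math.log(p)
    return ent


def _member_seed(config: ALConfig, member_index: int, generation: int = 0) -> int:
    # distinct, reproducible stream per (seed, member, retraining generation)
    return int(
        np.random.default_rng((config.seed, member_index, generation)).integers(2**31)
    )


def train_committee(
    labeled: SampleSet, config: ALConfig, generation: int = 0
) -> list:
    """Train C random forests, each on an independent bootstrap resample of L.

    Members are exchangeable but not identical: each draws its own resample
    and forest seed from (config.seed, member index, retraining generation).
    """
    classes = labeled.classes()
    if len(classes) < 2:
        raise ValueError(
            "labeled pool contains a single class; enlarge or stratify the initial pool"
        )
    X = labeled.feature_matrix()
    y = labeled.labels()
    committee = []
    for m in range(config.committee_size):
        seed = _member_seed(config, m, generation)
        rng = np.random.default_rng(seed)
        # resample until both the bootstrap keeps >= 2 classes
        for _ in range(100):
            idx = rng.integers(len(X), size=len(X))
            if len(set(y[idx])) >= 2:
                break
        clf = RandomForestClassifier(
            n_estimators=config.committee_trees, random_state=seed % (2**31)
        )
        clf.fit(X[idx], y[idx])
        committee.append(clf)
    return committee


@dataclass
class ALResult:
    """Outcome of a full run: final labeled ids, audit trail, stop reason."""

    labeled_ids: list
    discarded_ids: list
    unlabeled_ids: list
    history: list
    stop_reason: str  # plateau | exhausted | pool_empty
    config: ALConfig

    @property
    def n_labeled(self) -> int:
        return len(self.labeled_ids)

    def accuracy_trace(self) -> list:
        return [r.committee_accuracy for r in self.history if r.accepted]

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        return {
            "config": cfg,
            "stop_reason": self.stop_reason,
            "labeled_ids": list(self.labeled_ids),
            "discarded_ids": list(self.discarded_ids),
            "history": [asdict(r) for r in self.history],
        }


def init_pool(train: SampleSet, config: ALConfig) -> ALState:
    """Draw the initial labeled pool L (uniform at random, optionally
    class-stratified) and train the first committee."""
    if len(train) <= config.n_initial:
        raise ValueError(
            f"pool of {len(train)} cannot supply {config.n_initial} initial samples "
            "and a non-empty unlabeled set"
        )
    rng = np.random.default_rng(config.seed)
    ids = train.ids
    if config.stratified_initial:
        by_class: dict = {}
        for s in train:
            by_class.setdefault(s.label, []).append(s.id)
        chosen: list = []
        classes = sorted(by_class)
        quota, extra = divmod(config.n_initial, len(classes))
        for k, cls in enumerate(classes):
            take = quota + (1 if k < extra else 0)
            pool = by_class[cls]
            chosen.extend(
                pool[i] for i in rng.choice(len(pool), size=min(take, len(pool)), replace=False)
            )
        labeled = list(chosen[: config.n_initial])
    else:
        labeled = [ids[i] for i in rng.choice(len(ids), size=config.n_initial, replace=False)]
    unlabeled = [i for i in ids if i not in set(labeled)]
    committee = train_committee(train.subset(labeled), config, generation=0)
    return ALState(labeled, unlabeled, [], committee)


def rank_candidates(state: ALState, train: SampleSet, config: ALConfig) -> list:
    """Unlabeled candidate ids ordered by descending vote entropy.

    Ties — ubiquitous with a two-member committee, where entropy is either 0
    or ln 2 — are broken by a seeded uniform random permutation within each
    entropy level, so the order is reproducible but not position-biased.
    """
    cands = train.subset(state.unlabeled_ids)
    if not len(cands):
        raise ValueError("unlabeled pool is empty")
    X = cands.feature_matrix()
    votes = np.stack([m.predict(X) for m in state.committee], axis=1)
    ent = np.array(
        [vote_entropy(row, config.committee_size) for row in votes]
    )
    rng = np.random.default_rng((config.seed, len(state.labeled_ids), 7))
    shuffle = rng.permutation(len(ent))
    # stable sort over a pre-shuffled order randomizes within entropy ties
    order = shuffle[np.argsort(-ent[shuffle], kind="stable")]
    return [(cands.ids[i], float(ent[i])) for i in order]


def spatial_admissible(
    candidate, labeled: SampleSet, range_threshold_m: float
) -> bool:
    """True iff the candidate is at least the range threshold away from every
    labeled sample (distance exactly equal to the threshold is admissible;
    strictly below discards). Vacuously true for an empty labeled set."""
    if range_threshold_m <= 0:
        raise ValueError("range_threshold_m must be positive")
    if not len(labeled):
        return True
    d = cdist([[candidate.x, candidate.y]], labeled.coords())
    return bool(d.min() >= range_threshold_m)


def _committee_accuracy(state: ALState, train: SampleSet) -> float | None:
    """Majority-vote accuracy of the committee on the remaining unlabeled
    pool against oracle labels (ties go to the lower-index member)."""
    rest = train.subset(state.unlabeled_ids)
    if not len(rest):
        return None
    X = rest.feature_matrix()
    votes = np.stack([m.predict(X) for m in state.committee], axis=1)
    preds = []
    for row in votes:
        counts = Counter(row)
        top = max(counts.values())
        # first member whose vote attains the top count wins ties
        preds.append(next(v for v in row if counts[v] == top))
    return float(np.mean(np.array(preds) == rest.labels()))


def step(state: ALState, train: SampleSet, config: ALConfig) -> ALState:
    """One query iteration (mutates and returns ``state``).

    The top-entropy candidate is queried; in spatial mode inadmissible
    candidates are moved to the discarded pool until an admissible one is
    found or U is exhausted (then ``state.exhausted`` is set). The accepted
    sample takes its oracle label, joins L, and the committee is retrained;
    its accuracy on the remaining unlabeled pool is recorded.
    """
    if not state.unlabeled_ids:
        raise ValueError("unlabeled pool is empty")
    iteration = len(state.history) + 1
    ranked = rank_candidates(state, train, config)
    labeled_set = train.subset(state.labeled_ids)
    for cand_id, ent in ranked:
        if config.mode == "spatial" and not spatial_admissible(
            train.by_id(cand_id), labeled_set, config.range_threshold_m
        ):
            state.unlabeled_ids.remove(cand_id)
            state.discarded_ids.append(cand_id)
            state.history.append(
                IterationRecord(iteration, cand_id, False, None, len(state.labeled_ids), ent)
            )
            iteration += 1
            continue
        state.unlabeled_ids.remove(cand_id)
        state.labeled_ids.append(cand_id)  # oracle label comes with the sample
        generation = len(state.labeled_ids)
        state.committee = train_committee(
            train.subset(state.labeled_ids), config, generation=generation
        )
        acc = _committee_accuracy(state, train)
        state.history.append(
            IterationRecord(iteration, cand_id, True, acc, len(state.labeled_ids), ent)
        )
        state.check_conservation()
        return state
    state.exhausted = True
    state.check_conservation()
    return state


def check_stop(history: list, stop_window: int, stop_epsilon: float) -> bool:
    """Plateau rule: stop once the best committee accuracy over the last
    ``stop_window`` accepted queries exceeds the accuracy at the start of
    that window by less than ``stop_epsilon``."""
    accs = [r.committee_accuracy for r in history if r.accepted and r.committee_accuracy is not None]
    if len(accs) < stop_window:
        return False
    window = accs[-stop_window:]
    return (max(window) - window[0]) < stop_epsilon


def run_al(train: SampleSet, config: ALConfig) -> ALResult:
    """Run the full loop: iterate :func:`step` until the accuracy plateaus,
    no admissible candidate remains, or the unlabeled pool empties."""
    state = init_pool(train, config)
    stop_reason = "pool_empty"
    while state.unlabeled_ids:
        step(state, train, config)
        if state.exhausted:
            stop_reason = "exhausted"
            break
        if check_stop(state.history, config.stop_window, config.stop_epsilon):
            stop_reason = "plateau"
            break
    return ALResult(
        labeled_ids=list(state.labeled_ids),
        discarded_ids=list(state.discarded_ids),
        unlabeled_ids=list(state.unlabeled_ids),
        history=list(state.history),
        stop_reason=stop_reason,
        config=config,
    )
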
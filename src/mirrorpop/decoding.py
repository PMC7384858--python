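"""Pseudo-population condition decoding.

A maximum-correlation-coefficient classifier is trained per 50 ms bin on
z-scored pseudo-population rates (train-fold statistics only), evaluated by
stratified leave-one-split-out cross-validation, averaged over resampled
split assignments, and compared per bin against a label-permutation null.
A bin is significant only when observed accuracy exceeds *every* null
value, and significance is reported only within clusters of at least
``cluster_min`` consecutive significant bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from mirrorpop.dataio import SessionBundle
from mirrorpop.preprocess import bin_edges, bin_spikes

log = logging.getLogger(__name__)


@dataclass
class DecodingConfig:
    conditions: tuple[str, ...] = ("execution", "observation", "nogo")
    bin_width: float = 50.0
    window: tuple[float, float] = (-1000.0, 1000.0)  # ms around Go/NoGo
    trials_per_condition: int = 10
    cv_splits: int = 10
    resamples: int = 50
    permutations: int = 50
    cluster_min: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.trials_per_condition % self.cv_splits:
            raise ValueError("trials_per_condition must divide into cv_splits")
        if self.cluster_min < 1:
            raise ValueError("cluster_min must be >= 1")


@dataclass
class DecodingResult:
    accuracy: np.ndarray  # (bins,) observed mean accuracy
    null: np.ndarray  # (permutations, bins)
    significant: np.ndarray  # (bins,) bool, pointwise
    clusters: list[tuple[int, int]]  # inclusive (start, end) bin indices
    chance: float
    time_axis: np.ndarray = None
    config: DecodingConfig = None


def build_pseudopopulation(
    bundle: SessionBundle,
    config: DecodingConfig,
    neuron_ids: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pseudo-trials x neurons x bins rate tensor plus labels.

    Each unit contributes ``trials_per_condition`` independently sampled
    trials per condition (singly aligned to the Go/NoGo cue, raw 50 ms
    counts converted to rates).  Units below the trial floor in any
    requested condition are excluded with a log message.

    Returns (tensor, labels, time_axis); labels index into
    ``config.conditions``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = neuron_ids if neuron_ids is not None else bundle.neuron_ids
    edges = bin_edges(config.window, config.bin_width)
    n_bins = edges.size - 1
    trials_by_cond = {
        c: [t for t in bundle.select_trials(c) if "GoNogo" in t.events]
        for c in config.conditions
    }
    for c, trs in trials_by_cond.items():
        if len(trs) < config.trials_per_condition:
            raise ValueError(
                f"condition {c}: only {len(trs)} trials, need "
                f"{config.trials_per_condition}"
            )
    # pre-bin every trial for every unit
    binned = {}  # (cond, trial position) -> (units, bins)
    usable_ids = []
    for nid in ids:
        ok = True
        for c, trs in trials_by_cond.items():
            with_unit = [t for t in trs if nid in t.spikes]
            if len(with_unit) < config.trials_per_condition:
                ok = False
        if ok:
            usable_ids.append(nid)
        else:
            log.info("unit %s below trial floor; excluded from decoding", nid)
    n_units = len(usable_ids)
    if n_units == 0:
        raise ValueError("no units meet the per-condition trial floor")

    n_per = config.trials_per_condition
    tensor = np.zeros((len(config.conditions) * n_per, n_units, n_bins))
    labels = np.repeat(np.arange(len(config.conditions)), n_per)
    scale = 1000.0 / config.bin_width
    for ci, c in enumerate(config.conditions):
        trs = trials_by_cond[c]
        for ui, nid in enumerate(usable_ids):
            pick = rng.choice(len(trs), size=n_per, replace=False)
            for pi, ti in enumerate(pick):
                tr = trs[ti]
                st = np.asarray(tr.spikes[nid]) - tr.events["GoNogo"]
                tensor[ci * n_per + pi, ui] = (
                    bin_spikes(st, config.window, config.bin_width) * scale
                )
    return tensor, labels, edges[:-1]


def max_corr_classify(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray
) -> np.ndarray:
    """Maximum correlation coefficient classifier.

    Features are z-scored with training-set statistics; class templates are
    mean training vectors; each test point is assigned the class whose
    template correlates maximally with it (ties break to the lowest class
    index).  A zero-variance test vector has undefined correlation and is
    returned as -1 (callers count it incorrect).
    """
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.atleast_2d(np.asarray(test_x, dtype=float))
    classes = np.unique(train_y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    mu = train_x.mean(axis=0)
    sd = train_x.std(axis=0)
    sd[sd == 0] = 1.0
    tr = (train_x - mu) / sd
    te = (test_x - mu) / sd
    templates = np.vstack([tr[train_y == c].mean(axis=0) for c in classes])
    tc = templates - templates.mean(axis=1, keepdims=True)
    ec = te - te.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(tc, axis=1)
    en = np.linalg.norm(ec, axis=1)
    corr = ec @ tc.T
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = corr / en[:, None] / tn[None, :]
    pred = np.where(
        (en == 0) | ~np.isfinite(corr).all(axis=1),
        -1,
        classes[np.argmax(corr, axis=1)],
    )
    return pred


def _stratified_splits(rng, labels, n_splits):
    """Assign each point to a split, one point per class per split."""
    assign = np.empty(labels.size, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        per = idx.size // n_splits
        order = rng.permutation(idx)
        for s in range(n_splits):
            assign[order[s * per:(s + 1) * per]] = s
    return assign


def _cv_accuracy(rng, x, labels, n_splits):
    """One resample: mean leave-one-split-out accuracy for one bin."""
    assign = _stratified_splits(rng, labels, n_splits)
    correct = 0
    total = 0
    for s in range(n_splits):
        test = assign == s
        pred = max_corr_classify(x[~test], labels[~test], x[test])
        correct += int((pred == labels[test]).sum())
        total += int(test.sum())
    return correct / total


def decode_timecourse(
    tensor: np.ndarray,
    labels: np.ndarray,
    config: DecodingConfig,
    time_axis: np.ndarray | None = None,
) -> DecodingResult:
    """Per-bin cross-validated accuracy, permutation null, and clusters."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_points, n_units, n_bins = tensor.shape
    acc = np.empty(n_bins)
    for b in range(n_bins):
        x = tensor[:, :, b]
        acc[b] = np.mean(
            [_cv_accuracy(rng, x, labels, config.cv_splits)
             for _ in range(config.resamples)]
        )
    null = np.empty((config.permutations, n_bins))
    for p in range(config.permutations):
        perm_labels = rng.permutation(labels)
        for b in range(n_bins):
            x = tensor[:, :, b]
            null[p, b] = np.mean(
                [_cv_accuracy(rng, x, perm_labels, config.cv_splits)
                 for _ in range(config.resamples)]
            )
    significant = acc > null.max(axis=0)
    clusters = find_clusters(significant, config.cluster_min)
    in_cluster = np.zeros(n_bins, dtype=bool)
    for s, e in clusters:
        in_cluster[s:e + 1] = True
    return DecodingResult(
        accuracy=acc,
        null=null,
        significant=significant & in_cluster,
        clusters=clusters,
        chance=1.0 / np.unique(labels).size,
        time_axis=time_axis,
        config=config,
    )


def find_clusters(significant: np.ndarray, cluster_min: int) -> list[tuple[int, int]]:
    """Maximal runs of >= cluster_min consecutive True bins, as inclusive
    (start, end) index pairs."""
    out = []
    start = None
    sig = np.concatenate([np.asarray(significant, dtype=bool), [False]])
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            if i - start >= cluster_min:
                out.append((start, i - 1))
            start = None
    return out
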
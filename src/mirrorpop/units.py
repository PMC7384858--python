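"""Single-neuron task-modulation testing and mirror-neuron categorization.

A unit is *modulated* in a condition when a 2-way ANOVA (EPOCH x GRASP) on
trial-level epoch mean rates shows a significant epoch main effect or
interaction, AND at least one post-hoc task-epoch-vs-baseline comparison is
significant.  Units modulated in both execution and observation are mirror
neurons (MNs); MNs are categorized F/S per condition by the sign of their
largest absolute deviation from baseline over the two task epochs,
yielding F-F / F-S / S-F / S-S per grasp.

The ANOVA is implemented directly (Type-II sums of squares via nested
least-squares fits) so it stays fast for calibration runs over thousands of
simulated units; post-hoc tests are paired t-tests (epochs are within
trial), uncorrected by default with an optional Holm correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
TASK_EPOCHS = ("Reach", "GraspHold")
BASELINE_EPOCH = "Baseline"


class ZeroVarianceError(ValueError):
    """All cells have zero variance; the unit is untestable."""


@dataclass
class ConditionStats:
    p_epoch: float
    p_grasp: float
    p_interaction: float
    posthoc: dict  # (grasp, epoch) -> p
    modulated: bool


@dataclass
class UnitClassification:
    neuron_id: str
    per_condition: dict[str, ConditionStats] = field(default_factory=dict)
    is_mn: bool = False
    category: dict[str, str] = field(default_factory=dict)  # grasp -> F-F etc.


def _dummy(labels):
    levels = sorted(set(labels))
    idx = {l: i for i, l in enumerate(levels)}
    x = np.zeros((len(labels), len(levels) - 1))
    for r, l in enumerate(labels):
        if idx[l] > 0:
            x[r, idx[l] - 1] = 1.0
    return x, levels


def _rss(y, x):
    if x.shape[1] == 0:
        return float(((y - y.mean()) ** 2).sum()), 1
    xx = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(xx, y, rcond=None)
    resid = y - xx @ beta
    return float(resid @ resid), int(np.linalg.matrix_rank(xx))


def two_way_anova(y, a_labels, b_labels):
    """Type-II two-way ANOVA with interaction on (possibly unbalanced) data.

    Returns (p_a, p_b, p_interaction).  Implemented via nested OLS fits:
    SS(A|B) = RSS(B) - RSS(A+B), SS(AB|A+B) = RSS(A+B) - RSS(A+B+AB); the
    error term comes from the full model.
    """
    y = np.asarray(y, dtype=float)
    xa, _ = _dummy(a_labels)
    xb, _ = _dummy(b_labels)
    xab = np.column_stack(
        [xa[:, i] * xb[:, j] for i in range(xa.shape[1]) for j in range(xb.shape[1])]
    ) if xa.shape[1] and xb.shape[1] else np.zeros((len(y), 0))

    rss_b, _ = _rss(y, xb)
    rss_a, _ = _rss(y, xa)
    rss_ab, rank_add = _rss(y, np.column_stack([xa, xb]))
    rss_full, rank_full = _rss(y, np.column_stack([xa, xb, xab]))

    df_err = len(y) - rank_full
    if df_err <= 0:
        raise ZeroVarianceError("no error degrees of freedom")
    ms_err = rss_full / df_err
    if ms_err == 0:
        raise ZeroVarianceError("zero variance in all cells")

    def ftest(ss, df):
        if df <= 0:
            return 1.0
        f = (ss / df) / ms_err
        return float(stats.f.sf(max(f, 0.0), df, df_err))

    df_a = xa.shape[1]
    df_b = xb.shape[1]
    df_ab = xab.shape[1]
    p_a = ftest(rss_b - rss_ab, df_a)
    p_b = ftest(rss_a - rss_ab, df_b)
    p_ab = ftest(rss_ab - rss_full, df_ab)
    return p_a, p_b, p_ab


def _holm(pvals: dict, alpha: float) -> dict:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj = {}
    running = 0.0
    for i, (k, p) in enumerate(items):
        running = max(running, min((m - i) * p, 1.0))
        adj[k] = running
    return adj


def condition_stats(
    table: pd.DataFrame,
    alpha: float = ALPHA,
    holm: bool = False,
) -> ConditionStats:
    """ANOVA + post-hoc stats for one neuron in one condition.

    *table* is long-format with columns trial, grasp, epoch, rate, holding
    the three ANOVA epochs.
    """
    y = table["rate"].to_numpy(dtype=float)
    p_epoch, p_grasp, p_inter = two_way_anova(
        y, table["epoch"].tolist(), table["grasp"].tolist()
    )
    posthoc = {}
    wide = table.pivot_table(index=["grasp", "trial"], columns="epoch",
                             values="rate")
    for grasp in sorted(table["grasp"].unique()):
        sub = wide.loc[grasp]
        for ep in TASK_EPOCHS:
            if ep not in sub or BASELINE_EPOCH not in sub:
                continue
            pair = sub[[ep, BASELINE_EPOCH]].dropna()
            if len(pair) < 2:
                continue
            d = pair[ep] - pair[BASELINE_EPOCH]
            if np.allclose(d, d.iloc[0]):
                p = 0.0 if d.iloc[0] != 0 else 1.0
            else:
                p = float(stats.ttest_rel(pair[ep], pair[BASELINE_EPOCH]).pvalue)
            posthoc[(grasp, ep)] = p
    if holm and posthoc:
        posthoc = _holm(posthoc, alpha)
    any_posthoc = any(p < alpha for p in posthoc.values())
    modulated = (p_epoch < alpha or p_inter < alpha) and any_posthoc
    return ConditionStats(
        p_epoch=p_epoch, p_grasp=p_grasp, p_interaction=p_inter,
        posthoc=posthoc, modulated=modulated,
    )


def mn_category(table: pd.DataFrame, grasp: str) -> str:
    """F/S pair for one grasp: sign of the largest |epoch - baseline|
    deviation over the task epochs, execution then observation.

    Exact ties in |deviation| are resolved in favour of the earlier epoch
    (Reach).  Invariant to adding a constant to all epochs.
    """
    signs = []
    for cond in ("execution", "observation"):
        sub = table[(table["condition"] == cond) & (table["grasp"] == grasp)]
        means = sub.groupby("epoch")["rate"].mean()
        base = means.get(BASELINE_EPOCH, 0.0)
        best, best_abs = 0.0, -1.0
        for ep in TASK_EPOCHS:  # Reach first: earlier epoch wins exact ties
            if ep not in means:
                continue
            dev = means[ep] - base
            if abs(dev) > best_abs:
                best, best_abs = dev, abs(dev)
        signs.append("F" if best >= 0 else "S")
    return "-".join(signs)


def anova_classify(
    epoch_table: pd.DataFrame,
    alpha: float = ALPHA,
    holm: bool = False,
    min_trials: int = 10,
) -> list[UnitClassification]:
    """Classify every neuron in a long epoch-rate table.

    *epoch_table* comes from :func:`mirrorpop.preprocess.epoch_average` with
    the ANOVA epochs.  Units with fewer than *min_trials* trials per grasp
    in either Go condition, or with zero variance in all cells, are skipped.
    """
    out = []
    for nid, tbl in epoch_table.groupby("neuron_id", sort=True):
        cls = UnitClassification(neuron_id=nid)
        ok = True
        for cond in ("execution", "observation"):
            sub = tbl[tbl["condition"] == cond]
            n_per_grasp = sub.groupby("grasp")["trial"].nunique()
            if len(n_per_grasp) < 2 or (n_per_grasp < min_trials).any():
                ok = False
                break
            try:
                cls.per_condition[cond] = condition_stats(sub, alpha, holm)
            except ZeroVarianceError:
                ok = False
                break
        if not ok:
            continue
        cls.is_mn = all(cls.per_condition[c].modulated
                        for c in ("execution", "observation"))
        if cls.is_mn:
            for grasp in sorted(tbl["grasp"].unique()):
                cls.category[grasp] = mn_category(tbl, grasp)
        out.append(cls)
    return out


def classification_table(classifications: list[UnitClassification]) -> pd.DataFrame:
    """Flat CSV-ready table of the classification results."""
    rows = []
    for c in classifications:
        row = {"neuron_id": c.neuron_id, "is_MN": c.is_mn}
        for cond, st in c.per_condition.items():
            row[f"{cond}_p_epoch"] = st.p_epoch
            row[f"{cond}_p_grasp"] = st.p_grasp
            row[f"{cond}_p_interaction"] = st.p_interaction
            row[f"{cond}_modulated"] = st.modulated
        for grasp, cat in c.category.items():
            row[f"category_{grasp}"] = cat
        rows.append(row)
    return pd.DataFrame(rows)
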
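"""Group-level statistics: per-lead ANOVA across the four imagery tasks
with Benjamini-Hochberg FDR correction, descriptives, and 18-channel
correlation connectivity.

The per-lead test is a one-way ANOVA on subject-level mean amplitudes
(between-groups df = 3 for four tasks); a pooled two-factor task x lead
model is reported alongside. Connectivity is the Pearson correlation
between channel time courses, averaged across epochs through Fisher's z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaTable",
    "ConnectivityMatrix",
    "trial_mean_table",
    "lead_anova",
    "fdr_adjust",
    "descriptives",
    "connectivity",
    "strongest_pair",
]

TASKS = ("forward", "reverse", "left", "right")


@dataclass
class AnovaTable:
    """Per-lead one-way ANOVA results (with FDR-adjusted p-values) plus the
    pooled two-factor task x lead model."""

    per_lead: pd.DataFrame  # lead, df_between, mean_square, F, p, p_fdr, significant
    two_factor: pd.DataFrame
    alpha: float = 0.05


@dataclass
class ConnectivityMatrix:
    """Symmetric 18 x 18 channel-correlation matrix for one task."""

    matrix: np.ndarray
    labels: list[str]
    task: str
    n_epochs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels,
                            columns=self.labels)


# ---------------------------------------------------------------------------


def trial_mean_table(epochs) -> pd.DataFrame:
    """Per-trial mean amplitude of every lead, tidy long format
    (subject, block, task, lead, value in microvolts)."""
    rows = []
    for ep in epochs:
        means = ep.data.mean(axis=1)
        for lead, v in zip(ep.channel_labels, means):
            rows.append(
                {
                    "subject": ep.subject,
                    "block": ep.block,
                    "task": ep.task,
                    "lead": lead,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def lead_anova(trial_means: pd.DataFrame, alpha: float = 0.05) -> AnovaTable:
    """Per-lead one-way ANOVA across the four tasks on subject-level means,
    BH-corrected across leads, plus a pooled two-factor model.

    ``trial_means`` is the long table from :func:`trial_mean_table` (or any
    table with columns subject, task, lead, value). Trials are first
    averaged within subject x task x lead, so each cell contributes one
    observation per subject.
    """
    required = {"subject", "task", "lead", "value"}
    missing_cols = required - set(trial_means.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")

    cell = (
        trial_means.groupby(["subject", "task", "lead"], as_index=False)[
            "value"
        ].mean()
    )
    n_subjects = cell["subject"].nunique()
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    counts = cell.groupby(["subject", "task", "lead"]).size()
    full = pd.MultiIndex.from_product(
        [
            sorted(cell["subject"].unique()),
            sorted(cell["task"].unique()),
            sorted(cell["lead"].unique()),
        ],
        names=["subject", "task", "lead"],
    )
    empty = full.difference(counts.index)
    if len(empty):
        cells = [f"subject {s}, {t}/{lead}" for s, t, lead in empty]
        raise ValueError(f"missing cells: {cells}")

    rows = []
    for lead, grp in cell.groupby("lead"):
        groups = [g["value"].to_numpy() for _, g in grp.groupby("task")]
        if len(groups) != len(TASKS):
            raise ValueError(f"lead {lead}: not all tasks present")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p = spstats.f_oneway(*groups)
        gm = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
        df_between = len(groups) - 1
        if not np.isfinite(f_stat) and np.isclose(ss_between, 0.0):
            f_stat, p = 0.0, 1.0  # no variation at all: no effect
        rows.append(
            {
                "lead": lead,
                "df_between": df_between,
                "mean_square": ss_between / df_between,
                "F": float(f_stat),
                "p": float(p),
            }
        )
    per_lead = pd.DataFrame(rows)
    per_lead["p_fdr"] = fdr_adjust(per_lead["p"].to_numpy())
    per_lead["significant"] = per_lead["p_fdr"] < alpha

    model = smf.ols("value ~ C(task) * C(lead)", data=cell).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        two_factor = sm.stats.anova_lm(model, typ=2)
    return AnovaTable(per_lead=per_lead, two_factor=two_factor, alpha=alpha)


def descriptives(trial_means: pd.DataFrame) -> pd.DataFrame:
    """Mean (sd) amplitude per lead x task, in microvolts."""
    out = (
        trial_means.groupby(["lead", "task"])["value"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "mean_uV", "std": "sd_uV"})
    )
    return out


# ---------------------------------------------------------------------------
# connectivity


def connectivity(epochs, task: str) -> ConnectivityMatrix:
    """Channel x channel Pearson correlation during one task, Fisher-z
    averaged across that task's epochs.

    Zero-variance channels yield zero correlations (with a warning) rather
    than NaNs.
    """
    sel = [e for e in epochs if e.task == task]
    if not sel:
        raise ValueError(f"no epochs with task {task!r}")
    labels = list(sel[0].channel_labels)
    n = len(labels)
    z_sum = np.zeros((n, n))
    for ep in sel:
        sd = ep.data.std(axis=1)
        flat = sd == 0
        if flat.any():
            bad = [labels[i] for i in np.flatnonzero(flat)]
            warnings.warn(
                f"zero-variance channel(s) {bad}; correlations set to 0",
                stacklevel=2,
            )
        safe = ep.data.copy()
        safe[flat] = np.random.default_rng(0).standard_normal(
            (int(flat.sum()), ep.data.shape[1])
        )  # placeholder rows, zeroed below
        r = np.corrcoef(safe)
        r[flat, :] = 0.0
        r[:, flat] = 0.0
        np.fill_diagonal(r, 1.0)
        z_sum += np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    r_mean = np.tanh(z_sum / len(sel))
    np.fill_diagonal(r_mean, 1.0)
    r_mean = 0.5 * (r_mean + r_mean.T)
    return ConnectivityMatrix(
        matrix=r_mean, labels=labels, task=task, n_epochs=len(sel)
    )


def strongest_pair(conn: ConnectivityMatrix) -> tuple[str, str]:
    """Off-diagonal pair with maximal |r|; ties break lexicographically."""
    n = len(conn.labels)
    best = None
    best_val = -np.inf
    pairs = sorted(
        (tuple(sorted((conn.labels[i], conn.labels[j]))), i, j)
        for i in range(n)
        for j in range(i + 1, n)
    )
    for names, i, j in pairs:
        v = abs(conn.matrix[i, j])
        if v > best_val:
            best, best_val = names, v
    return best
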
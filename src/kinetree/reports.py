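"""Summary analyses: confusion matrices, psychometric and confidence curves,
and repetition consistency.

These are the descriptive statistics of the identification experiments.
Curves are binned versions of per-trial quantities (ideal-observer log-odds
or the logit of the Bayesian predicted confidence); default binning uses
equal-count (quantile) bins over the pooled x-values, with log-odds clamped
to +-30 nats for display.  Binomial counts are retained for error bars, and
empty bins are reported as missing rather than zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .sessions import SessionDataset

__all__ = [
    "confusion_matrix",
    "expected_confusion_matrix",
    "psychometric_curve",
    "consistency",
    "cohort_consistency",
    "confidence_curve",
    "quantile_bins",
    "LOG_ODDS_CLAMP",
]

LOG_ODDS_CLAMP = 30.0


def confusion_matrix(
    true_labels: Sequence[str] | SessionDataset,
    choices: Sequence[str] | None = None,
    labels: Sequence[str] = ("I", "G", "C", "H"),
) -> pd.DataFrame:
    """Row-normalized empirical choice frequencies.

    Rows are true structures, columns chosen structures.  Rows with no
    trials are reported as NaN, not zero.  Accepts a responded
    :class:`SessionDataset` or explicit label/choice sequences.
    """
    if isinstance(true_labels, SessionDataset):
        ds = true_labels
        choices = ds.choices
        true_labels = ds.trial_labels
        labels = ds.choice_labels
    true_labels = np.asarray(true_labels, dtype=object)
    choices = np.asarray(choices, dtype=object)
    mat = np.full((len(labels), len(labels)), np.nan)
    for i, s in enumerate(labels):
        row_mask = true_labels == s
        n = int(row_mask.sum())
        if n == 0:
            continue
        for j, c in enumerate(labels):
            mat[i, j] = np.sum(choices[row_mask] == c) / n
    return pd.DataFrame(mat, index=list(labels), columns=list(labels))


def expected_confusion_matrix(
    true_labels: Sequence[str],
    predicted_probs: np.ndarray,
    labels: Sequence[str] = ("I", "G", "C", "H"),
) -> pd.DataFrame:
    """Model confusion matrix: mean predicted choice distribution per row.

    ``predicted_probs`` holds one distribution over ``labels`` per trial
    (e.g. cross-validated model predictions).
    """
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_probs = np.asarray(predicted_probs, dtype=float)
    mat = np.full((len(labels), len(labels)), np.nan)
    for i, s in enumerate(labels):
        mask = true_labels == s
        if mask.sum():
            mat[i] = predicted_probs[mask].mean(axis=0)
    return pd.DataFrame(mat, index=list(labels), columns=list(labels))


def quantile_bins(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-count bin edges over pooled values."""
    return np.unique(np.quantile(np.asarray(x, dtype=float), np.linspace(0, 1, n_bins + 1)))


def psychometric_curve(
    log_odds: np.ndarray,
    chosen: np.ndarray,
    bins: np.ndarray | int = 10,
    model_probs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binned choice frequency as a function of ideal-observer log-odds.

    ``chosen`` is a boolean indicator (structure S was chosen) aligned with
    the per-trial log-odds for S.  Returns bin centers, empirical choice
    fractions with trial counts (for binomial error bars), and — when
    per-trial model probabilities are passed — the model curve as the mean
    predicted probability per bin.
    """
    log_odds = np.clip(np.asarray(log_odds, dtype=float),
                       -LOG_ODDS_CLAMP, LOG_ODDS_CLAMP)
    chosen = np.asarray(chosen, dtype=float)
    edges = quantile_bins(log_odds, bins) if np.isscalar(bins) else np.sort(np.asarray(bins))
    if log_odds.min() < edges[0] or log_odds.max() > edges[-1]:
        raise ValueError("bins must cover the observed log-odds range")
    idx = np.clip(np.digitize(log_odds, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        rows.append(
            {
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "n": n,
                "fraction": chosen[mask].mean() if n else np.nan,
                "model": (model_probs[mask].mean()
                          if (model_probs is not None and n) else np.nan),
            }
        )
    return pd.DataFrame(rows)


def consistency(dataset: SessionDataset) -> float:
    """Fraction of repetition pairs answered with the identical structure."""
    if dataset.pair_ids is None:
        raise ValueError("consistency is undefined without repetition pairs")
    if dataset.choices is None:
        raise ValueError("consistency needs responses")
    df = pd.DataFrame({"pair": dataset.pair_ids, "choice": dataset.choices})
    agree = df.groupby("pair")["choice"].agg(lambda c: c.iloc[0] == c.iloc[-1])
    return float(agree.mean())


def cohort_consistency(datasets: Sequence[SessionDataset]) -> pd.Series:
    """Per-participant consistency plus cohort mean and s.e.m. (n-1)."""
    vals = pd.Series({ds.participant: consistency(ds) for ds in datasets})
    summary = vals.copy()
    summary.loc["mean"] = vals.mean()
    summary.loc["sem"] = vals.std(ddof=1) / np.sqrt(len(vals))
    return summary


def confidence_curve(
    reported_high: np.ndarray,
    bayes_confidence: np.ndarray,
    bins: np.ndarray | int = 10,
) -> pd.DataFrame:
    """Mean reported (binary) confidence per bin of logit Bayesian confidence."""
    conf = np.clip(np.asarray(bayes_confidence, dtype=float), 1e-12, 1 - 1e-12)
    x = np.clip(np.log(conf) - np.log1p(-conf), -LOG_ODDS_CLAMP, LOG_ODDS_CLAMP)
    return psychometric_curve(x, np.asarray(reported_high, dtype=float), bins=bins)
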
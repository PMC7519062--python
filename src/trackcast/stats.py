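"""Quantitative evaluation: prediction MSE, t-test comparisons and screens.

The headline check of the package is distributional: a predictor is "good"
when the descriptor distributions extracted from predicted track endings are
statistically indistinguishable (two-sample Student's t-test, alpha = 0.05)
from those extracted from the corresponding ground-truth endings.  Condition
contrasts (e.g. drug vs no-drug) use the same test between condition labels
and ask whether significance found on ground truth survives on predictions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    descriptor: str
    group_a: str
    n_a: int
    group_b: str
    n_b: int
    t_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["significant"] = self.significant
        return d


def average_mse(results) -> float:
    """Mean over tracks of the per-track mean squared Euclidean error.

    ``results`` is an iterable of objects with ``ground_truth_ending`` and
    ``predicted_ending`` (n, 2) arrays of equal length (or bare array pairs).
    """
    per_track = []
    for item in results:
        if hasattr(item, "ground_truth_ending"):
            y, yhat = item.ground_truth_ending, item.predicted_ending
        else:
            y, yhat = item
        y = np.asarray(y, float)
        yhat = np.asarray(yhat, float)
        if y.shape != yhat.shape:
            raise ValueError("paired sequences differ in shape")
        per_track.append(float(((y - yhat) ** 2).sum(axis=1).mean()))
    if not per_track:
        raise ValueError("no prediction results")
    return float(np.mean(per_track))


def compare_distributions(samples_a, samples_b, label_a: str = "a",
                          label_b: str = "b", descriptor: str = "",
                          equal_var: bool = True) -> ComparisonResult:
    """Two-sample two-tailed Student's t-test between empirical samples.

    Pooled-variance by default (the literal Student test); set
    ``equal_var=False`` for Welch.  Degenerate input (both groups constant
    and equal) yields t = 0, p = 1 by convention.
    """
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 finite samples")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(descriptor, label_a, a.size, label_b, b.size,
                            float(t), float(p))


def _values(df: pd.DataFrame, name: str, **filters) -> np.ndarray:
    mask = df["name"] == name
    for col, val in filters.items():
        mask &= df[col] == val
    return df.loc[mask, "value"].to_numpy()


def equivalence_screen(descriptor_df: pd.DataFrame, descriptor_set,
                       equal_var: bool = True) -> list[ComparisonResult]:
    """Predicted-vs-ground-truth comparison, one t-test per descriptor.

    ``descriptor_df`` holds rows for both ``source`` values ("ground_truth"
    and "predicted") of the same tracks.  The screen passes when no
    descriptor differs significantly (see :func:`screen_passes`).
    """
    out = []
    for name in descriptor_set:
        truth = _values(descriptor_df, name, source="ground_truth")
        pred = _values(descriptor_df, name, source="predicted")
        if truth.size == 0 or pred.size == 0:
            raise ValueError(f"missing {name!r} samples for a source")
        out.append(compare_distributions(truth, pred, "ground_truth", "predicted",
                                         descriptor=name, equal_var=equal_var))
    return out


def contrast_screen(descriptor_df: pd.DataFrame, descriptor_set,
                    cond_a: str, cond_b: str,
                    equal_var: bool = True) -> dict[str, list[ComparisonResult]]:
    """Condition contrast per source: does the ground-truth effect survive
    on predictions?  Returns comparisons keyed by source."""
    out: dict[str, list[ComparisonResult]] = {}
    for source in sorted(descriptor_df["source"].unique()):
        comps = []
        for name in descriptor_set:
            a = _values(descriptor_df, name, source=source, condition_label=cond_a)
            b = _values(descriptor_df, name, source=source, condition_label=cond_b)
            if a.size == 0 or b.size == 0:
                raise ValueError(f"missing condition samples for {name!r}")
            comps.append(compare_distributions(a, b, cond_a, cond_b,
                                               descriptor=name,
                                               equal_var=equal_var))
        out[source] = comps
    return out


def screen_passes(comparisons: list[ComparisonResult]) -> bool:
    """True when no descriptor comparison is significant at alpha = 0.05."""
    return not any(c.significant for c in comparisons)


def boxplot_pairs(descriptor_df: pd.DataFrame, descriptor_set, path) -> None:
    """Side-by-side ground-truth/predicted boxplots, one panel per descriptor."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(descriptor_set),
                             figsize=(4 * len(descriptor_set), 4))
    if len(descriptor_set) == 1:
        axes = [axes]
    for ax, name in zip(axes, descriptor_set):
        truth = _values(descriptor_df, name, source="ground_truth")
        pred = _values(descriptor_df, name, source="predicted")
        ax.boxplot([truth, pred], tick_labels=["ground truth", "predicted"])
        ax.set_title(name)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
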